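"""Integrate clinical, proteomic and AFM variables by PCA.

Z-scores the per-patient variable matrix (SLRP proteoglycan abundances,
modulus, morphometry, PWV, clinical covariates), projects onto the first two
principal components, and draws 67%-coverage group ellipses. Patients with
missing proteomic panels are excluded, mirroring incomplete clinical data.
"""

import json

from advafm import io, pipeline


def main() -> None:
    pca, ellipses = pipeline.run_integration("results")
    summary = json.loads(open("results/pca_summary.json").read())

    evr = summary["explained_variance_ratio"]
    print(f"PC1 explains {evr[0]:.0%}, PC2 {evr[1]:.0%} of variance "
          f"({len(pca.scores)} complete patients, "
          f"{len(summary['excluded_patients'])} excluded for missing data)")
    loadings = io.read_table("results/pca_loadings.csv").set_index("variable")
    top = loadings["PC1"].abs().sort_values(ascending=False).head(3).index.tolist()
    print(f"strongest PC1 loadings: {', '.join(top)}")
    for e in ellipses:
        print(f"67% ellipse [{e.group}]: centre=({e.center[0]:+.2f}, "
              f"{e.center[1]:+.2f}), degenerate={e.degenerate}")
    print("wrote results/pca_scores.csv, pca_loadings.csv, pca_summary.json")


if __name__ == "__main__":
    main()
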