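"""End-to-end study pipeline: simulate a cohort to disk, then analyze it.

``simulate_study`` lays a full synthetic study out on disk (topography TIFFs
with calibration sidecars, ground-truth tables, DMT force curves including a
reference-sample set, patient tables, a checksummed manifest).
``run_study`` replays the published analysis over such a directory:
morphometry -> nanomechanics (with reference calibration) -> patient
aggregation and group statistics -> PCA integration, writing every stage's
tables under the results directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohortstats, integration, io, morphometry, nanomech, synthetic
from ._rng import derive_seed, substream
from .config import PipelineConfig

__all__ = [
    "simulate_study",
    "run_morphometry",
    "run_nanomech",
    "run_group_stats",
    "run_integration",
    "run_study",
]

log = logging.getLogger("advafm")

#: Curves sampled per force-volume map in the simulated study (a thinned
#: stand-in for the 65,536 curves of a full map).
CURVES_PER_IMAGE = 16
N_REFERENCE_CURVES = 24
REFERENCE_MODULUS_MPA = 2700.0  # photoelastic coating polymer, order GPa-ish


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_study(
    config: PipelineConfig, out_dir: str | Path, force: bool = False
) -> Path:
    """Generate and write the full synthetic study; returns the directory."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)

    cfg = replace(config.cohort, seed=config.seed)
    cohort = synthetic.generate_cohort(cfg)
    seed = config.seed

    written: list[Path] = []
    written.append(io.write_table(cohort.patients, out / "patients.csv", seed=seed))
    written.append(io.write_table(cohort.images, out / "image_truth.csv", seed=seed))
    written.append(io.write_table(cohort.fibrils, out / "fibril_truth.csv", seed=seed))

    truth_frames = []
    curve_frames = []
    for _, img in cohort.images.iterrows():
        pid, img_id = img["patient_id"], img["image_id"]
        group = cohort.patients.set_index("patient_id").loc[pid, "group"]
        fspec = cfg.field_low if group == "low" else cfg.field_high
        img_seed = derive_seed(seed, f"render:{img_id}")
        image, truth = synthetic.render_fibril_image(
            fspec, nm_per_px=config.nm_per_px, size_px=config.image_size_px, seed=img_seed
        )
        image.id = img_id
        written.append(
            io.write_topography(image, out / "images" / f"{img_id}.tif", seed=img_seed, spec=fspec)
        )
        truth["image_id"] = img_id
        truth_frames.append(truth)

        rng = substream(seed, f"curves:{img_id}")
        for k in range(CURVES_PER_IMAGE):
            e = max(float(rng.normal(img["modulus_MPa"], 0.05 * img["modulus_MPa"])), 1.0)
            curve = synthetic.generate_force_curve(
                E_sample_MPa=e,
                nu=config.dmt.nu,
                R_nm=config.dmt.R_nm,
                F_adh_nN=-2.0,
                max_depth_nm=10.0,
                noise_sd_nN=1.0,
                seed=int(rng.integers(2**31)),
                curve_id=f"{img_id}-c{k}",
            )
            curve_frames.append(
                pd.DataFrame(
                    {
                        "image_id": img_id,
                        "curve_id": curve.curve_id,
                        "depth_nm": curve.depth_nm,
                        "force_nN": curve.force_nN,
                    }
                )
            )

    written.append(
        io.write_table(pd.concat(truth_frames, ignore_index=True), out / "ground_truth.csv", seed=seed)
    )
    written.append(
        io.write_table(pd.concat(curve_frames, ignore_index=True), out / "force_curves.csv", seed=seed)
    )

    # reference-sample curves for modulus calibration
    rng = substream(seed, "reference")
    ref_frames = []
    for k in range(N_REFERENCE_CURVES):
        curve = synthetic.generate_force_curve(
            E_sample_MPa=REFERENCE_MODULUS_MPA,
            nu=config.dmt.nu,
            R_nm=config.dmt.R_nm,
            F_adh_nN=-1.0,
            max_depth_nm=10.0,
            noise_sd_nN=0.5,
            seed=int(rng.integers(2**31)),
            curve_id=f"ref-c{k}",
        )
        ref_frames.append(
            pd.DataFrame(
                {"curve_id": curve.curve_id, "depth_nm": curve.depth_nm, "force_nN": curve.force_nN}
            )
        )
    written.append(
        io.write_table(pd.concat(ref_frames, ignore_index=True), out / "reference_curves.csv", seed=seed)
    )
    (out / "reference_meta.json").write_text(
        json.dumps({"E_ref_known_MPa": REFERENCE_MODULUS_MPA})
    )
    written.append(out / "reference_meta.json")

    manifest = {
        "seed": seed,
        "config_hash": config.hash(),
        "files": {str(p.relative_to(out)): _checksum(p) for p in sorted(written)},
    }
    # sidecars travel with their TIFFs
    for sc in sorted((out / "images").glob("*.json")):
        manifest["files"][str(sc.relative_to(out))] = _checksum(sc)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _fit_curves(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    rows = []
    for cid, g in df.groupby("curve_id", sort=False):
        curve = nanomech.ForceCurve(
            depth_nm=g["depth_nm"].to_numpy(), force_nN=g["force_nN"].to_numpy(), curve_id=str(cid)
        )
        image_id = g["image_id"].iloc[0] if "image_id" in g else ""
        try:
            fit = nanomech.fit_dmt(
                curve, R_nm=config.dmt.R_nm, nu=config.dmt.nu, fit_window=config.dmt.fit_window
            )
            rows.append(
                {
                    "curve_id": cid,
                    "image_id": image_id,
                    "E_MPa": fit.E_MPa,
                    "E_r_MPa": fit.E_r_MPa,
                    "F_adh_nN": fit.F_adh_nN,
                    "r_squared": fit.r_squared,
                    "ok": True,
                    "error": "",
                }
            )
        except ValueError as exc:  # logged, not fatal: failed pixels are normal
            log.warning("fit failed for %s: %s", cid, exc)
            rows.append(
                {
                    "curve_id": cid,
                    "image_id": image_id,
                    "E_MPa": np.nan,
                    "E_r_MPa": np.nan,
                    "F_adh_nN": np.nan,
                    "r_squared": np.nan,
                    "ok": False,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)


def _img_to_patient(study: Path) -> dict[str, str]:
    image_truth = io.read_table(study / "image_truth.csv")
    return dict(zip(image_truth["image_id"], image_truth["patient_id"]))


def run_morphometry(
    study_dir: str | Path, out_dir: str | Path, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every topography image; writes segments.csv and image_qc.csv."""
    config = config or PipelineConfig()
    study, out = Path(study_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    img_to_patient = _img_to_patient(study)

    seg_frames, qc_rows = [], []
    for tif in sorted((study / "images").glob("*.tif")):
        image = io.read_topography(tif)
        segments, qc = morphometry.analyze_image(image, config.morphometry)
        segments["patient_id"] = img_to_patient.get(image.id, "")
        seg_frames.append(segments)
        qc_rows.append({**dataclasses.asdict(qc), "patient_id": img_to_patient.get(image.id, "")})
    segments = pd.concat(seg_frames, ignore_index=True) if seg_frames else pd.DataFrame()
    qc = pd.DataFrame(qc_rows)
    io.write_table(segments, out / "segments.csv", seed=seed)
    io.write_table(qc, out / "image_qc.csv", seed=seed)
    return segments, qc


def run_nanomech(
    study_dir: str | Path, out_dir: str | Path, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, nanomech.CalibrationResult]:
    """Fit all force curves with calibration; writes dmt_fits.csv, image_modulus.csv."""
    config = config or PipelineConfig()
    study, out = Path(study_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    img_to_patient = _img_to_patient(study)

    fits = _fit_curves(io.read_table(study / "force_curves.csv"), config)
    ref_df = io.read_table(study / "reference_curves.csv")
    ref_df["image_id"] = "reference"
    ref_fits_df = _fit_curves(ref_df, config)
    ref_meta_path = study / "reference_meta.json"
    if not ref_meta_path.exists():
        raise FileNotFoundError(f"missing calibration sidecar: {ref_meta_path}")
    e_ref = json.loads(ref_meta_path.read_text())["E_ref_known_MPa"]
    ref_fits = [
        nanomech.DMTFit(
            E_r_MPa=r.E_r_MPa, E_MPa=r.E_MPa, F_adh_nN=r.F_adh_nN, R_nm=config.dmt.R_nm,
            nu=config.dmt.nu, r_squared=r.r_squared, fit_window=config.dmt.fit_window,
            n_points=0, curve_id=r.curve_id,
        )
        for r in ref_fits_df[ref_fits_df["ok"]].itertuples()
    ]
    calib = nanomech.calibrate(ref_fits, e_ref)
    fits["E_MPa_cal"] = fits["E_MPa"] * calib.scale_factor
    io.write_table(fits, out / "dmt_fits.csv", seed=seed)

    image_summary = (
        fits[fits["ok"]]
        .groupby("image_id")["E_MPa_cal"]
        .agg(mean_MPa="mean", sd_MPa="std", n_success="size")
        .reset_index()
    )
    image_summary["patient_id"] = image_summary["image_id"].map(img_to_patient)
    io.write_table(image_summary, out / "image_modulus.csv", seed=seed)
    return fits, image_summary, calib


def run_group_stats(
    study_dir: str | Path, out_dir: str | Path, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Aggregate per patient and run the group comparisons.

    Reads segments.csv, image_qc.csv and image_modulus.csv from ``out_dir``
    (the morphometry and nanomechanics stages must have run first); writes
    patient_summary.csv, group_tests.csv, distribution_tests.csv,
    correlation.json and subgroup_bins.csv. Returns the patient summary.
    """
    config = config or PipelineConfig()
    study, out = Path(study_dir), Path(out_dir)
    seed = config.seed
    patients = io.read_table(study / "patients.csv")
    segments = io.read_table(out / "segments.csv")
    qc = io.read_table(out / "image_qc.csv")
    image_summary = io.read_table(out / "image_modulus.csv")

    unusable_images = set(qc.loc[~qc["usable"], "image_id"]) if len(qc) else set()
    seg_ok = segments[~segments["image_id"].isin(unusable_images)] if len(segments) else segments
    diam = cohortstats.aggregate_per_patient(seg_ok, "diameter_nm", valid_col="valid")
    dper = cohortstats.aggregate_per_patient(seg_ok, "dperiod_nm", valid_col="valid")
    modulus = cohortstats.aggregate_per_patient(image_summary, "mean_MPa")

    measured = patients.set_index("patient_id").copy()
    measured["measured_modulus_MPa"] = modulus
    measured["measured_diameter_nm"] = diam
    measured["measured_dperiod_nm"] = dper
    measured = measured.reset_index()
    io.write_table(measured, out / "patient_summary.csv", seed=seed)

    # ---- group statistics ----------------------------------------------
    if min((measured["group"] == "low").sum(), (measured["group"] == "high").sum()) < 2:
        raise ValueError("group statistics need at least 2 patients per group")
    stats_df = cohortstats.compare_variables(
        measured.dropna(subset=["measured_modulus_MPa"]),
        ["measured_modulus_MPa", "measured_diameter_nm", "measured_dperiod_nm", "pwv_ms"],
        test="mann_whitney",
    )
    io.write_table(stats_df, out / "group_tests.csv", seed=seed)

    pooled_rows = []
    for var in ("diameter_nm", "dperiod_nm"):
        x = seg_ok.loc[
            seg_ok["valid"] & seg_ok["patient_id"].isin(measured.loc[measured["group"] == "low", "patient_id"]),
            var,
        ]
        y = seg_ok.loc[
            seg_ok["valid"] & seg_ok["patient_id"].isin(measured.loc[measured["group"] == "high", "patient_id"]),
            var,
        ]
        if len(x) >= 8 and len(y) >= 8:
            r = cohortstats.ks_two_sample(x, y, variable=var)
            pooled_rows.append({"variable": var, "D": r.statistic, "p_value": r.p_value})
    io.write_table(pd.DataFrame(pooled_rows), out / "distribution_tests.csv", seed=seed)

    rho, p_rho = cohortstats.spearman(
        measured.dropna(subset=["measured_modulus_MPa"])["pwv_ms"],
        measured.dropna(subset=["measured_modulus_MPa"])["measured_modulus_MPa"],
    )
    (out / "correlation.json").write_text(
        json.dumps({"spearman_rho_pwv_modulus": rho, "p_value": p_rho})
    )

    bin_frames = []
    for var, spec in (("diameter_nm", cohortstats.DIAMETER_BINS), ("dperiod_nm", cohortstats.DPERIOD_BINS)):
        for grp in ("low", "high"):
            vals = seg_ok.loc[
                seg_ok["valid"]
                & seg_ok["patient_id"].isin(measured.loc[measured["group"] == grp, "patient_id"]),
                var,
            ]
            tbl, n_out = cohortstats.bin_subgroups(vals, spec)
            tbl.insert(0, "variable", var)
            tbl.insert(1, "group", grp)
            tbl["n_out_of_range"] = n_out
            bin_frames.append(tbl)
    io.write_table(pd.concat(bin_frames, ignore_index=True), out / "subgroup_bins.csv", seed=seed)
    return measured


def run_integration(
    out_dir: str | Path, config: PipelineConfig | None = None
) -> tuple[integration.PCAResult, list[integration.GroupEllipse]]:
    """PCA over the patient summary; writes pca_scores/loadings/summary."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    seed = config.seed
    measured = io.read_table(out / "patient_summary.csv")

    variables = list(integration.DEFAULT_VARIABLES)
    matrix, excluded = integration.assemble_matrix(measured, variables)
    pca = integration.run_pca(matrix, n_components=2)
    groups = measured.set_index("patient_id").loc[matrix.index, "group"]
    if groups.value_counts().min() >= 3:
        ellipses = integration.group_ellipse(pca.scores.to_numpy(), groups.to_numpy())
    else:
        log.warning("group ellipses skipped: fewer than 3 complete patients in a group")
        ellipses = []
    io.write_table(pca.scores.reset_index(), out / "pca_scores.csv", seed=seed)
    io.write_table(pca.loadings.reset_index(names="variable"), out / "pca_loadings.csv", seed=seed)
    (out / "pca_summary.json").write_text(
        json.dumps(
            {
                "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
                "excluded_patients": excluded,
                "ellipses": [dataclasses.asdict(e) for e in ellipses],
            },
            indent=2,
        )
    )
    return pca, ellipses


def run_study(
    study_dir: str | Path, out_dir: str | Path, config: PipelineConfig | None = None
) -> Path:
    """Analyze a simulated (or equivalently laid out) study directory."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    run_morphometry(study_dir, out, config)
    run_nanomech(study_dir, out, config)
    run_group_stats(study_dir, out, config)
    run_integration(out, config)
    return out
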