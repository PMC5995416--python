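"""Simulate the full synthetic study to disk.

Writes a 17-patient cohort (8 low-PWV, 9 high-PWV) with 6 topography
images per patient (2 x 2 um, 256 px/line), DMT force curves per image,
reference-sample curves for modulus calibration, fibril ground truth and a
checksummed manifest under results/study/.
"""

import sys
from pathlib import Path

from advafm import pipeline
from advafm.config import PipelineConfig


def main(seed: int = 0) -> None:
    out = Path("results/study")
    cfg = PipelineConfig(seed=seed)
    pipeline.simulate_study(cfg, out, force=True)
    n_imgs = len(list((out / "images").glob("*.tif")))
    print(f"simulated cohort: {cfg.cohort.n_low} low + {cfg.cohort.n_high} high PWV patients")
    print(f"{n_imgs} topography images at {cfg.image_size_px} px, {cfg.nm_per_px:.4f} nm/px")
    print(f"study written to {out} (seed {seed})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
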