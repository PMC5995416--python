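"""Synthetic AFM data with ground truth.

Emulates the three data layers of an adventitia nanomechanics study:

* **Topography images** — 2 x 2 um, 256 px/line height fields of tightly
  packed, aligned, D-banded collagen fibrils.  Fibrils are half-cylinders
  (circular-segment cross-section) laid side by side, with an asymmetric
  axial height modulation: each D-period carries a raised-cosine gap zone of
  configurable depth occupying a fixed fraction of the period.
* **Force curves** — DMT force-indentation curves with adhesion, evaluated
  from the same contact law the fitting stage inverts.
* **Patient cohort** — a 17-patient study with a low and a high arterial
  stiffness (PWV) group: per-patient pulse wave velocity, clinical
  covariates, per-image elastic modulus means, fibril diameter / D-period
  populations, and seven SLRP protein abundances with a configurable
  down-regulation in the high-PWV group plus panel-level missingness.

Every generator takes an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nanomech
from ._rng import substream

__all__ = [
    "SLRP_NAMES",
    "FibrilFieldSpec",
    "TopographyImage",
    "CohortConfig",
    "Cohort",
    "fibril_apex_height",
    "render_fibril_image",
    "generate_force_curve",
    "generate_cohort",
    "low_pwv_field_spec",
    "high_pwv_field_spec",
]

SLRP_NAMES = (
    "decorin",
    "biglycan",
    "mimecan",
    "lumican",
    "prolargin",
    "podocan",
    "asporin",
)

#: Default scan geometry: 2000 nm / 256 px.
DEFAULT_NM_PER_PX = 2000.0 / 256.0


@dataclass
class FibrilFieldSpec:
    """Parameters of a rendered collagen fibril field.

    diameter distribution is a Gaussian mixture (means/SDs in nm, weights
    summing to 1); the D-period is a single Gaussian.  ``packing`` scales the
    centre-to-centre spacing of adjacent fibrils relative to the sum of their
    radii (1.0 = tangent half-cylinders, the tightly packed regime).
    """

    n_fibrils: int = 24
    diameter_means_nm: tuple[float, ...] = (101.5, 133.3, 165.7)
    diameter_sds_nm: tuple[float, ...] = (11.5, 8.5, 13.0)
    diameter_weights: tuple[float, ...] = (0.556, 0.309, 0.135)
    dperiod_mean_nm: float = 62.4
    dperiod_sd_nm: float = 3.0
    orientation_deg: float = 30.0
    orientation_jitter_deg: float = 10.0
    packing: float = 1.0
    band_depth_nm: float = 20.0
    gap_fraction: float = 0.25
    noise_sd_nm: float = 0.0
    tilt_nm_per_px: float = 0.0

    def validate(self) -> None:
        if self.n_fibrils < 1:
            raise ValueError("n_fibrils must be >= 1")
        w = np.asarray(self.diameter_weights, dtype=float)
        if not (
            len(self.diameter_means_nm)
            == len(self.diameter_sds_nm)
            == len(self.diameter_weights)
        ):
            raise ValueError("diameter mixture components must have equal lengths")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("diameter mixture weights must sum to 1")
        if np.any(np.asarray(self.diameter_sds_nm) < 0) or self.dperiod_sd_nm < 0:
            raise ValueError("SDs must be non-negative")
        for m in self.diameter_means_nm:
            if not 40.0 <= m <= 300.0:
                raise ValueError("diameter component means must lie in [40, 300] nm")
        if not 40.0 <= self.dperiod_mean_nm <= 90.0:
            raise ValueError("D-period mean must lie in [40, 90] nm")
        if self.packing < 1.0:
            raise ValueError("packing factor must be >= 1.0")
        if not 0.0 < self.gap_fraction < 1.0:
            raise ValueError("gap fraction must lie in (0, 1)")
        if self.band_depth_nm < 0 or self.noise_sd_nm < 0:
            raise ValueError("band depth and noise SD must be non-negative")


@dataclass
class TopographyImage:
    """A calibrated height field: heights in nm on a square pixel grid."""

    heights: np.ndarray
    nm_per_px: float
    scan_size_nm: float
    id: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        expected = self.nm_per_px * self.heights.shape[1]
        if abs(expected - self.scan_size_nm) > 1e-6 * self.scan_size_nm:
            raise ValueError("nm_per_px x pixels per line must equal scan_size_nm")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


def fibril_apex_height(diameter_nm: float) -> float:
    """Apex height of the half-cylindrical cross-section (= the radius)."""
    return diameter_nm / 2.0


def _band_profile(s_nm: np.ndarray, dperiod_nm: float, phase_nm: float, gap_fraction: float) -> np.ndarray:
    """Normalized gap-zone depth profile along the fibril axis.

    A raised-cosine pulse of total width ``gap_fraction * D`` centred at
    ``s = phase (mod D)``: 1 at the gap centre, 0 in the overlap zone, with
    smooth (fully tapered cosine) edges so the rendered image is
    thresholdable without staircase artefacts.
    """
    half_width = 0.5 * gap_fraction * dperiod_nm
    t = np.mod(s_nm - phase_nm + dperiod_nm / 2.0, dperiod_nm) - dperiod_nm / 2.0
    g = np.zeros_like(t)
    inside = np.abs(t) <= half_width
    g[inside] = 0.5 * (1.0 + np.cos(np.pi * t[inside] / half_width))
    return g


def _clip_line(
    px: float, py: float, ct: float, st: float, scan: float
) -> tuple[float, float, float, float] | None:
    """Clip the infinite line through (px, py) with direction (ct, st) to the
    [0, scan]^2 square; returns (x0, y0, x1, y1) in nm or None if outside."""
    t_lo, t_hi = -math.inf, math.inf
    for p, d in ((px, ct), (py, st)):
        if abs(d) < 1e-12:
            if not 0.0 <= p <= scan:
                return None
            continue
        t0, t1 = (0.0 - p) / d, (scan - p) / d
        if t0 > t1:
            t0, t1 = t1, t0
        t_lo, t_hi = max(t_lo, t0), min(t_hi, t1)
    if t_lo > t_hi:
        return None
    return (px + t_lo * ct, py + t_lo * st, px + t_hi * ct, py + t_hi * st)


def render_fibril_image(
    spec: FibrilFieldSpec,
    nm_per_px: float = DEFAULT_NM_PER_PX,
    size_px: int = 256,
    seed: int = 0,
) -> tuple[TopographyImage, pd.DataFrame]:
    """Render a field of parallel D-banded collagen fibrils.

    Returns the calibrated height image and a ground-truth table with one row
    per fibril (``fibril_id, diameter_nm, dperiod_nm, orientation_deg,
    offset_nm, phase_nm, visible, x0_px, y0_px, x1_px, y1_px``); the endpoint
    columns give the centreline clipped to the image for visible fibrils.

    Raises ``ValueError("empty field")`` if no fibril contributes any height
    at the requested size.
    """
    spec.validate()
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    rng = np.random.default_rng(seed)
    n = spec.n_fibrils

    comp = rng.choice(len(spec.diameter_weights), size=n, p=np.asarray(spec.diameter_weights))
    means = np.asarray(spec.diameter_means_nm)[comp]
    sds = np.asarray(spec.diameter_sds_nm)[comp]
    diameters = rng.normal(means, sds)
    diameters = np.clip(diameters, 20.0, None)
    dperiods = np.clip(rng.normal(spec.dperiod_mean_nm, spec.dperiod_sd_nm, size=n), 20.0, None)
    thetas = np.deg2rad(
        spec.orientation_deg
        + rng.uniform(-spec.orientation_jitter_deg, spec.orientation_jitter_deg, size=n)
    )
    phases = rng.uniform(0.0, dperiods)

    # centre-to-centre offsets perpendicular to the mean orientation
    radii = diameters / 2.0
    spacing = spec.packing * (radii[:-1] + radii[1:]) if n > 1 else np.array([])
    offsets = np.concatenate([[0.0], np.cumsum(spacing)])
    offsets -= offsets.mean()

    scan = nm_per_px * size_px
    cx = cy = scan / 2.0
    theta_mean = np.deg2rad(spec.orientation_deg)
    # perpendicular of the mean orientation
    nx, ny = -math.sin(theta_mean), math.cos(theta_mean)

    cols = np.arange(size_px) * nm_per_px
    rows = np.arange(size_px) * nm_per_px
    x, y = np.meshgrid(cols, rows)

    heights = np.zeros((size_px, size_px))
    half_diag = scan * math.sqrt(2.0) / 2.0
    visible = np.zeros(n, dtype=bool)
    endpoints = np.full((n, 4), np.nan)

    for i in range(n):
        px = cx + offsets[i] * nx
        py = cy + offsets[i] * ny
        ct, st = math.cos(thetas[i]), math.sin(thetas[i])
        # fast reject: centreline farther from the image centre than reach
        dist_centre = abs(-(cx - px) * st + (cy - py) * ct)
        if dist_centre > radii[i] + half_diag:
            continue
        u = -(x - px) * st + (y - py) * ct
        core = radii[i] ** 2 - u**2
        mask = core > 0
        if not np.any(mask):
            continue
        s = (x - px) * ct + (y - py) * st
        h = np.zeros_like(heights)
        h[mask] = np.sqrt(core[mask])
        g = _band_profile(s[mask], dperiods[i], phases[i], spec.gap_fraction)
        h[mask] = np.maximum(h[mask] - spec.band_depth_nm * g, 0.0)
        np.maximum(heights, h, out=heights)
        visible[i] = True
        seg = _clip_line(px, py, ct, st, scan)
        if seg is not None:
            endpoints[i] = [v / nm_per_px for v in seg]

    if heights.max() <= 0.0:
        raise ValueError("empty field")

    if spec.tilt_nm_per_px != 0.0:
        heights = heights + spec.tilt_nm_per_px * np.arange(size_px)[None, :]
    if spec.noise_sd_nm > 0.0:
        heights = heights + rng.normal(0.0, spec.noise_sd_nm, size=heights.shape)

    truth = pd.DataFrame(
        {
            "fibril_id": np.arange(n),
            "diameter_nm": diameters,
            "dperiod_nm": dperiods,
            "orientation_deg": np.rad2deg(thetas),
            "offset_nm": offsets,
            "phase_nm": phases,
            "visible": visible,
            "x0_px": endpoints[:, 0],
            "y0_px": endpoints[:, 1],
            "x1_px": endpoints[:, 2],
            "y1_px": endpoints[:, 3],
        }
    )
    image = TopographyImage(heights=heights, nm_per_px=nm_per_px, scan_size_nm=scan, id=f"synthetic-{seed}")
    return image, truth


def generate_force_curve(
    E_sample_MPa: float,
    nu: float = 0.0,
    R_nm: float = 8.0,
    F_adh_nN: float = 0.0,
    max_depth_nm: float = 10.0,
    n_points: int = 64,
    noise_sd_nN: float = 0.0,
    seed: int = 0,
    curve_id: str = "",
) -> nanomech.ForceCurve:
    """Forward-model a DMT force-indentation curve.

    F(delta) = F_adh + (4/3) E_r sqrt(R) delta^(3/2) with
    E_r = E_sample / (1 - nu^2) (rigid tip), plus optional Gaussian noise.
    """
    if E_sample_MPa <= 0 or R_nm <= 0:
        raise ValueError("modulus and tip radius must be positive")
    if not 0.0 <= nu < 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    depth = np.linspace(0.0, max_depth_nm, n_points)
    e_r = E_sample_MPa / (1.0 - nu**2)
    force = nanomech.dmt_force(depth, e_r, R_nm, F_adh_nN)
    if noise_sd_nN > 0:
        force = force + rng.normal(0.0, noise_sd_nN, size=force.shape)
    return nanomech.ForceCurve(depth_nm=depth, force_nN=force, curve_id=curve_id)


def low_pwv_field_spec(**overrides) -> FibrilFieldSpec:
    """Fibril field of the low-PWV group (three-component diameter mixture)."""
    return replace(FibrilFieldSpec(), **overrides)


def high_pwv_field_spec(**overrides) -> FibrilFieldSpec:
    """Fibril field of the high-PWV group: fewer thin fibrils, same scale."""
    base = FibrilFieldSpec(
        diameter_means_nm=(102.3, 133.1, 165.3),
        diameter_sds_nm=(11.1, 8.5, 12.2),
        diameter_weights=(0.514, 0.337, 0.149),
        dperiod_mean_nm=62.5,
    )
    return replace(base, **overrides)


# Clinical covariates: (low mean, low SD, high mean, high SD) for continuous
# variables; (low rate, high rate) for binary flags.
_CLINICAL_CONTINUOUS = {
    "age_y": (67.9, 10.7, 69.9, 7.0),
    "bmi": (26.5, 4.7, 28.4, 4.6),
    "systolic_bp_mmHg": (131.3, 18.7, 154.1, 28.6),
    "diastolic_bp_mmHg": (77.0, 10.7, 79.4, 12.3),
    "cholesterol_total_mmolL": (4.1, 0.5, 4.9, 1.5),
    "ldl_mmolL": (2.1, 0.5, 3.1, 1.3),
    "hdl_mmolL": (1.2, 0.1, 1.1, 0.3),
    "triglyceride_mmolL": (1.6, 0.6, 1.6, 0.5),
    "creatinine_mmolL": (89.8, 19.9, 91.6, 20.4),
    "hba1c": (0.06, 0.007, 0.06, 0.002),
}
_CLINICAL_BINARY = {
    "male": (0.875, 1.0),
    "diabetes": (0.125, 0.0),
    "hypertension": (0.50, 0.667),
    "smoking": (0.625, 0.889),
}


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the published study conditions: 8 low-PWV and 9
    high-PWV patients, PWV 8.5 +- 0.7 vs 13.4 +- 3.0 m/s, patient-mean
    elastic modulus 2159.3 +- 282.5 vs 2895.2 +- 414.4 MPa, 6 images per
    patient and ~460 fibril measurements per patient.  ``slrp_effect`` is the
    log2-fold shift of each SLRP protein in the high group (negative =
    down-regulated); ``missing_rate`` the fraction of patients whose whole
    proteomics panel is missing.
    """

    n_low: int = 8
    n_high: int = 9
    pwv_low: tuple[float, float] = (8.5, 0.7)
    pwv_high: tuple[float, float] = (13.4, 3.0)
    modulus_low: tuple[float, float] = (2159.3, 282.5)
    modulus_high: tuple[float, float] = (2895.2, 414.4)
    images_per_patient: int = 6
    measurements_per_image: int = 76
    within_patient_sd_frac: float = 0.5
    field_low: FibrilFieldSpec = field(default_factory=low_pwv_field_spec)
    field_high: FibrilFieldSpec = field(default_factory=high_pwv_field_spec)
    diameter_patient_sd_nm: float = 5.0
    dperiod_patient_sd_nm: float = 1.2
    slrp_effect: dict[str, float] = field(
        default_factory=lambda: {name: -0.5 for name in SLRP_NAMES}
    )
    slrp_baseline_log2: float = 20.0
    slrp_patient_sd_log2: float = 0.4
    missing_rate: float = 2.0 / 17.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_low < 1 or self.n_high < 1:
            raise ValueError("group sizes must be >= 1")
        if self.images_per_patient < 1 or self.measurements_per_image < 1:
            raise ValueError("image and measurement counts must be >= 1")
        for pair in (self.pwv_low, self.pwv_high, self.modulus_low, self.modulus_high):
            if pair[1] < 0:
                raise ValueError("SDs must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        self.field_low.validate()
        self.field_high.validate()


@dataclass
class Cohort:
    """A generated cohort: patient table, per-image moduli, fibril draws.

    ``patients`` has one row per patient (group, PWV, clinical covariates,
    true and realized mean modulus, SLRP abundances with NaN for missing
    panels); ``images`` one row per image (image-mean modulus); ``fibrils``
    one row per fibril measurement (diameter and D-period draws).
    """

    patients: pd.DataFrame
    images: pd.DataFrame
    fibrils: pd.DataFrame
    config: CohortConfig


def _draw_mixture(rng: np.random.Generator, spec: FibrilFieldSpec, n: int) -> np.ndarray:
    comp = rng.choice(len(spec.diameter_weights), size=n, p=np.asarray(spec.diameter_weights))
    means = np.asarray(spec.diameter_means_nm)[comp]
    sds = np.asarray(spec.diameter_sds_nm)[comp]
    return np.clip(rng.normal(means, sds), 20.0, None)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort from a :class:`CohortConfig`."""
    config = config or CohortConfig()
    config.validate()
    seed = config.seed

    patient_rows = []
    image_rows = []
    fibril_frames = []

    groups = ["low"] * config.n_low + ["high"] * config.n_high
    rng_missing = substream(seed, "missing")
    missing = rng_missing.random(len(groups)) < config.missing_rate

    for idx, group in enumerate(groups):
        pid = f"P{idx:03d}"
        rng = substream(seed, f"patient:{pid}")
        pwv_mu, pwv_sd = config.pwv_low if group == "low" else config.pwv_high
        mod_mu, mod_sd = config.modulus_low if group == "low" else config.modulus_high
        fspec = config.field_low if group == "low" else config.field_high

        pwv = max(rng.normal(pwv_mu, pwv_sd), 0.1)
        true_modulus = rng.normal(mod_mu, mod_sd)
        within_sd = config.within_patient_sd_frac * mod_sd
        image_means = rng.normal(true_modulus, within_sd, size=config.images_per_patient)
        for j, m in enumerate(image_means):
            image_rows.append(
                {"patient_id": pid, "image_id": f"{pid}-img{j}", "modulus_MPa": m}
            )

        n_meas = config.images_per_patient * config.measurements_per_image
        diam_shift = rng.normal(0.0, config.diameter_patient_sd_nm)
        dper_shift = rng.normal(0.0, config.dperiod_patient_sd_nm)
        diam = _draw_mixture(rng, fspec, n_meas) + diam_shift
        dper = (
            np.clip(rng.normal(fspec.dperiod_mean_nm, fspec.dperiod_sd_nm, size=n_meas), 20.0, None)
            + dper_shift
        )
        fibril_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "group": group,
                    "diameter_nm": diam,
                    "dperiod_nm": dper,
                }
            )
        )

        row = {
            "patient_id": pid,
            "group": group,
            "pwv_ms": pwv,
            "true_modulus_MPa": true_modulus,
            "mean_modulus_MPa": float(np.mean(image_means)),
            "mean_diameter_nm": float(np.mean(diam)),
            "mean_dperiod_nm": float(np.mean(dper)),
        }
        for name, (lmu, lsd, hmu, hsd) in _CLINICAL_CONTINUOUS.items():
            mu, sd = (lmu, lsd) if group == "low" else (hmu, hsd)
            row[name] = rng.normal(mu, sd)
        for name, (lp, hp) in _CLINICAL_BINARY.items():
            p = lp if group == "low" else hp
            row[name] = int(rng.random() < p)
        shift = 0.0
        for name in SLRP_NAMES:
            eff = config.slrp_effect.get(name, 0.0) if group == "high" else 0.0
            log2_ab = rng.normal(
                config.slrp_baseline_log2 + eff, config.slrp_patient_sd_log2
            )
            row[name] = np.nan if missing[idx] else float(2.0**log2_ab)
        patient_rows.append(row)

    patients = pd.DataFrame(patient_rows)
    images = pd.DataFrame(image_rows)
    fibrils = pd.concat(fibril_frames, ignore_index=True)
    return Cohort(patients=patients, images=images, fibrils=fibrils, config=config)
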