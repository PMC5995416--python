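"""PCA integration of proteomic, nanomechanical and clinical variables.

Assembles a patients x variables feature matrix (SLRP abundances, elastic
modulus, fibril diameter and D-period, PWV, age, BMI, cholesterol, HbA1c),
excludes patients with missing values, runs mean-centred unit-variance PCA,
and summarizes each patient group with a normal-theory concentration
ellipse (the "67% region") in the score plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "DEFAULT_VARIABLES",
    "GroupEllipse",
    "PCAResult",
    "assemble_matrix",
    "run_pca",
    "group_ellipse",
    "ellipse_contains",
]

from .synthetic import SLRP_NAMES

#: Default integration variable set: 7 SLRPs + nanomechanics + metadata.
DEFAULT_VARIABLES: tuple[str, ...] = SLRP_NAMES + (
    "mean_modulus_MPa",
    "mean_diameter_nm",
    "mean_dperiod_nm",
    "pwv_ms",
    "age_y",
    "bmi",
    "cholesterol_total_mmolL",
    "hba1c",
)


@dataclass
class GroupEllipse:
    """Normal-theory concentration ellipse of one group in the score plane."""

    group: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float
    level: float
    degenerate: bool = False


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a fitted PCA."""

    scores: pd.DataFrame  # patients x components
    loadings: pd.DataFrame  # variables x components
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray
    scale_: np.ndarray


def assemble_matrix(
    patients: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    drop_incomplete: bool = True,
    index_col: str = "patient_id",
) -> tuple[pd.DataFrame, list[str]]:
    """Build the feature matrix, excluding patients with any missing value.

    Returns the complete matrix (indexed by patient, columns in the order of
    ``variables``) and the list of excluded patient ids.
    """
    missing_cols = [v for v in variables if v not in patients.columns]
    if missing_cols:
        raise KeyError(f"variables not in patient table: {missing_cols}")
    mat = patients.set_index(index_col)[list(variables)].astype(float)
    if drop_incomplete:
        complete = mat.dropna()
        excluded = sorted(set(mat.index) - set(complete.index))
        mat = complete
    else:
        excluded = []
    if len(mat) < 3:
        raise ValueError("fewer than 3 complete patients after exclusion")
    return mat, excluded


def run_pca(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Mean-centred, unit-variance (sample SD, n-1) PCA via SVD.

    Loadings carry a deterministic sign convention: the largest-magnitude
    loading of each component is positive.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; assemble with exclusion")
    if n_components > min(len(matrix) - 1, matrix.shape[1]):
        raise ValueError("n_components exceeds the matrix rank bound")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(scale == 0)
    if zero_var.size:
        names = [matrix.columns[i] for i in zero_var]
        raise ValueError(f"zero-variance columns: {names}")
    z = (x - mean) / scale
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.T  # variables x components, orthonormal columns
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean_=mean,
        scale_=scale,
    )


def group_ellipse(
    scores: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    level: float = 0.67,
) -> list[GroupEllipse]:
    """Per-group bivariate-normal concentration ellipses in the score plane.

    The ellipse is centred on the group mean with axes from the sample
    covariance eigendecomposition scaled by the chi-square(2 df) quantile of
    ``level``; a singular covariance yields a degenerate (flagged) ellipse.
    """
    pts = np.asarray(scores, dtype=float)[:, :2]
    groups = np.asarray(groups)
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    r2 = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    out = []
    for g in pd.unique(groups):
        sel = pts[groups == g]
        if len(sel) < 3:
            raise ValueError(f"group {g!r} needs at least 3 points")
        center = sel.mean(axis=0)
        cov = np.cov(sel, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        degenerate = bool(np.min(evals) <= 0)
        evals = np.clip(evals, 0.0, None)
        # largest eigenvalue first for the major axis
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        semi = np.sqrt(evals * r2)
        angle = math.degrees(math.atan2(evecs[1, 0], evecs[0, 0])) % 180.0
        out.append(
            GroupEllipse(
                group=str(g),
                center=(float(center[0]), float(center[1])),
                semi_axes=(float(semi[0]), float(semi[1])),
                angle_deg=angle,
                level=level,
                degenerate=degenerate,
            )
        )
    return out


def ellipse_contains(points: np.ndarray, ellipse: GroupEllipse) -> np.ndarray:
    """Boolean mask of the points inside (or on) a group ellipse."""
    pts = np.asarray(points, dtype=float)[:, :2] - np.asarray(ellipse.center)
    t = math.radians(ellipse.angle_deg)
    rot = np.array([[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])
    local = pts @ rot.T
    a, b = ellipse.semi_axes
    if a == 0 or b == 0:
        return np.all(np.isclose(local, 0.0), axis=1)
    return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0
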