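"""Region time-series extraction and subject inclusion.

Implements the study's region-level preprocessing: a discrete-cosine
high-pass filter whose cutoff is twice the maximum stimulus repetition time
(read as twice the longest interval between consecutive onsets of the same
stimulus condition), an OLS activation test for the faces-versus-rest
contrast, the inclusion rule (every region must show p < .05 activation
with a local maximum within 14 mm of the group maximum), and first-
eigenvariate extraction from a sphere of voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task_design import TaskDesign

__all__ = [
    "RegionFocus",
    "RegionAssessment",
    "EigenvariateSeries",
    "stimulus_repetition_cutoff_s",
    "highpass_filter",
    "glm_activation",
    "subject_included",
    "extract_eigenvariate",
]

MAX_FOCUS_DISTANCE_MM = 14.0
_T_CAP = 1e6  # reported in place of an infinite t on a perfect fit


@dataclass(frozen=True)
class RegionFocus:
    """A region's group maximum and a subject's local maximum (mm, MNI)."""

    region: str
    group_max_mm: tuple[float, float, float]
    subject_max_mm: tuple[float, float, float]

    @property
    def distance_mm(self) -> float:
        a = np.asarray(self.group_max_mm, dtype=float)
        b = np.asarray(self.subject_max_mm, dtype=float)
        return float(np.linalg.norm(a - b))


@dataclass(frozen=True)
class RegionAssessment:
    """Inclusion evidence for one region: locality plus activation."""

    focus: RegionFocus
    t: float
    p: float


@dataclass(frozen=True)
class EigenvariateSeries:
    """First-eigenvariate summary of a voxel sphere."""

    values: np.ndarray
    explained_variance: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not (0.0 < self.explained_variance <= 1.0 + 1e-12):
            raise ValueError("explained variance must lie in (0, 1]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("eigenvariate contains non-finite values")


def stimulus_repetition_cutoff_s(design: TaskDesign) -> float:
    """Twice the longest interval between consecutive same-condition onsets.

    Stimulus conditions are the face blocks (N, H, S, F); rest is not a
    stimulus. Conditions occurring once contribute no interval.
    """
    onsets = design.block_onsets()
    longest = 0.0
    for letter in "NHSF":
        idx = design.blocks_of(letter)
        if len(idx) >= 2:
            gaps = np.diff(onsets[idx])
            longest = max(longest, float(gaps.max()))
    if longest == 0.0:
        raise ValueError("no repeated stimulus condition; cutoff undefined")
    return 2.0 * longest


def _dct_basis(n: int, n_components: int) -> np.ndarray:
    """Unit-norm discrete-cosine regressors k = 1..n_components."""
    t = np.arange(n)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n)) * np.sqrt(2.0 / n)
        for k in range(1, n_components + 1)
    ]
    return np.column_stack(cols) if cols else np.zeros((n, 0))


def highpass_filter(
    series: np.ndarray, design: TaskDesign, cutoff_s: float | None = None
) -> np.ndarray:
    """Remove the mean and all DCT components with period above the cutoff.

    The cutoff defaults to :func:`stimulus_repetition_cutoff_s`. Output is
    zero-mean. Works on 1-D series or T x k column stacks.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    duration = n * design.tr_s
    if cutoff_s is None:
        cutoff_s = stimulus_repetition_cutoff_s(design)
    if cutoff_s < 2.0 * design.tr_s:
        raise ValueError(
            f"cutoff {cutoff_s:g} s is below the Nyquist period {2 * design.tr_s:g} s"
        )
    n_comp = int(np.floor(2.0 * duration / cutoff_s))
    X = _dct_basis(n, n_comp)
    centered = series - series.mean(axis=0)
    return centered - X @ (X.T @ centered)


def glm_activation(
    series: np.ndarray,
    regressors: np.ndarray,
    contrast: np.ndarray | None = None,
) -> tuple[float, float]:
    """OLS t statistic for a contrast over task regressors.

    An intercept column is appended. The default contrast averages all
    task-regressor betas (faces versus rest/baseline). Returns ``(t, p)``
    with a one-column-per-regressor design; a perfect fit reports the
    capped maximal t.
    """
    y = np.asarray(series, dtype=float)
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    k = X.shape[1]
    X = np.column_stack([X, np.ones(X.shape[0])])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if contrast is None:
        contrast = np.full(k, 1.0 / k)
    c = np.concatenate([np.asarray(contrast, dtype=float), [0.0]])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    denom2 = sigma2 * float(c @ xtx_inv @ c)
    effect = float(c @ beta)
    if denom2 <= np.finfo(float).tiny * max(1.0, effect**2):
        t = np.sign(effect) * _T_CAP if effect != 0 else 0.0
    else:
        t = effect / np.sqrt(denom2)
        t = float(np.clip(t, -_T_CAP, _T_CAP))
    p = float(stats.t.sf(t, dof))  # one-sided: activation means positive effect
    return t, p


def subject_included(
    assessments: dict[str, RegionAssessment],
    alpha: float = 0.05,
    max_distance_mm: float = MAX_FOCUS_DISTANCE_MM,
    required_regions: tuple[str, ...] = ("V1", "FG", "AMY", "OFC"),
) -> tuple[bool, dict[str, str]]:
    """Apply the inclusion rule across all four regions.

    A subject is included iff every region passes both the activation test
    (p < alpha) and the locality rule (local maximum within 14 mm of the
    group maximum). Returns ``(included, reasons)`` where ``reasons`` names
    each failing region and why.
    """
    missing = [r for r in required_regions if r not in assessments]
    if missing:
        raise ValueError(f"missing region assessment(s): {missing}")
    reasons: dict[str, str] = {}
    for region in required_regions:
        a = assessments[region]
        if not (a.p < alpha):
            reasons[region] = f"no significant activation (p = {a.p:.3g} >= {alpha})"
        elif a.focus.distance_mm > max_distance_mm:
            reasons[region] = (
                f"local maximum {a.focus.distance_mm:.1f} mm from group maximum "
                f"(limit {max_distance_mm:g} mm)"
            )
    return (len(reasons) == 0), reasons


def extract_eigenvariate(
    patch,
    center_mm: tuple[float, float, float],
    radius_mm: float,
) -> EigenvariateSeries:
    """First eigenvariate of all voxels within a sphere of the patch.

    The sphere is the closed ball over voxel centers. Columns are centered;
    the first right-singular direction of the time-by-voxel matrix is
    scaled so its standard deviation equals the mean voxel standard
    deviation, with sign fixed by positive correlation with the sphere-mean
    series.
    """
    coords = patch.voxel_coordinates_mm().reshape(-1, 3)
    nt = patch.data.shape[-1]
    Y_all = patch.data.reshape(-1, nt).T  # time x voxel
    d = np.linalg.norm(coords - np.asarray(center_mm, dtype=float), axis=1)
    mask = d <= radius_mm + 1e-9
    if not mask.any():
        raise ValueError(
            f"no voxels within {radius_mm:g} mm of {tuple(center_mm)} "
        )
    Y = Y_all[:, mask]
    Yc = Y - Y.mean(axis=0)
    U, S, _ = np.linalg.svd(Yc, full_matrices=False)
    total = float((S**2).sum())
    if total == 0:
        raise ValueError("sphere contains only constant voxels")
    ev = U[:, 0]
    mean_series = Yc.mean(axis=1)
    if float(ev @ mean_series) < 0:
        ev = -ev
    voxel_sd = Yc.std(axis=0).mean()
    ev_sd = ev.std()
    if ev_sd > 0:
        ev = ev * (voxel_sd / ev_sd)
    return EigenvariateSeries(
        values=ev,
        explained_variance=float(S[0] ** 2) / total,
        n_voxels=int(mask.sum()),
    )
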