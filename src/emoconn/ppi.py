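"""Psychophysiological-interaction (PPI) connectivity analysis.

A PPI regression asks whether the coupling between a seed region (here the
right amygdala) and a target changes with the task context. The interaction
regressor is the elementwise product of the seed time series and a
psychological vector coding the contrast (+1 on the emotion's blocks, -1 on
neutral blocks, 0 elsewhere); the interaction beta is estimated by OLS while
partialling the physiological and psychological main effects and nuisance
drift. Group comparison is a two-sample t test per target with Bonferroni
family-wise correction over the composite FG + OFC target set, and the
symptom analysis correlates rMDD betas with MADRS-like scores.

The seed series is used directly as the "neuronal" series (the extracted
eigenvariate); an optional Wiener deconvolution by the canonical HRF is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .generative_model import legendre_drift_basis
from .roi_extract import EigenvariateSeries
from .task_design import TaskDesign, canonical_hrf

__all__ = [
    "PPIDesign",
    "PPIGroupResult",
    "psychological_vector",
    "build_ppi_design",
    "fit_ppi",
    "group_compare",
    "symptom_correlation",
    "deconvolve_seed",
]

CONTRASTS = {"happy-neutral": "H", "sad-neutral": "S", "fear-neutral": "F"}


@dataclass(frozen=True)
class PPIDesign:
    """Regressors for one subject's PPI GLM."""

    seed: np.ndarray
    psychological: np.ndarray
    interaction: np.ndarray
    nuisance: np.ndarray
    contrast: str

    def __post_init__(self) -> None:
        for name in ("seed", "psychological", "interaction"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} regressor contains non-finite values")
        if not np.array_equal(self.interaction, self.seed * self.psychological):
            raise ValueError("interaction must equal seed * psychological exactly")


@dataclass
class PPIGroupResult:
    """Second-level PPI outcome over targets."""

    targets: list[str]
    group_a: str
    group_b: str
    mean_difference: dict[str, float]
    t: dict[str, float]
    p_raw: dict[str, float]
    p_corrected: dict[str, float]
    significant: dict[str, bool]
    direction: dict[str, str]
    correction: str = "bonferroni"
    symptom_r: dict[str, float] = field(default_factory=dict)
    symptom_p: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.p_raw, self.p_corrected):
            for t, p in d.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"p value for {t} outside [0, 1]")


def psychological_vector(design: TaskDesign, contrast: str) -> np.ndarray:
    """+1 on the contrast emotion's blocks, -1 on neutral, 0 elsewhere,
    at volume resolution."""
    if contrast not in CONTRASTS:
        raise ValueError(
            f"unknown contrast {contrast!r}; expected one of {sorted(CONTRASTS)}"
        )
    letter = CONTRASTS[contrast]
    psych = np.zeros(design.n_volumes)
    for vol, t in enumerate(design.volume_times()):
        cond = design.condition_at(t)
        if cond == letter:
            psych[vol] = 1.0
        elif cond == "N":
            psych[vol] = -1.0
    return psych


def build_ppi_design(
    seed: EigenvariateSeries | np.ndarray,
    design: TaskDesign,
    contrast: str,
    drift_order: int = 2,
) -> PPIDesign:
    """Assemble the PPI regressors for one subject."""
    values = seed.values if isinstance(seed, EigenvariateSeries) else np.asarray(seed, dtype=float)
    if values.shape[0] != design.n_volumes:
        raise ValueError("seed length does not match the design's volume count")
    psych = psychological_vector(design, contrast)
    nuisance = legendre_drift_basis(design.n_volumes, drift_order)
    return PPIDesign(
        seed=values,
        psychological=psych,
        interaction=values * psych,
        nuisance=nuisance,
        contrast=contrast,
    )


def fit_ppi(target: np.ndarray, ppi: PPIDesign) -> tuple[float, float]:
    """OLS interaction beta and t for one target series.

    The physiological and psychological main effects and the nuisance
    columns are partialled out.
    """
    y = np.asarray(target, dtype=float)
    X = np.column_stack([ppi.interaction, ppi.seed, ppi.psychological, ppi.nuisance])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("PPI design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    var_b = sigma2 * np.linalg.inv(X.T @ X)[0, 0]
    t = beta[0] / np.sqrt(var_b) if var_b > 0 else np.sign(beta[0]) * np.inf
    return float(beta[0]), float(t)


def group_compare(
    betas_by_group: dict[str, pd.DataFrame],
    targets: tuple[str, ...] = ("FG", "OFC"),
    alpha: float = 0.05,
    symptom_scores: dict[str, np.ndarray] | None = None,
    symptom_group: str | None = None,
) -> PPIGroupResult:
    """Two-sample comparison of interaction betas per target.

    ``betas_by_group`` maps group label to a subjects-by-targets frame.
    Family-wise error is controlled by Bonferroni over the composite target
    set. If symptom scores are supplied, the named group's betas are
    correlated with them per target.
    """
    if len(betas_by_group) != 2:
        raise ValueError("exactly two groups are required")
    (ga, da), (gb, db) = betas_by_group.items()
    for g, d in betas_by_group.items():
        if len(d) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    mean_diff, tstat, p_raw, p_corr, sig, direction = {}, {}, {}, {}, {}, {}
    m = len(targets)
    for target in targets:
        a = da[target].to_numpy(dtype=float)
        b = db[target].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b)
        mean_diff[target] = float(a.mean() - b.mean())
        tstat[target] = float(t)
        p_raw[target] = float(p)
        p_corr[target] = float(min(1.0, p * m))
        sig[target] = p_corr[target] < alpha
        direction[target] = f"{ga} > {gb}" if mean_diff[target] > 0 else f"{gb} > {ga}"
    result = PPIGroupResult(
        targets=list(targets),
        group_a=ga,
        group_b=gb,
        mean_difference=mean_diff,
        t=tstat,
        p_raw=p_raw,
        p_corrected=p_corr,
        significant=sig,
        direction=direction,
    )
    if symptom_scores is not None and symptom_group is not None:
        betas = betas_by_group[symptom_group]
        scores = np.asarray(symptom_scores[symptom_group], dtype=float)
        r, p = symptom_correlation(betas, scores, targets)
        result.symptom_r = r
        result.symptom_p = p
    return result


def symptom_correlation(
    betas: pd.DataFrame,
    scores: np.ndarray,
    targets: tuple[str, ...] = ("FG", "OFC"),
) -> tuple[dict[str, float], dict[str, float]]:
    """Pearson correlation (with exact t-based p) of betas with scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if np.allclose(scores.std(), 0.0):
        raise ValueError("symptom scores have zero variance")
    r_out, p_out = {}, {}
    for target in targets:
        res = stats.pearsonr(betas[target].to_numpy(dtype=float), scores)
        r_out[target] = float(res.statistic)
        p_out[target] = float(res.pvalue)
    return r_out, p_out


def deconvolve_seed(
    seed: np.ndarray, design: TaskDesign, regularization: float = 0.1
) -> np.ndarray:
    """Optional Wiener deconvolution of a BOLD seed by the canonical HRF.

    Returns an approximate underlying activity series at volume resolution;
    the default PPI path uses the extracted series directly.
    """
    seed = np.asarray(seed, dtype=float)
    n = seed.size
    h = canonical_hrf(design.tr_s)
    H = np.fft.rfft(h, n=n)
    Y = np.fft.rfft(seed - seed.mean(), n=n)
    power = np.abs(H) ** 2
    X = Y * np.conj(H) / (power + regularization * power.max())
    return np.fft.irfft(X, n=n)
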