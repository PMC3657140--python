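"""Group-level Bayesian model selection over models and families.

Per-subject free energies approximate log model evidence; the default
fixed-effects (FFX) group evidence sums them over subjects. Model posteriors
are a stable softmax of log prior + group log evidence. Family inference
assigns each family a uniform prior split equally among its members — so a
large family is not favored merely by size — sums member posteriors into
family posteriors, picks the winning family, and renormalizes within it to
pick the winning model. A random-effects (RFX) alternative estimates a
hierarchical Dirichlet over model frequencies by the standard variational
update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, logsumexp

__all__ = [
    "EvidenceTable",
    "BMSResult",
    "group_log_evidence",
    "model_posteriors",
    "family_inference",
    "bayes_factor_interpretation",
]


@dataclass
class EvidenceTable:
    """Subjects-by-models free energies (nats) plus the family map."""

    free_energy: np.ndarray
    subject_ids: list[str]
    model_ids: list[int]
    families: dict[int, int]

    def __post_init__(self) -> None:
        F = np.asarray(self.free_energy, dtype=float)
        if F.shape != (len(self.subject_ids), len(self.model_ids)):
            raise ValueError("free_energy must be subjects x models")
        self.free_energy = F
        missing = set(self.model_ids) - set(self.families)
        if missing:
            raise ValueError(f"models without family assignment: {sorted(missing)}")
        bad = np.argwhere(~np.isfinite(F))
        if bad.size:
            s, m = bad[0]
            raise ValueError(
                f"missing/non-finite evidence for subject {self.subject_ids[s]!r}, "
                f"model {self.model_ids[m]}"
            )


@dataclass
class BMSResult:
    """Group BMS outcome: model and family posteriors plus winners."""

    model_ids: list[int]
    group_log_evidence: np.ndarray
    model_posterior: np.ndarray
    family_ids: list[int]
    family_posterior: np.ndarray
    winning_family: int
    winning_model: int
    within_family_posterior: dict[int, float]
    method: str = "ffx"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.model_posterior.sum() - 1.0) > 1e-10:
            raise ValueError("model posteriors must sum to 1")
        if abs(self.family_posterior.sum() - 1.0) > 1e-10:
            raise ValueError("family posteriors must sum to 1")


def group_log_evidence(table: EvidenceTable) -> np.ndarray:
    """Fixed-effects group log evidence: the per-model sum over subjects."""
    return table.free_energy.sum(axis=0)


def model_posteriors(group_le: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Stable softmax of log prior + group log evidence."""
    group_le = np.asarray(group_le, dtype=float)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != group_le.shape:
        raise ValueError("prior and evidences must have matching shapes")
    if np.any(prior < 0) or prior.sum() <= 0:
        raise ValueError("prior must be non-negative and sum to a positive value")
    if not np.isclose(prior.sum(), 1.0):
        raise ValueError("prior must sum to 1")
    with np.errstate(divide="ignore"):
        logp = np.log(prior) + group_le
    return np.exp(logp - logsumexp(logp))


def _family_partition(model_ids: list[int], families: dict[int, int]):
    fam_ids = sorted(set(families[m] for m in model_ids))
    members = {f: [i for i, m in enumerate(model_ids) if families[m] == f] for f in fam_ids}
    counted = sum(len(v) for v in members.values())
    if counted != len(model_ids):
        raise ValueError("families do not partition the models")
    return fam_ids, members


def family_inference(
    table: EvidenceTable,
    family_prior: dict[int, float] | None = None,
    method: str = "ffx",
) -> BMSResult:
    """Family-level BMS with equal within-family prior splitting.

    ``family_prior`` maps family id to prior mass (default uniform over
    families). With ``method="rfx"`` model probabilities come from the
    variational Dirichlet estimate of model frequencies instead of the FFX
    softmax; family probabilities still sum member probabilities.
    """
    fam_ids, members = _family_partition(table.model_ids, table.families)
    if family_prior is None:
        family_prior = {f: 1.0 / len(fam_ids) for f in fam_ids}
    if set(family_prior) != set(fam_ids):
        raise ValueError("family_prior keys must match the family ids")
    total = sum(family_prior.values())
    if total <= 0:
        raise ValueError("family prior mass must be positive")
    model_prior = np.zeros(len(table.model_ids))
    for f in fam_ids:
        for i in members[f]:
            model_prior[i] = family_prior[f] / (total * len(members[f]))

    group_le = group_log_evidence(table)
    if method == "ffx":
        post = model_posteriors(group_le, model_prior)
        extras = {}
    elif method == "rfx":
        alpha = _rfx_dirichlet(table.free_energy, alpha0=model_prior * len(table.model_ids))
        post = alpha / alpha.sum()
        extras = {"dirichlet_alpha": alpha}
    else:
        raise ValueError(f"unknown method {method!r}")

    fam_post = np.array([post[members[f]].sum() for f in fam_ids])
    win_f = fam_ids[int(np.argmax(fam_post))]
    within = post[members[win_f]]
    within = within / within.sum()
    within_map = {
        table.model_ids[i]: float(w) for i, w in zip(members[win_f], within)
    }
    win_m = table.model_ids[members[win_f][int(np.argmax(within))]]
    return BMSResult(
        model_ids=list(table.model_ids),
        group_log_evidence=group_le,
        model_posterior=post,
        family_ids=fam_ids,
        family_posterior=fam_post,
        winning_family=win_f,
        winning_model=win_m,
        within_family_posterior=within_map,
        method=method,
        extras=extras,
    )


def _rfx_dirichlet(F: np.ndarray, alpha0: np.ndarray, max_iter: int = 256) -> np.ndarray:
    """Variational update for the Dirichlet over model frequencies."""
    alpha = alpha0.astype(float).copy()
    for _ in range(max_iter):
        logu = F + (digamma(alpha) - digamma(alpha.sum()))
        u = np.exp(logu - logsumexp(logu, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < 1e-6:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha


def bayes_factor_interpretation(delta_log_evidence: float) -> str:
    """Evidence category for a log-evidence difference (nats).

    Thresholds (closed lower bounds): 1.1 -> positive, 3 -> strong,
    5 -> very strong; below 1.1 -> weak.
    """
    d = float(delta_log_evidence)
    if d >= 5.0:
        return "very strong"
    if d >= 3.0:
        return "strong"
    if d >= 1.1:
        return "positive"
    return "weak"
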