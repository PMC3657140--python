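"""End-to-end orchestration: simulate -> include -> fit -> BMS -> PPI -> report.

A :class:`RunConfig` fixes the design, the two cohorts, inversion and BMS
settings and a master seed; :func:`run_all` executes the stages in order,
caching the expensive per-subject evidence tables as CSV artifacts that are
reloaded (and integrity-checked) on resume. The four group-by-emotion BMS
runs and the PPI group decisions are summarized in a :class:`RunReport`
whose markdown table mirrors the group x emotion x winning-family/model
layout of the study's selection analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .bms import BMSResult, EvidenceTable, family_inference
from .generative_model import legendre_drift_basis
from .inversion import PriorSpec, invert
from .model_space import (
    build_modulatory_space,
    family_map,
    to_dcm_spec,
    winner_structural_model,
)
from .ppi import build_ppi_design, fit_ppi, group_compare
from .roi_extract import (
    RegionAssessment,
    RegionFocus,
    glm_activation,
    subject_included,
)
from .synthetic_data import CohortSpec, SubjectRecord, make_cohorts
from .task_design import (
    PAPER_BLOCK_ORDER,
    build_glm_regressors,
    canonical_hrf,
    parse_block_order,
)

__all__ = ["RunConfig", "RunReport", "ProvenanceError", "run_all", "make_report"]

log = logging.getLogger("emoconn")

#: Group-maximum coordinates used as fixed region labels (mm, MNI).
REGION_FOCI = {
    "V1": (18.0, -95.0, 0.0),
    "FG": (42.0, -60.0, -15.0),
    "AMY": (25.0, -4.0, -15.0),
    "OFC": (28.0, 32.0, -15.0),
}


class ProvenanceError(RuntimeError):
    """A cached artifact does not match its recorded digest."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    block_order: str = PAPER_BLOCK_ORDER
    block_s: float = 21.0
    tr_s: float = 2.1
    n_volumes: int = 218
    microtime_bins_per_tr: int = 16
    n_hc: int = 21
    n_rmdd: int = 22
    snr: float = 1.0
    weak_ofc_fraction: float = 0.25
    emotions: tuple[str, ...] = ("happy", "sad")
    inversion_max_iter: int = 64
    inversion_bins: int = 8
    nuisance_other_emotions: bool = True
    drift_order: int = 2
    bms_method: str = "ffx"
    ppi_alpha: float = 0.05
    inclusion_alpha: float = 0.05
    out_dir: str = "runs/default"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.emotions, list):
            self.emotions = tuple(self.emotions)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["emotions"] = list(self.emotions)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    @property
    def config_hash(self) -> str:
        doc = asdict(self)
        doc["emotions"] = list(self.emotions)
        doc.pop("out_dir")  # location does not affect the computation
        payload = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def design(self):
        return parse_block_order(
            self.block_order,
            self.block_s,
            tr_s=self.tr_s,
            n_volumes=self.n_volumes,
            microtime_bins_per_tr=self.microtime_bins_per_tr,
        )

    def cohorts(self) -> tuple[CohortSpec, CohortSpec]:
        seeds = np.random.SeedSequence(self.master_seed).generate_state(2) % (2**31)
        if seeds[0] == seeds[1]:
            seeds[1] += 1
        hc = CohortSpec(
            group="HC", n_subjects=self.n_hc,
            truth_by_emotion={"happy": 5, "sad": 21},
            seed=int(seeds[0]), snr=self.snr,
            weak_ofc_fraction=self.weak_ofc_fraction, madrs_sigma=1.5,
        )
        rmdd = CohortSpec(
            group="rMDD", n_subjects=self.n_rmdd,
            truth_by_emotion={"happy": 21, "sad": 2},
            seed=int(seeds[1]), snr=self.snr,
            weak_ofc_fraction=self.weak_ofc_fraction, madrs_sigma=3.5,
        )
        return hc, rmdd


@dataclass
class RunReport:
    """Summary of one end-to-end run."""

    selections: dict[str, dict]
    retention: dict[str, dict]
    ppi: dict[str, dict]
    caveats: list[str]
    provenance: dict[str, str]

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_markdown(self) -> str:
        lines = [
            "| Group | Emotion | Winning family | Winning model | Family posterior | Model posterior |",
            "|---|---|---|---|---|---|",
        ]
        for key in sorted(self.selections):
            s = self.selections[key]
            group, emotion = key.split("/")
            lines.append(
                f"| {group} | {emotion} | F{s['winning_family']} | "
                f"Model {s['winning_model']} | {s['family_posterior']:.3f} | "
                f"{s['model_posterior']:.3f} |"
            )
        lines.append("")
        for group, r in sorted(self.retention.items()):
            lines.append(f"- {group}: {r['included']} of {r['total']} subjects included")
        for emotion, p in sorted(self.ppi.items()):
            for target, sig in p["significant"].items():
                mark = "significant" if sig else "n.s."
                lines.append(
                    f"- PPI {emotion}, amygdala->{target}: {p['direction'][target]} ({mark})"
                )
        for c in self.caveats:
            lines.append(f"- caveat: {c}")
        lines.append(f"- provenance: config {self.provenance['config_hash']}, "
                     f"emoconn {self.provenance['version']}")
        return "\n".join(lines)

    @property
    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


# -- stage helpers ----------------------------------------------------------


def assess_subjects(
    records: list[SubjectRecord], config: RunConfig
) -> tuple[list[SubjectRecord], int]:
    """Apply the activation inclusion rule; returns (included, total)."""
    design = records[0].design
    hrf = canonical_hrf(design.tr_s / design.microtime_bins_per_tr)
    regressors = build_glm_regressors(design, hrf)
    drift = legendre_drift_basis(design.n_volumes, config.drift_order)[:, 1:]
    X = np.column_stack([regressors.to_numpy(), drift])
    contrast = np.concatenate(
        [np.full(regressors.shape[1], 1.0 / regressors.shape[1]), np.zeros(drift.shape[1])]
    )
    included = []
    for rec in records:
        assessments = {}
        for region in rec.bold.regions:
            t, p = glm_activation(rec.bold.series(region), X, contrast)
            focus = RegionFocus(
                region=region,
                group_max_mm=REGION_FOCI[region],
                subject_max_mm=REGION_FOCI[region],
            )
            assessments[region] = RegionAssessment(focus=focus, t=t, p=p)
        ok, reasons = subject_included(assessments, alpha=config.inclusion_alpha)
        if ok:
            included.append(rec)
        else:
            log.info("excluded %s: %s", rec.subject_id, reasons)
    return included, len(records)


def fit_evidence_table(
    records: list[SubjectRecord],
    emotion: str,
    config: RunConfig,
) -> EvidenceTable:
    """Fit all 21 modulatory models to every subject for one emotion.

    By default every other analysed emotion enters each candidate DCM as a
    free nuisance modulator on all six candidate edges — identical across
    the 21 candidates, so evidence differences reflect only the emotion of
    interest. (Leaving the other emotion unmodelled biases selection toward
    the wrong single-edge models.)

    The free-energy landscape is multimodal, and a stalled fit understates
    a model's evidence enough to corrupt comparison. Candidates are
    therefore fitted up the model lattice with dual initialization: an
    unmodulated null model first, then the 21 candidates in order of
    increasing edge count, each fitted twice — once cold from the prior
    mean and once warm from the posterior of its best-fitting strict
    subset (falling back to the null) — keeping the better optimum. The
    protocol is identical for every candidate.
    """
    from .model_space import MODULATORY_EDGES

    winner = winner_structural_model()
    models = build_modulatory_space()
    design = records[0].design
    priors = PriorSpec()
    extra = {}
    if config.nuisance_other_emotions:
        extra = {
            other: frozenset(MODULATORY_EDGES)
            for other in config.emotions
            if other != emotion
        }
    invert_kw = dict(
        microtime_bins=config.inversion_bins,
        max_iter=config.inversion_max_iter,
        drift_order=config.drift_order,
    )
    lattice_order = sorted(models, key=lambda m: (len(m.modulated_edges), m.id))
    F = np.zeros((len(records), len(models)))
    col = {m.id: i for i, m in enumerate(models)}
    for si, rec in enumerate(records):
        null_spec = to_dcm_spec(winner, None, extra_modulators=extra)
        null = invert(null_spec, rec.bold, design, priors, **invert_kw)
        fitted: dict[int, tuple[frozenset, object]] = {}
        for model in lattice_order:
            init, best_f = null.posterior, null.free_energy
            for edges2, res2 in fitted.values():
                if edges2 < model.modulated_edges and res2.free_energy > best_f:
                    init, best_f = res2.posterior, res2.free_energy
            spec = to_dcm_spec(winner, model, emotion, extra_modulators=extra)
            res_warm = invert(
                spec, rec.bold, design, priors, theta_init=init, **invert_kw
            )
            res_cold = invert(spec, rec.bold, design, priors, **invert_kw)
            res = res_warm if res_warm.free_energy >= res_cold.free_energy else res_cold
            fitted[model.id] = (model.modulated_edges, res)
            F[si, col[model.id]] = res.free_energy
        log.info(
            "fitted %s/%s emotion=%s (config %s)",
            rec.group, rec.subject_id, emotion, config.config_hash,
        )
    return EvidenceTable(
        free_energy=F,
        subject_ids=[r.subject_id for r in records],
        model_ids=[m.id for m in models],
        families=family_map(models),
    )


def _evidence_paths(out_dir: Path, group: str, emotion: str) -> tuple[Path, Path]:
    base = out_dir / "evidences"
    return base / f"{group}_{emotion}.csv", base / f"{group}_{emotion}.meta.json"


def save_evidence(table: EvidenceTable, csv_path: Path, meta_path: Path, config_hash: str) -> None:
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for si, sid in enumerate(table.subject_ids):
        for mi, mid in enumerate(table.model_ids):
            rows.append({"subject_id": sid, "model_id": mid,
                         "free_energy": table.free_energy[si, mi]})
    # %.17g round-trips float64 exactly, keeping cached reruns bit-identical
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.17g")
    digest = hashlib.sha256(csv_path.read_bytes()).hexdigest()
    meta_path.write_text(json.dumps({"config_hash": config_hash, "sha256": digest}))


def load_evidence(csv_path: Path, meta_path: Path, config_hash: str) -> EvidenceTable | None:
    """Load a cached evidence table; None if absent or from another config.

    Raises :class:`ProvenanceError` if the file does not match its digest.
    """
    if not (csv_path.exists() and meta_path.exists()):
        return None
    meta = json.loads(meta_path.read_text())
    if meta.get("config_hash") != config_hash:
        return None
    digest = hashlib.sha256(csv_path.read_bytes()).hexdigest()
    if digest != meta.get("sha256"):
        raise ProvenanceError(
            f"evidence file {csv_path} does not match its recorded digest"
        )
    df = pd.read_csv(csv_path, float_precision="round_trip")
    wide = df.pivot(index="subject_id", columns="model_id", values="free_energy")
    model_ids = [int(m) for m in wide.columns]
    return EvidenceTable(
        free_energy=wide.to_numpy(),
        subject_ids=[str(s) for s in wide.index],
        model_ids=model_ids,
        families={k: v for k, v in family_map().items() if k in set(model_ids)},
    )


def ppi_stage(
    included: dict[str, list[SubjectRecord]], config: RunConfig
) -> dict[str, dict]:
    """Amygdala-seed PPI per emotion with group comparison and symptom
    correlation in the rMDD group."""
    out = {}
    for emotion in config.emotions:
        contrast = f"{emotion}-neutral"
        betas_by_group: dict[str, pd.DataFrame] = {}
        scores: dict[str, np.ndarray] = {}
        for group, recs in included.items():
            rows = []
            for rec in recs:
                design = rec.design
                ppi = build_ppi_design(rec.bold.series("AMY"), design, contrast,
                                       drift_order=config.drift_order)
                row = {}
                for target in ("FG", "OFC"):
                    beta, _ = fit_ppi(rec.bold.series(target), ppi)
                    row[target] = beta
                rows.append(row)
            betas_by_group[group] = pd.DataFrame(rows)
            scores[group] = np.array([r.symptom_score for r in recs])
        can_correlate = (
            "rMDD" in scores
            and scores["rMDD"].size >= 3
            and scores["rMDD"].std() > 0
        )
        result = group_compare(
            betas_by_group,
            alpha=config.ppi_alpha,
            symptom_scores=scores if can_correlate else None,
            symptom_group="rMDD" if can_correlate else None,
        )
        out[emotion] = {
            "mean_difference": result.mean_difference,
            "t": result.t,
            "p_corrected": result.p_corrected,
            "significant": result.significant,
            "direction": result.direction,
            "symptom_r": result.symptom_r,
            "symptom_p": result.symptom_p,
        }
    return out


# -- the orchestrator -------------------------------------------------------


def run_all(config: RunConfig, resume: bool = True) -> RunReport:
    """Execute every stage; identical config + seed gives an identical report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = config.design()
    hc, rmdd = config.cohorts()
    log.info("stage=simulate seed=%s config=%s", config.master_seed, config.config_hash)
    records, manifest = make_cohorts(hc, rmdd, design, out_dir=out_dir / "data")

    included: dict[str, list[SubjectRecord]] = {}
    retention = {}
    for group, recs in records.items():
        inc, total = assess_subjects(recs, config)
        if len(inc) < 2:
            raise RuntimeError(f"stage=include group={group}: fewer than 2 subjects retained")
        included[group] = inc
        retention[group] = {"included": len(inc), "total": total}
        log.info("stage=include group=%s retained=%d/%d", group, len(inc), total)

    bms_results: dict[str, BMSResult] = {}
    evidence_tables: dict[str, EvidenceTable] = {}
    for group, recs in included.items():
        for emotion in config.emotions:
            key = f"{group}/{emotion}"
            csv_path, meta_path = _evidence_paths(out_dir, group, emotion)
            table = load_evidence(csv_path, meta_path, config.config_hash) if resume else None
            if table is None:
                log.info("stage=fit cell=%s n=%d models=21", key, len(recs))
                try:
                    table = fit_evidence_table(recs, emotion, config)
                except Exception as exc:
                    raise RuntimeError(f"stage=fit cell={key} failed: {exc}") from exc
                save_evidence(table, csv_path, meta_path, config.config_hash)
            evidence_tables[key] = table
            bms_results[key] = family_inference(table, method=config.bms_method)

    ppi = ppi_stage(included, config)

    artifacts = {
        "config": config,
        "bms": bms_results,
        "retention": retention,
        "ppi": ppi,
        "included": included,
    }
    report = make_report(artifacts)
    report.to_json(out_dir / "report.json")
    (out_dir / "report.md").write_text(report.to_markdown() + "\n")
    config.to_yaml(out_dir / "config.yaml")
    return report


def make_report(artifacts: dict) -> RunReport:
    """Assemble the run report from stage artifacts (all must be present)."""
    for name in ("config", "bms", "retention", "ppi"):
        if name not in artifacts:
            raise ValueError(f"missing artifact {name!r}")
    config: RunConfig = artifacts["config"]
    selections = {}
    for key, res in artifacts["bms"].items():
        fam_idx = res.family_ids.index(res.winning_family)
        selections[key] = {
            "winning_family": res.winning_family,
            "winning_model": res.winning_model,
            "family_posterior": float(res.family_posterior[fam_idx]),
            "model_posterior": float(res.within_family_posterior[res.winning_model]),
        }
    caveats = []
    for group, r in artifacts["retention"].items():
        if r["included"] < 5:
            caveats.append(
                f"group {group} retains only {r['included']} subjects; "
                "selection results are unstable at this size"
            )
    return RunReport(
        selections=selections,
        retention=artifacts["retention"],
        ppi=artifacts["ppi"],
        caveats=caveats,
        provenance={
            "config_hash": config.config_hash,
            "version": _pkg_version,
            "master_seed": str(config.master_seed),
        },
    )
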