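"""Synthetic two-cohort BOLD datasets with a group-by-valence reversal.

The generator emulates the study conditions: a healthy-control (HC) cohort
of ~21 subjects and a remitted-depression (rMDD) cohort of ~22 subjects,
each scanned on the published block design. Ground truth encodes the
reversal: in HC, happy faces modulate only the backward OFC->FG connection
(model 5) while sad faces modulate OFC<->AMY and OFC<->FG bidirectionally
(model 21); in rMDD the pattern reverses (happy -> model 21, sad -> the
forward FG->OFC model 2). Subject-level coupling parameters are drawn from
population Gaussians truncated to dynamical stability; observation noise,
low-frequency drift, and MADRS-like symptom scores complete each record.

A configurable fraction of subjects gets an attenuated OFC response so the
activation-based inclusion rule has real work, mirroring the study's
retention of 21/29 controls and 22/30 patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .generative_model import (
    BoldTimeSeries,
    DCMParameters,
    DCMSpec,
    check_stability,
    integrate_and_sample,
    _input_matrix,
)
from .model_space import build_modulatory_space, to_dcm_spec, winner_structural_model
from .task_design import PAPER_BLOCK_ORDER, TaskDesign, build_inputs, parse_block_order

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "RoiPatch",
    "PatchGeometry",
    "default_cohorts",
    "sample_subject",
    "make_cohorts",
    "render_patch",
]


#: Default population means for the intrinsic couplings (Hz). Forward
#: (up-hierarchy) connections are excitatory, feedback inhibitory, and the
#: magnitudes are heterogeneous: symmetric means would make the AMY and OFC
#: time courses nearly collinear and the source region of a modulated
#: afferent unidentifiable.
DEFAULT_EDGE_MEANS: dict[tuple[str, str], float] = {
    ("V1", "FG"): 0.40,
    ("FG", "V1"): -0.15,
    ("FG", "AMY"): 0.35,
    ("AMY", "FG"): -0.25,
    ("FG", "OFC"): 0.20,
    ("OFC", "FG"): -0.45,
    ("AMY", "OFC"): 0.35,
    ("OFC", "AMY"): -0.30,
}

#: Default self-inhibition means (Hz): the amygdala is fast and transient,
#: the OFC a slower integrator, so their within-block waveforms differ and a
#: modulated afferent can be attributed to its source region.
DEFAULT_SELF_MEANS: dict[str, float] = {
    "V1": -0.6,
    "FG": -0.5,
    "AMY": -0.9,
    "OFC": -0.35,
}


@dataclass(frozen=True)
class CohortSpec:
    """Population description of one cohort.

    ``truth_by_emotion`` maps emotion name to the id of the modulatory model
    (1..21) that is ground truth for that cohort. Population means/SDs are
    coupling rates in Hz; ``snr`` is std(noiseless signal) / noise SD.
    ``edge_means`` overrides the per-edge intrinsic means (defaults to
    :data:`DEFAULT_EDGE_MEANS`; edges absent from the map fall back to
    ``a_mean`` for forward and ``a_feedback_mean`` for feedback connections).
    """

    group: str
    n_subjects: int
    truth_by_emotion: dict[str, int]
    seed: int
    a_mean: float = 0.3
    a_feedback_mean: float = -0.3
    self_mean: float = -0.5
    c_mean: float = 0.8
    b_mean: float = 0.7
    b_backward_mean: float = 0.5
    between_sd: float = 0.1
    snr: float = 1.0
    weak_ofc_fraction: float = 0.25
    madrs_sigma: float = 1.5
    drift_amplitude: float = 0.3
    edge_means: dict[tuple[str, str], float] | None = None
    self_means: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        valid_ids = {m.id for m in build_modulatory_space()}
        for emotion, mid in self.truth_by_emotion.items():
            if mid not in valid_ids:
                raise ValueError(
                    f"truth for {emotion!r} (model {mid}) is not in the model space"
                )


def default_cohorts(
    seed: int = 0, *, n_hc: int = 21, n_rmdd: int = 22, snr: float = 1.0,
    weak_ofc_fraction: float = 0.25,
) -> tuple[CohortSpec, CohortSpec]:
    """The study-default cohorts: HC happy->5 / sad->21, rMDD happy->21 / sad->2."""
    hc = CohortSpec(
        group="HC",
        n_subjects=n_hc,
        truth_by_emotion={"happy": 5, "sad": 21},
        seed=seed * 2 + 1,
        snr=snr,
        weak_ofc_fraction=weak_ofc_fraction,
        madrs_sigma=1.5,
    )
    rmdd = CohortSpec(
        group="rMDD",
        n_subjects=n_rmdd,
        truth_by_emotion={"happy": 21, "sad": 2},
        seed=seed * 2 + 2,
        snr=snr,
        weak_ofc_fraction=weak_ofc_fraction,
        madrs_sigma=3.5,
    )
    return hc, rmdd


@dataclass
class SubjectRecord:
    """One simulated subject: data, design, labels, and retained truth."""

    subject_id: str
    group: str
    bold: BoldTimeSeries
    design: TaskDesign
    symptom_score: float
    true_params: DCMParameters
    weak_ofc: bool = False

    def __post_init__(self) -> None:
        if self.bold.n_volumes != self.design.n_volumes:
            raise ValueError("time series length does not match design")
        if self.symptom_score < 0:
            raise ValueError("symptom score must be >= 0")


def _generative_spec(truth_by_emotion: dict[str, int]) -> DCMSpec:
    """Fully connected winner architecture with one modulator per emotion."""
    winner = winner_structural_model()
    models = {m.id: m for m in build_modulatory_space()}
    extra = {
        emotion: models[mid].modulated_edges
        for emotion, mid in truth_by_emotion.items()
    }
    return to_dcm_spec(winner, None, extra_modulators=extra)


def _subject_rng(cohort: CohortSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cohort.seed, spawn_key=(subject_index,))
    )


def sample_subject(
    cohort: CohortSpec,
    design: TaskDesign,
    subject_index: int,
    rng: np.random.Generator | None = None,
) -> SubjectRecord:
    """Draw one subject's parameters (truncated to stability) and simulate.

    Deterministic given ``(cohort.seed, subject_index)`` unless an explicit
    ``rng`` is supplied. Raises after 100 stability rejections.
    """
    rng = _subject_rng(cohort, subject_index) if rng is None else rng
    spec = _generative_spec(cohort.truth_by_emotion)
    n = spec.n_regions
    inputs = build_inputs(design)
    n_bins = design.n_volumes * design.microtime_bins_per_tr
    u_all = _input_matrix(spec, inputs, n_bins)

    weak_ofc = bool(rng.random() < cohort.weak_ofc_fraction)
    ofc = spec.index("OFC")
    a_mask = spec.a_mask(include_diagonal=False)
    sd = cohort.between_sd
    # forward (up-hierarchy) connections are excitatory, feedback inhibitory;
    # the resulting near-skew coupling keeps the fully connected network stable
    rank = {r: i for i, r in enumerate(spec.regions)}
    edge_means = DEFAULT_EDGE_MEANS if cohort.edge_means is None else cohort.edge_means
    self_means = DEFAULT_SELF_MEANS if cohort.self_means is None else cohort.self_means
    a_means = np.zeros((n, n))
    for src, dst in spec.intrinsic_edges:
        fallback = cohort.a_mean if rank[dst] > rank[src] else cohort.a_feedback_mean
        mean = edge_means.get((src, dst), fallback)
        a_means[spec.index(dst), spec.index(src)] = mean
    self_mean_vec = np.array(
        [self_means.get(r, cohort.self_mean) for r in spec.regions]
    )

    params = None
    for attempt in range(100):
        A = np.zeros((n, n))
        A[a_mask] = rng.normal(a_means[a_mask], sd)
        diag = rng.normal(self_mean_vec, sd)
        np.fill_diagonal(A, np.minimum(diag, -0.1))
        if weak_ofc:
            off = np.arange(n) != ofc
            A[ofc, off] *= 0.1
        B = {}
        for name in spec.modulator_names:
            bmat = np.zeros((n, n))
            for src, dst in sorted(spec.modulated_edges[name]):
                mean = cohort.b_mean if rank[dst] > rank[src] else cohort.b_backward_mean
                bmat[spec.index(dst), spec.index(src)] = rng.normal(mean, sd)
            B[name] = bmat
        C = np.zeros((n, len(spec.driving_names)))
        C[spec.c_mask()] = rng.normal(cohort.c_mean, sd, size=int(spec.c_mask().sum()))
        candidate = DCMParameters(spec=spec, A=A, B=B, C=C)
        try:
            check_stability(candidate, u_all)
        except ValueError:
            continue
        params = candidate
        break
    if params is None:
        raise RuntimeError(
            f"no stable coupling parameters after 100 draws for "
            f"{cohort.group} subject {subject_index}"
        )

    noiseless = integrate_and_sample(spec, params, inputs, design)
    signal_sd = float(noiseless.data.std())
    params.noise_sd = signal_sd / cohort.snr
    drift = np.zeros((3, n))
    drift[1:, :] = rng.normal(0.0, cohort.drift_amplitude * signal_sd, size=(2, n))
    params.drift_coeffs = drift
    bold = integrate_and_sample(spec, params, inputs, design, rng=rng)
    score = float(abs(rng.normal(0.0, cohort.madrs_sigma)))
    return SubjectRecord(
        subject_id=f"{cohort.group}{subject_index:02d}",
        group=cohort.group,
        bold=bold,
        design=design,
        symptom_score=score,
        true_params=params,
        weak_ofc=weak_ofc,
    )


def make_cohorts(
    hc: CohortSpec,
    rmdd: CohortSpec,
    design: TaskDesign | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, list[SubjectRecord]], pd.DataFrame]:
    """Simulate both cohorts; optionally write per-subject TSVs + manifest.

    Returns ``(records_by_group, manifest)``. The manifest (subject_id,
    group, seed, subject_index, madrs_like) suffices to regenerate every
    series bit-for-bit via :func:`sample_subject`.
    """
    if hc.seed == rmdd.seed:
        raise ValueError("cohorts must use distinct seeds")
    design = parse_block_order(PAPER_BLOCK_ORDER) if design is None else design
    records: dict[str, list[SubjectRecord]] = {}
    rows = []
    seen_ids: set[str] = set()
    for cohort in (hc, rmdd):
        recs = [sample_subject(cohort, design, i) for i in range(cohort.n_subjects)]
        for i, rec in enumerate(recs):
            if rec.subject_id in seen_ids:
                raise ValueError(f"duplicate subject id {rec.subject_id!r}")
            seen_ids.add(rec.subject_id)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "seed": cohort.seed,
                    "subject_index": i,
                    "madrs_like": rec.symptom_score,
                }
            )
        records[cohort.group] = recs
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        for recs in records.values():
            for rec in recs:
                rec.bold.to_frame().to_csv(
                    out_dir / f"{rec.subject_id}.tsv", sep="\t", index=False
                )
    return records, manifest


# -- voxel patches for the ROI / PPI stages ---------------------------------


@dataclass(frozen=True)
class PatchGeometry:
    """Geometry of a rendered voxel patch around a region focus."""

    shape: tuple[int, int, int] = (7, 7, 5)
    voxel_size_mm: tuple[float, float, float] = (3.5, 3.5, 5.0)
    kernel_fwhm_mm: float = 8.0
    voxel_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        extent = [s * v for s, v in zip(self.shape, self.voxel_size_mm)]
        if min(extent) < 12.0:
            raise ValueError(
                "patch extent must cover the 6-mm extraction sphere "
                f"(got {extent} mm)"
            )


@dataclass
class RoiPatch:
    """A small 4-D neighborhood (x, y, z, t) around one region's focus.

    Voxel (i, j, k) sits at ``(ijk - focus_index) * voxel_size + focus_mm``
    in mm coordinates (MNI axis convention).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    focus_index: tuple[int, int, int]
    focus_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tr_s: float = 2.1

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("patch data must be 4-D (x, y, z, t)")

    def voxel_coordinates_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center mm coordinates."""
        nx, ny, nz, _ = self.data.shape
        grid = np.stack(
            np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"),
            axis=-1,
        ).astype(float)
        offset = grid - np.asarray(self.focus_index, dtype=float)
        return offset * np.asarray(self.voxel_size_mm) + np.asarray(self.focus_mm)

    def to_nifti(self, path) -> None:
        """Optional NIfTI-1 export (requires nibabel)."""
        import nibabel as nib

        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        affine[:3, 3] = -np.asarray(self.focus_index) * np.asarray(
            self.voxel_size_mm
        ) + np.asarray(self.focus_mm)
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))


def render_patch(
    subject: SubjectRecord,
    region: str,
    geometry: PatchGeometry = PatchGeometry(),
    rng: np.random.Generator | None = None,
    focus_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> RoiPatch:
    """Render a voxel patch whose signal is the region series times a
    spatial Gaussian loading (maximal at the focus voxel) plus i.i.d. noise.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    series = subject.bold.series(region)
    focus_index = tuple(s // 2 for s in geometry.shape)
    patch = RoiPatch(
        data=np.zeros(geometry.shape + (series.size,)),
        voxel_size_mm=geometry.voxel_size_mm,
        focus_index=focus_index,
        focus_mm=focus_mm,
        tr_s=subject.bold.tr_s,
    )
    coords = patch.voxel_coordinates_mm()
    d2 = ((coords - np.asarray(focus_mm)) ** 2).sum(axis=-1)
    if geometry.kernel_fwhm_mm <= 0:
        loading = (d2 == 0.0).astype(float)
    else:
        sigma = geometry.kernel_fwhm_mm / np.sqrt(8.0 * np.log(2.0))
        loading = np.exp(-d2 / (2.0 * sigma**2))
    data = loading[..., None] * series[None, None, None, :]
    if geometry.voxel_noise_sd > 0:
        data = data + rng.normal(0.0, geometry.voxel_noise_sd, size=data.shape)
    patch.data = data
    return patch
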