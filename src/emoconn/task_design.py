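"""Block-design parsing and regressor construction for the emotional-faces task.

The task is a block design over five conditions — neutral (N), happy (H),
sad (S), fearful (F) faces and rest/fixation (R) — presented in a fixed
pseudorandom order of 21-s blocks, six 3-s faces with a 500-ms gap per block.
This module turns the order string into a timed :class:`TaskDesign`, builds
the boxcar input functions that drive the neural model (an all-faces driving
input plus one modulator per emotion), and convolves them with a hemodynamic
response function to form GLM regressors at the volume sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "CONDITION_NAMES",
    "PAPER_BLOCK_ORDER",
    "ACQUIRED_VOLUMES",
    "TaskDesign",
    "InputFunctions",
    "parse_block_order",
    "build_inputs",
    "build_glm_regressors",
    "canonical_hrf",
    "events_table",
    "design_from_events",
]

#: Condition letter -> condition name. R is rest (fixation), not a stimulus.
CONDITION_NAMES = {
    "N": "neutral",
    "H": "happy",
    "S": "sad",
    "F": "fear",
    "R": "rest",
}
_NAME_TO_LETTER = {v: k for k, v in CONDITION_NAMES.items()}

#: The study's published block order: 22 blocks, 462 s.
PAPER_BLOCK_ORDER = "NHNSNFNRSNHNFNRFNSNHNR"

#: EPI volumes acquired in the study (457.8 s at TR = 2.1 s); the final
#: partial rest block is truncated at sampling.
ACQUIRED_VOLUMES = 218


@dataclass(frozen=True)
class TaskDesign:
    """A timed block design plus its sampling parameters.

    Parameters
    ----------
    block_order
        String over {N, H, S, F, R}, one letter per block.
    block_s, stim_s, gap_s
        Block length and per-face stimulus/gap durations (seconds).
    faces_per_block
        Number of faces per block; ``faces_per_block * (stim_s + gap_s)``
        must equal ``block_s``.
    tr_s
        Volume repetition time (seconds).
    n_volumes
        Number of sampled volumes. May truncate the task (the study
        acquired 218 volumes against a 462-s design).
    microtime_bins_per_tr
        Resolution of the microtime grid used for integration and
        convolution.
    """

    block_order: str
    block_s: float = 21.0
    stim_s: float = 3.0
    gap_s: float = 0.5
    faces_per_block: int = 6
    tr_s: float = 2.1
    n_volumes: int = ACQUIRED_VOLUMES
    microtime_bins_per_tr: int = 16

    def __post_init__(self) -> None:
        for pos, ch in enumerate(self.block_order):
            if ch not in CONDITION_NAMES:
                raise ValueError(
                    f"invalid block-order character {ch!r} at position {pos}"
                )
        if not self.block_order:
            raise ValueError("block_order must be non-empty")
        if not np.isclose(self.faces_per_block * (self.stim_s + self.gap_s), self.block_s):
            raise ValueError(
                "faces_per_block * (stim_s + gap_s) must equal block_s; got "
                f"{self.faces_per_block} * ({self.stim_s} + {self.gap_s}) != {self.block_s}"
            )
        if self.tr_s <= 0 or self.n_volumes <= 0:
            raise ValueError("tr_s and n_volumes must be positive")
        if self.microtime_bins_per_tr <= 0:
            raise ValueError("microtime_bins_per_tr must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def n_blocks(self) -> int:
        return len(self.block_order)

    @property
    def total_duration_s(self) -> float:
        """Task duration (may exceed the sampled duration)."""
        return self.n_blocks * self.block_s

    @property
    def sampled_duration_s(self) -> float:
        return self.n_volumes * self.tr_s

    @property
    def condition_counts(self) -> dict[str, int]:
        """Block count per condition letter (zero-count letters included)."""
        return {c: self.block_order.count(c) for c in CONDITION_NAMES}

    def block_onsets(self) -> np.ndarray:
        return np.arange(self.n_blocks) * self.block_s

    def blocks_of(self, condition: str) -> list[int]:
        """0-based block indices of a condition letter or name."""
        letter = _NAME_TO_LETTER.get(condition, condition)
        if letter not in CONDITION_NAMES:
            raise ValueError(f"unknown condition {condition!r}")
        return [i for i, c in enumerate(self.block_order) if c == letter]

    def condition_at(self, t_s: float) -> str | None:
        """Condition letter of the block covering time ``t_s``, or None."""
        if t_s < 0 or t_s >= self.total_duration_s:
            return None
        return self.block_order[int(t_s // self.block_s)]

    def volume_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s

    def with_full_coverage(self) -> "TaskDesign":
        """Variant sampling the whole task (e.g. 220 volumes for the
        published design instead of the 218 acquired)."""
        n = int(np.floor(self.total_duration_s / self.tr_s + 1e-9))
        return replace(self, n_volumes=n)


def parse_block_order(
    order: str,
    block_s: float = 21.0,
    *,
    tr_s: float = 2.1,
    n_volumes: int | None = None,
    full_coverage: bool = False,
    microtime_bins_per_tr: int = 16,
    stim_s: float = 3.0,
    gap_s: float = 0.5,
    faces_per_block: int = 6,
) -> TaskDesign:
    """Parse a block-order string into a :class:`TaskDesign`.

    When ``n_volumes`` is not given it defaults to the lesser of the number
    of whole TRs covering the task and the 218 volumes the study acquired;
    ``full_coverage=True`` instead samples every whole TR of the task.
    """
    if not order:
        raise ValueError("block_order must be non-empty")
    if n_volumes is None:
        covering = int(np.floor(len(order) * block_s / tr_s + 1e-9))
        n_volumes = covering if full_coverage else min(ACQUIRED_VOLUMES, covering)
    return TaskDesign(
        block_order=order,
        block_s=block_s,
        stim_s=stim_s,
        gap_s=gap_s,
        faces_per_block=faces_per_block,
        tr_s=tr_s,
        n_volumes=n_volumes,
        microtime_bins_per_tr=microtime_bins_per_tr,
    )


@dataclass(frozen=True)
class InputFunctions:
    """Boxcar input functions on the microtime grid.

    ``faces`` is the all-faces driving input (active on every non-rest
    block); ``happy``, ``sad``, ``fear`` and ``neutral`` are per-condition
    boxcars. All values are in {0, 1}. ``faces`` equals the elementwise
    maximum of the four condition boxcars.
    """

    time_axis: np.ndarray
    faces: np.ndarray
    happy: np.ndarray
    sad: np.ndarray
    fear: np.ndarray
    neutral: np.ndarray
    dt_s: float

    def by_name(self, name: str) -> np.ndarray:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown input function {name!r}") from None

    @property
    def n_bins(self) -> int:
        return self.time_axis.size


def build_inputs(design: TaskDesign) -> InputFunctions:
    """Build microtime boxcars for the driving input and each emotion.

    The grid covers the sampled duration (``n_volumes`` TRs) at
    ``tr_s / microtime_bins_per_tr`` resolution; bins beyond the end of the
    task (if any) are zero.
    """
    bins = design.microtime_bins_per_tr
    if bins <= 0:
        raise ValueError("microtime_bins_per_tr must be positive")
    dt = design.tr_s / bins
    n_bins = design.n_volumes * bins
    t = np.arange(n_bins) * dt

    box = {letter: np.zeros(n_bins) for letter in "NHSF"}
    in_task = t < design.total_duration_s
    block_idx = np.minimum((t // design.block_s).astype(int), design.n_blocks - 1)
    letters = np.array(list(design.block_order))
    cond = letters[block_idx]
    for letter in "NHSF":
        box[letter][(cond == letter) & in_task] = 1.0
    faces = np.maximum.reduce([box["N"], box["H"], box["S"], box["F"]])
    return InputFunctions(
        time_axis=t,
        faces=faces,
        happy=box["H"],
        sad=box["S"],
        fear=box["F"],
        neutral=box["N"],
        dt_s=dt,
    )


def canonical_hrf(dt_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response on a ``dt_s`` grid.

    Peak at ~6 s, undershoot at ~16 s with 1:6 amplitude ratio; scaled to
    unit peak. Units are per-bin (discrete convolution weights).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, duration_s, dt_s)
    h = _gamma_dist.pdf(t, 6.0) - _gamma_dist.pdf(t, 16.0) / 6.0
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate hrf")
    return h / peak


def build_glm_regressors(
    design: TaskDesign,
    hrf: np.ndarray,
    conditions: tuple[str, ...] = ("neutral", "happy", "sad", "fear"),
) -> pd.DataFrame:
    """Condition boxcars convolved with ``hrf`` and sampled at TR.

    ``hrf`` must be sampled on the design's microtime grid (its first
    element is applied at zero lag, so a single-sample ``[1.0]`` kernel
    returns the down-sampled boxcars unchanged). Returns a DataFrame with
    one column per condition and ``n_volumes`` rows.
    """
    hrf = np.asarray(hrf, dtype=float)
    if hrf.size < 1:
        raise ValueError("hrf must contain at least one bin")
    inputs = build_inputs(design)
    bins = design.microtime_bins_per_tr
    cols = {}
    for name in conditions:
        u = inputs.by_name(name)
        conv = np.convolve(u, hrf)[: u.size]
        cols[name] = conv[::bins][: design.n_volumes]
    out = pd.DataFrame(cols, index=design.volume_times())
    out.index.name = "time_s"
    if not np.all(np.isfinite(out.to_numpy())):
        raise ValueError("non-finite regressor values")
    return out


# -- events-table serialization (BIDS-style three-column TSV) ---------------


def events_table(design: TaskDesign) -> pd.DataFrame:
    """Events table with onset, duration, trial_type (seconds, 0-based)."""
    return pd.DataFrame(
        {
            "onset": design.block_onsets(),
            "duration": np.full(design.n_blocks, design.block_s),
            "trial_type": [CONDITION_NAMES[c] for c in design.block_order],
        }
    )


def design_from_events(
    events: pd.DataFrame,
    *,
    tr_s: float = 2.1,
    n_volumes: int | None = None,
    microtime_bins_per_tr: int = 16,
    stim_s: float = 3.0,
    gap_s: float = 0.5,
    faces_per_block: int | None = None,
) -> TaskDesign:
    """Rebuild a :class:`TaskDesign` from an events table.

    The table must describe contiguous equal-length blocks starting at 0.
    Exact round trip: ``design_from_events(events_table(d), ...) == d``.
    """
    ev = events.sort_values("onset").reset_index(drop=True)
    durations = ev["duration"].to_numpy(dtype=float)
    onsets = ev["onset"].to_numpy(dtype=float)
    if len(ev) == 0:
        raise ValueError("empty events table")
    block_s = float(durations[0])
    if not np.allclose(durations, block_s):
        raise ValueError("events do not form equal-length blocks")
    if not np.allclose(onsets, np.arange(len(ev)) * block_s):
        raise ValueError("events are not contiguous from onset 0")
    try:
        order = "".join(_NAME_TO_LETTER[t] for t in ev["trial_type"])
    except KeyError as exc:
        raise ValueError(f"unknown trial_type {exc.args[0]!r}") from None
    if faces_per_block is None:
        faces_per_block = int(round(block_s / (stim_s + gap_s)))
    return parse_block_order(
        order,
        block_s,
        tr_s=tr_s,
        n_volumes=n_volumes,
        microtime_bins_per_tr=microtime_bins_per_tr,
        stim_s=stim_s,
        gap_s=gap_s,
        faces_per_block=faces_per_block,
    )
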