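"""EMG envelope extraction, amplitude normalization and coactivation indices.

The processing chain mirrors standard surface-EMG practice for synergy
analysis: zero-phase 4th-order Butterworth high-pass at 50 Hz, full-wave
rectification, zero-phase 4th-order low-pass at 20 Hz; amplitude
normalization either to the per-direction maximum (for envelope/coactivation
comparisons) or per-trial min-max to [0, 1] (for factorization); each lunge
cycle time-normalized to 200 points, 50 for the swing and 150 for the stance
phase, then concatenated into the muscles-by-time matrix V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import LungeCycle
from .filters import butter_zero_phase
from . import muscles as M

logger = logging.getLogger(__name__)

SWING_POINTS = 50
STANCE_POINTS = 150
CYCLE_POINTS = SWING_POINTS + STANCE_POINTS  # 200


def as_muscle_matrix(envelopes) -> np.ndarray:
    """Coerce a mapping {muscle: trace} or (13, n) array to canonical order."""
    if isinstance(envelopes, Mapping):
        missing = [m for m in M.MUSCLES if m not in envelopes]
        if missing:
            raise ValueError(f"missing EMG channels: {missing}")
        return np.vstack([np.asarray(envelopes[m], dtype=float) for m in M.MUSCLES])
    arr = np.asarray(envelopes, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != M.N_MUSCLES:
        raise ValueError(f"expected a ({M.N_MUSCLES}, n) matrix, got {arr.shape}")
    return arr


@dataclass
class EnvelopeMatrix:
    """Non-negative muscles-by-time matrix of normalized, concatenated cycles."""

    values: np.ndarray  # (13, 200 * n_cycles)
    normalization: str  # "synergy" | "per-direction-max"
    cycle_offsets: list[int] = field(default_factory=list)
    muscle_names: tuple[str, ...] = M.MUSCLES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != M.N_MUSCLES:
            raise ValueError("values must be a (13, n) matrix")
        if np.any(self.values < 0):
            raise ValueError("envelope matrix must be non-negative")
        if self.values.shape[1] % CYCLE_POINTS:
            raise ValueError(f"column count must be a multiple of {CYCLE_POINTS}")
        if not self.cycle_offsets:
            self.cycle_offsets = list(
                range(0, self.values.shape[1], CYCLE_POINTS))

    @property
    def n_cycles(self) -> int:
        return self.values.shape[1] // CYCLE_POINTS

    def cycle(self, k: int) -> np.ndarray:
        """Column block of cycle k, shape (13, 200)."""
        o = self.cycle_offsets[k]
        return self.values[:, o:o + CYCLE_POINTS]

    def mean_cycle(self) -> np.ndarray:
        return self.values.reshape(M.N_MUSCLES, self.n_cycles,
                                   CYCLE_POINTS).mean(axis=1)


@dataclass
class CoactivationSeries:
    """Antagonist/agonist ratio per time point; undefined points are NaN."""

    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray


def envelope(raw: np.ndarray, rate: float, highpass: float = 50.0,
             lowpass: float = 20.0, order: int = 4) -> np.ndarray:
    """Linear envelope of one raw EMG channel (non-negative output)."""
    if rate <= 2 * highpass:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a {highpass} Hz high-pass")
    x = np.asarray(raw, dtype=float)
    x = butter_zero_phase(x, highpass, rate, btype="highpass", order=order)
    x = np.abs(x)
    x = butter_zero_phase(x, lowpass, rate, btype="lowpass", order=order)
    return np.clip(x, 0.0, None)  # zero-phase low-pass may undershoot


def time_normalize_cycle(trace: np.ndarray, cycle: LungeCycle,
                         rate: float | None = None) -> np.ndarray:
    """Resample one cycle of a trace to 200 points (50 swing + 150 stance).

    ``rate`` is the sampling rate of ``trace``; cycle indices are converted
    from the cycle's own timebase when the rates differ. Interpolation is
    linear, so a trace already sampled on the 50+150 grid is returned
    unchanged and touchdown always lands on the swing/stance boundary.
    """
    trace = np.asarray(trace, dtype=float)
    cyc = cycle if rate is None else cycle.to_rate(rate)
    lo, td, sse = cyc.lift_off, cyc.touchdown, cyc.steady_state_end
    if sse >= trace.size:
        raise ValueError("cycle extends past the end of the trace")
    if td - lo < 2 or sse - td + 1 < 2:
        raise ValueError("swing and stance must each span at least 2 samples")
    grid = np.arange(trace.size)
    swing = np.interp(np.linspace(lo, td - 1, SWING_POINTS), grid, trace)
    stance = np.interp(np.linspace(td, sse, STANCE_POINTS), grid, trace)
    return np.concatenate([swing, stance])


def _unit_scale(row: np.ndarray, name: str) -> np.ndarray:
    """Min-max scale one muscle trace to [0, 1]; constant rows become zero."""
    hi, lo = row.max(), row.min()
    if hi <= 0:
        raise ValueError(f"muscle {name!r} has zero maximum activation (dead channel)")
    span = hi - lo
    if span == 0:
        logger.warning("muscle %r is constant; row is all-zero after min "
                       "subtraction", name)
        return np.zeros_like(row)
    return (row - lo) / span


def normalize_for_synergies(envelopes, cycles: Sequence[LungeCycle],
                            rate: float | None = None) -> EnvelopeMatrix:
    """Build the factorization input V from envelope traces and cycle events.

    Per muscle the amplitude is scaled to the trial maximum and the minimum
    activity subtracted, so each row of V spans [0, 1] over the trial; every
    cycle is then time-normalized to 200 points and concatenated.
    """
    if not cycles:
        raise ValueError("at least one cycle is required")
    mat = as_muscle_matrix(envelopes)
    blocks = []
    for cyc in cycles:
        blocks.append(np.vstack(
            [time_normalize_cycle(mat[i], cyc, rate=rate)
             for i in range(M.N_MUSCLES)]))
    v = np.hstack(blocks)
    v = np.vstack([_unit_scale(v[i], M.MUSCLES[i]) for i in range(M.N_MUSCLES)])
    return EnvelopeMatrix(values=v, normalization="synergy")


def normalize_per_direction(envelopes_per_trial: Sequence,
                            cycles_per_trial: Sequence[Sequence[LungeCycle]],
                            rate: float | None = None) -> list[EnvelopeMatrix]:
    """Normalize each trial's envelopes to the per-direction muscle maxima.

    The divisor for every muscle is its maximum over all trials supplied
    (i.e. all repetitions of one direction for one participant); no minimum
    subtraction is applied. Output values are invariant to a common positive
    rescaling of the inputs.
    """
    if len(envelopes_per_trial) != len(cycles_per_trial):
        raise ValueError("one cycle list per trial is required")
    mats = [as_muscle_matrix(e) for e in envelopes_per_trial]
    normed = []
    for mat, cycles in zip(mats, cycles_per_trial):
        if not cycles:
            raise ValueError("at least one cycle per trial is required")
        normed.append(np.hstack([
            np.vstack([time_normalize_cycle(mat[i], cyc, rate=rate)
                       for i in range(M.N_MUSCLES)])
            for cyc in cycles]))
    maxima = np.max(np.hstack([v.max(axis=1, keepdims=True) for v in normed]),
                    axis=1)
    dead = [M.MUSCLES[i] for i in np.flatnonzero(maxima <= 0)]
    if dead:
        raise ValueError(f"muscles with zero maximum activation: {dead}")
    return [EnvelopeMatrix(values=v / maxima[:, None],
                           normalization="per-direction-max") for v in normed]


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    n_undef = int((~ok).sum())
    if n_undef:
        logger.warning("coactivation undefined at %d points (zero agonist "
                       "activity); marked NaN", n_undef)
    return out


def coactivation(envelopes) -> CoactivationSeries:
    """Pointwise antagonist/agonist coactivation ratios for hip, knee, ankle.

    hip  = mean(FL, RF) / mean(ME, MA)
    knee = mean(BF, ST) / mean(RF, VM, VL)
    ankle = TA / mean(GM, GL, SO)

    Inputs must be per-direction-max normalized envelopes. Points with zero
    agonist activity are returned as NaN, never as zero.
    """
    mat = as_muscle_matrix(envelopes)
    row = {m: mat[i] for i, m in enumerate(M.MUSCLES)}

    def group_mean(names):
        return np.mean([row[n] for n in names], axis=0)

    hip = _ratio(group_mean(M.HIP_ANTAGONISTS), group_mean(M.HIP_AGONISTS))
    knee = _ratio(group_mean(M.KNEE_ANTAGONISTS), group_mean(M.KNEE_AGONISTS))
    ankle = _ratio(group_mean(M.ANKLE_ANTAGONISTS), group_mean(M.ANKLE_AGONISTS))
    return CoactivationSeries(hip=hip, knee=knee, ankle=ankle)
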