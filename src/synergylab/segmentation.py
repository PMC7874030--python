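"""Lunge-cycle event detection: touchdown, lift-off and steady-state end.

Touchdown is the first ground-reaction-force sample whose Euclidean norm
exceeds a configurable threshold (0 N for clean synthetic plates, ~10 N
suggested for real ones). Lift-off uses the foot acceleration-and-jerk
rule: the fifth-metatarsal vertical trace is zero-phase low-pass filtered
at 50 Hz, differentiated twice (acceleration) and three times (jerk) by
central differences; the lift-off estimate LOe is the global acceleration
maximum in the 800 ms window before touchdown, and the returned lift-off is
the jerk zero-crossing marking a local acceleration minimum inside
(LOe - 50 ms, LOe + 200 ms), falling back to LOe with a warning when no
crossing qualifies. The cycle ends at the beginning of the knee-angle
steady state: after maximum flexion, the knee-angle slope series is split
by divisive energy-statistic change-point detection (E-divisive: recursive
bisection maximizing the between-segment energy distance, permutation
significance test), and the first segment whose mean slope does not
significantly depart from zero starts the steady state.

All event indices are reported on the 1 kHz analog timebase; kinematic
indices are converted by the rate ratio with round-half-up.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import LungeCycle, TrialRecording, fill_marker_gaps, \
    kinematic_to_analog_index
from .filters import butter_zero_phase, derivative
from .kinetics import knee_flexion_angle

logger = logging.getLogger(__name__)


class NoContactError(ValueError):
    """The GRF trace never exceeds the contact threshold."""


class NoSteadyStateError(ValueError):
    """No post-flexion segment with a statistically flat knee-angle slope."""


@dataclass
class EventDetectionConfig:
    grf_threshold: float = 0.0  # N; first norm above this is touchdown
    lpf_cutoff: float = 50.0  # Hz, foot kinematics low-pass
    search_window_before_td: float = 800.0  # ms, LOe search window
    neighborhood: tuple[float, float] = (-50.0, 200.0)  # ms around LOe
    changepoint_alpha: float = 0.05
    changepoint_min_segment: int = 30  # points
    n_permutations: int = 199
    energy_alpha: float = 1.0  # energy-distance exponent
    min_unloaded_ms: float = 100.0  # gap separating loading episodes
    max_marker_gap: int = 10  # samples, linear gap fill limit
    seed: int = 0  # permutation-test rng seed

    def __post_init__(self) -> None:
        if self.search_window_before_td <= 0:
            raise ValueError("search window must be positive")
        if self.neighborhood[1] <= self.neighborhood[0]:
            raise ValueError("neighborhood must have positive length")
        if not 0 < self.changepoint_alpha < 1:
            raise ValueError("changepoint_alpha must lie in (0, 1)")
        if self.changepoint_min_segment < 2:
            raise ValueError("changepoint_min_segment must be >= 2")

    def check_rate(self, rate: float) -> None:
        if self.lpf_cutoff >= rate / 2:
            raise ValueError(
                f"lpf_cutoff {self.lpf_cutoff} Hz must be below the Nyquist "
                f"frequency of the {rate} Hz stream")


# ---------------------------------------------------------------------------
# E-divisive change-point detection (energy statistic)
# ---------------------------------------------------------------------------

def _prefix(d: np.ndarray) -> np.ndarray:
    s = np.zeros((d.shape[0] + 1, d.shape[1] + 1))
    s[1:, 1:] = d.cumsum(axis=0).cumsum(axis=1)
    return s


def _block(s: np.ndarray, a: int, b: int, c, d) -> np.ndarray:
    """Sum of D[a:b, c:d] from the padded prefix array (c, d vectorizable)."""
    return s[b, d] - s[a, d] - s[b, c] + s[a, c]


def _best_split(s: np.ndarray, lo: int, hi: int, min_size: int):
    """Best within-[lo, hi) split by the scaled energy statistic Q.

    Q(tau) = n1 n2 / (n1 + n2) * [2 B/(n1 n2) - W1/(n1 (n1-1)/2)/2 ... ]
    computed from the pairwise-distance prefix sums in O(1) per tau.
    Returns (q, tau) or None when the segment is too short.
    """
    taus = np.arange(lo + min_size, hi - min_size + 1)
    if taus.size == 0:
        return None
    n1 = (taus - lo).astype(float)
    n2 = (hi - taus).astype(float)
    st = s[taus, taus]
    between = s[taus, hi] - s[lo, hi] - st + s[lo, taus]  # sum D[lo:t, t:hi]
    w1 = st - s[lo, taus] - s[taus, lo] + s[lo, lo]  # sum D[lo:t, lo:t]
    w2 = s[hi, hi] - s[taus, hi] - s[hi, taus] + st  # sum D[t:hi, t:hi]
    e = (2.0 * between / (n1 * n2)
         - np.where(n1 > 1, w1 / np.maximum(n1 * (n1 - 1), 1), 0.0)
         - np.where(n2 > 1, w2 / np.maximum(n2 * (n2 - 1), 1), 0.0))
    q = n1 * n2 / (n1 + n2) * e
    k = int(np.argmax(q))
    return float(q[k]), int(taus[k])


def _best_over_segments(s: np.ndarray, boundaries: list[int], min_size: int):
    best = None
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        cand = _best_split(s, lo, hi, min_size)
        if cand is not None and (best is None or cand[0] > best[0]):
            best = (cand[0], cand[1], lo, hi)
    return best


def e_divisive(x: np.ndarray, min_size: int = 30, alpha: float = 1.0,
               n_permutations: int = 199, sig_level: float = 0.05,
               rng: np.random.Generator | None = None) -> list[int]:
    """Divisive energy-statistic change-point estimation on a 1-D series.

    Recursively bisects the series at the split maximizing the scaled
    between-segment energy distance Q; each split must survive a permutation
    test (observations permuted within the current segments) at
    ``sig_level``. Returns the sorted change-point indices (segment starts,
    excluding 0).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    rng = rng or np.random.default_rng(0)
    if n < 2 * min_size:
        return []
    d = np.abs(x[:, None] - x[None, :]) ** alpha
    s = _prefix(d)
    boundaries = [0, n]
    cps: list[int] = []
    while True:
        best = _best_over_segments(s, boundaries, min_size)
        if best is None:
            break
        q_obs = best[0]
        exceed = 0
        for _ in range(n_permutations):
            perm = np.arange(n)
            for lo, hi in zip(boundaries[:-1], boundaries[1:]):
                perm[lo:hi] = lo + rng.permutation(hi - lo)
            dp = d[np.ix_(perm, perm)]
            cand = _best_over_segments(_prefix(dp), boundaries, min_size)
            if cand is not None and cand[0] >= q_obs:
                exceed += 1
        p = (1 + exceed) / (n_permutations + 1)
        if p > sig_level:
            break
        cps.append(best[1])
        boundaries = sorted(boundaries + [best[1]])
    return sorted(cps)


def _mean_is_zero(segment: np.ndarray, n_permutations: int, sig_level: float,
                  rng: np.random.Generator) -> bool:
    """One-sample sign-flip permutation test of mean == 0; True if flat."""
    obs = abs(float(np.mean(segment)))
    if obs == 0:
        return True
    flips = rng.choice([-1.0, 1.0], size=(n_permutations, segment.size))
    perm = np.abs((flips * segment).mean(axis=1))
    p = (1 + int(np.sum(perm >= obs))) / (n_permutations + 1)
    return p > sig_level


# ---------------------------------------------------------------------------
# Event detectors
# ---------------------------------------------------------------------------

def touchdown_detect(grf: np.ndarray, cfg: EventDetectionConfig | None = None
                     ) -> int:
    """Index of the first GRF sample whose norm exceeds the threshold."""
    cfg = cfg or EventDetectionConfig()
    grf = np.asarray(grf, dtype=float)
    norm = np.linalg.norm(grf, axis=1) if grf.ndim == 2 else np.abs(grf)
    idx = np.flatnonzero(norm > cfg.grf_threshold)
    if idx.size == 0:
        raise NoContactError(
            f"no GRF sample exceeds the {cfg.grf_threshold} N threshold")
    return int(idx[0])


def liftoff_detect(metatarsal_z: np.ndarray, td: int, rate: float,
                   cfg: EventDetectionConfig | None = None) -> int:
    """Lift-off sample from the fifth-metatarsal vertical trace.

    ``td`` is the touchdown index on the same timebase as the trace.
    """
    cfg = cfg or EventDetectionConfig()
    cfg.check_rate(rate)
    z = np.asarray(metatarsal_z, dtype=float).ravel()
    if not 0 < td <= z.size:
        raise ValueError("touchdown index must lie inside the trace")
    z = butter_zero_phase(z, cfg.lpf_cutoff, rate)
    acc = derivative(z, rate, n=2)
    jerk = derivative(acc, rate, n=1)

    w0 = max(0, td - int(round(cfg.search_window_before_td * rate / 1000.0)))
    if td - w0 < 3:
        raise ValueError("search window before touchdown is too short")
    loe = w0 + int(np.argmax(acc[w0:td]))

    lo_n = max(0, loe + int(round(cfg.neighborhood[0] * rate / 1000.0)))
    hi_n = min(z.size - 1, loe + int(round(cfg.neighborhood[1] * rate / 1000.0)))
    # jerk sign change - to + marks a local acceleration minimum
    j = jerk[lo_n:hi_n + 1]
    cross = np.flatnonzero((j[:-1] < 0) & (j[1:] >= 0))
    if cross.size == 0:
        logger.warning("no jerk-zero acceleration minimum in (%g, %g) ms "
                       "around LOe; falling back to LOe", *cfg.neighborhood)
        return int(loe)
    cands = []
    for c in cross:
        i = lo_n + c
        # pick the adjacent sample closer to the zero crossing
        cands.append(i if abs(jerk[i]) <= abs(jerk[i + 1]) else i + 1)
    cands = np.array(sorted(set(cands)))
    dist = np.abs(cands - loe)
    return int(cands[np.flatnonzero(dist == dist.min())[0]])  # tie -> earlier


def steady_state_detect(knee_flexion: np.ndarray, rate: float,
                        cfg: EventDetectionConfig | None = None) -> int:
    """Start of the knee-angle steady state in a post-touchdown trace.

    ``knee_flexion`` is a flexion angle (larger = more flexed) sampled at
    ``rate``, starting at touchdown. Returns the sample index (relative to
    the trace start) where the first statistically flat slope segment after
    maximum flexion begins.
    """
    cfg = cfg or EventDetectionConfig()
    theta = np.asarray(knee_flexion, dtype=float).ravel()
    if theta.size < 2 * cfg.changepoint_min_segment:
        raise ValueError("trace too short for change-point analysis")
    rng = np.random.default_rng(cfg.seed)
    i_max = int(np.argmax(theta))  # plateau ties break to the earliest sample
    slope = derivative(theta[i_max:], rate, n=1)
    if slope.size < 2 * cfg.changepoint_min_segment:
        # settling window too short to split; test it whole
        if _mean_is_zero(slope, cfg.n_permutations, cfg.changepoint_alpha, rng):
            return i_max
        raise NoSteadyStateError("no steady state before the trace ends")
    cps = e_divisive(slope, min_size=cfg.changepoint_min_segment,
                     alpha=cfg.energy_alpha,
                     n_permutations=cfg.n_permutations,
                     sig_level=cfg.changepoint_alpha, rng=rng)
    starts = [0] + cps
    ends = cps + [slope.size]
    for s0, s1 in zip(starts, ends):
        if _mean_is_zero(slope[s0:s1], cfg.n_permutations,
                         cfg.changepoint_alpha, rng):
            return i_max + s0
    raise NoSteadyStateError("no steady state before the trace ends")


# ---------------------------------------------------------------------------
# Trial-level composition
# ---------------------------------------------------------------------------

def _loading_episodes(norm: np.ndarray, threshold: float, rate: float,
                      min_unloaded_ms: float) -> list[tuple[int, int]]:
    """Contiguous loaded intervals, merging gaps shorter than min_unloaded."""
    loaded = norm > threshold
    if not loaded.any():
        return []
    idx = np.flatnonzero(loaded)
    min_gap = max(1, int(round(min_unloaded_ms * rate / 1000.0)))
    episodes = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > min_gap:
            episodes.append((int(start), int(prev) + 1))
            start = i
        prev = i
    episodes.append((int(start), int(prev) + 1))
    return episodes


def _detect_cycle(trial: TrialRecording, cfg: EventDetectionConfig,
                  td_analog: int, stance_end_analog: int,
                  flexion: np.ndarray) -> LungeCycle:
    kin_rate, analog_rate = trial.marker_rate, trial.grf_rate
    td_kin = kinematic_to_analog_index(td_analog, analog_rate, kin_rate)
    met_z = fill_marker_gaps(trial.markers["fifth_metatarsal"],
                             max_gap=cfg.max_marker_gap)[:, 2]
    if np.isnan(met_z).any():
        raise ValueError("fifth-metatarsal trace has unfillable gaps")
    lo_kin = liftoff_detect(met_z, td_kin, kin_rate, cfg)

    end_kin = kinematic_to_analog_index(stance_end_analog, analog_rate, kin_rate)
    end_kin = min(end_kin, flexion.size)
    ss_kin = td_kin + steady_state_detect(flexion[td_kin:end_kin], kin_rate, cfg)

    lo_analog = kinematic_to_analog_index(lo_kin, kin_rate, analog_rate)
    ss_analog = min(kinematic_to_analog_index(ss_kin, kin_rate, analog_rate),
                    trial.n_analog - 1)
    return LungeCycle(lift_off=lo_analog, touchdown=td_analog,
                      steady_state_end=ss_analog, rate=analog_rate)


def segment_trial(trial: TrialRecording,
                  cfg: EventDetectionConfig | None = None) -> LungeCycle:
    """Detect the single lunge cycle of a one-repetition recording."""
    cfg = cfg or EventDetectionConfig()
    cfg.check_rate(trial.marker_rate)
    td = touchdown_detect(trial.grf, cfg)
    flexion = knee_flexion_angle(trial.markers, max_gap=cfg.max_marker_gap)
    try:
        return _detect_cycle(trial, cfg, td, trial.n_analog, flexion)
    except ValueError as exc:
        raise type(exc)(f"trial {trial.meta.participant} "
                        f"{trial.meta.direction}/{trial.meta.ground}: {exc}"
                        ) from exc


def segment_cycles(trial: TrialRecording,
                   cfg: EventDetectionConfig | None = None
                   ) -> tuple[list[LungeCycle], list[str]]:
    """Detect every lunge repetition in a continuous recording.

    Repetitions are GRF loading episodes separated by unloaded gaps; each
    episode's first loaded sample is its touchdown. Returns the detected
    cycles and a log of per-episode failures (detection continues).
    """
    cfg = cfg or EventDetectionConfig()
    cfg.check_rate(trial.marker_rate)
    norm = np.linalg.norm(trial.grf, axis=1)
    episodes = _loading_episodes(norm, cfg.grf_threshold, trial.grf_rate,
                                 cfg.min_unloaded_ms)
    if not episodes:
        raise NoContactError("no GRF loading episode found in the recording")
    flexion = knee_flexion_angle(trial.markers, max_gap=cfg.max_marker_gap)
    cycles, failures = [], []
    for k, (start, end) in enumerate(episodes):
        try:
            cycles.append(_detect_cycle(trial, cfg, start, end, flexion))
        except (ValueError, NoSteadyStateError) as exc:
            failures.append(f"repetition {k}: {exc}")
            logger.warning("repetition %d dropped: %s", k, exc)
    return cycles, failures
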