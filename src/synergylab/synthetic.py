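"""Synthetic lunge trials with known ground truth.

Every pipeline stage is exercised against data built from a known generative
model: EMG envelopes are a non-negative mixture of Gaussian-bump motor
primitives through a known module matrix plus truncated Gaussian noise; the
ground reaction force has a clean contact onset; the fifth-metatarsal
vertical trajectory carries the acceleration-maximum / jerk-zero lift-off
signature; and the knee angle rises to maximum flexion and settles onto a
plateau at a known steady-state time. Cycle-to-cycle variability is
emulated by jittering primitive centers (default sd 2 points) and
amplitudes (default 5%). The generator makes no claim of biomechanical
realism - streams only need to exercise the detectors and the
factorization - and identical (spec, seed) pairs produce bit-identical
output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import muscles as M
from .core_io import TrialMeta, TrialRecording
from .emg import CYCLE_POINTS, STANCE_POINTS, SWING_POINTS, EnvelopeMatrix
from .filters import butter_zero_phase
from .kinetics import SegmentParameters, static_equilibrium_moments

logger = logging.getLogger(__name__)

GRAVITY = 9.81


@dataclass(frozen=True)
class GroundTruthSynergy:
    """Generative counterpart of one module column and primitive row."""

    weights: np.ndarray  # (13,) non-negative, max 1
    center: float  # primitive center, normalized points in (0, 200)
    width_sigma: float  # Gaussian width, points
    amplitude: float = 1.0  # peak activation in (0, 1]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (M.N_MUSCLES,):
            raise ValueError(f"weights must have shape ({M.N_MUSCLES},)")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not np.isclose(w.max(), 1.0):
            raise ValueError("weights must be max-normalized to 1")
        object.__setattr__(self, "weights", w)
        if not 0 < self.center < CYCLE_POINTS:
            raise ValueError("center must lie in (0, 200)")
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must lie in (0, 1]")


def default_synergies() -> list[GroundTruthSynergy]:
    """Four well-separated reference synergies (swing, touchdown, weight
    acceptance, stabilization) with plausible muscle groupings."""
    def w(groups: dict[str, float]) -> np.ndarray:
        out = np.full(M.N_MUSCLES, 0.05)
        for m, v in groups.items():
            out[M.MUSCLES.index(m)] = v
        return out

    return [
        GroundTruthSynergy(  # swing: dorsiflexors, hip flexors/abductors
            w({"TA": 1.0, "RF": 0.7, "FL": 0.8, "ME": 0.5}), 25.0, 6.0),
        GroundTruthSynergy(  # touchdown: plantarflexors, hamstrings
            w({"GM": 1.0, "GL": 0.9, "SO": 0.8, "ST": 0.6, "BF": 0.6}),
            60.0, 6.0),
        GroundTruthSynergy(  # weight acceptance: knee and hip extensors
            w({"VM": 1.0, "VL": 0.95, "RF": 0.5, "MA": 0.7, "ME": 0.4}),
            85.0, 6.0),
        GroundTruthSynergy(  # stabilization: dorsiflexors, foot stabilizers
            w({"TA": 0.8, "PL": 1.0, "SO": 0.6, "GL": 0.4, "VL": 0.3}),
            120.0, 6.0),
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative study conditions for one synthetic condition recording."""

    synergies: list[GroundTruthSynergy] = field(default_factory=default_synergies)
    n_cycles: int = 25
    noise_sd: float = 0.05  # additive, relative to unit amplitude
    swing_ms: float = 300.0
    stance_ms: float = 900.0
    center_jitter: float = 2.0  # points, cycle-to-cycle sd
    amplitude_jitter: float = 0.05  # relative sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.swing_ms <= 0 or self.stance_ms <= 0:
            raise ValueError("phase durations must be positive")
        if not self.synergies:
            raise ValueError("at least one synergy is required")


def _primitive_rows(spec: SyntheticSpec, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cycle jittered Gaussian primitives.

    Returns (H, centers, amps): H is (r, n_cycles * 200); centers and amps
    are (n_cycles, r) per-cycle truths.
    """
    r = len(spec.synergies)
    t = np.arange(CYCLE_POINTS, dtype=float)
    centers = np.empty((spec.n_cycles, r))
    amps = np.empty((spec.n_cycles, r))
    blocks = []
    for c in range(spec.n_cycles):
        rows = np.empty((r, CYCLE_POINTS))
        for k, syn in enumerate(spec.synergies):
            centers[c, k] = syn.center + rng.normal(0.0, spec.center_jitter)
            amps[c, k] = syn.amplitude * max(
                0.0, 1.0 + rng.normal(0.0, spec.amplitude_jitter))
            rows[k] = amps[c, k] * np.exp(
                -((t - centers[c, k]) ** 2) / (2 * syn.width_sigma ** 2))
        blocks.append(rows)
    return np.hstack(blocks), centers, amps


def generate_envelopes(spec: SyntheticSpec) -> tuple[EnvelopeMatrix, dict]:
    """Synthesize the factorization input V = clip0(W H + noise) with truth.

    V is rescaled per muscle to [0, 1] exactly as the synergy normalization
    does, so it can be fed straight to the extractor. The truth dict carries
    the generative modules, noiseless primitives and mean cycles, nominal
    and per-cycle centers, and amplitudes.
    """
    rng = np.random.default_rng(spec.seed)
    w = np.column_stack([s.weights for s in spec.synergies])  # (13, r)
    h, centers, amps = _primitive_rows(spec, rng)
    clean = w @ h
    v = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    v = np.clip(v, 0.0, None)
    scaled = np.empty_like(v)
    for i in range(M.N_MUSCLES):
        hi, lo = v[i].max(), v[i].min()
        if hi <= 0 or hi == lo:
            logger.warning("muscle %s is all-zero/constant after noise "
                           "clipping", M.MUSCLES[i])
            scaled[i] = 0.0
        else:
            scaled[i] = (v[i] - lo) / (hi - lo)
    r = len(spec.synergies)
    mean_primitives = h.reshape(r, spec.n_cycles, CYCLE_POINTS).mean(axis=1)
    truth = {
        "modules": w,
        "primitives": h,
        "mean_primitives": mean_primitives,
        "centers": np.array([s.center for s in spec.synergies]),
        "sigmas": np.array([s.width_sigma for s in spec.synergies]),
        "amplitudes": np.array([s.amplitude for s in spec.synergies]),
        "cycle_centers": centers,
        "cycle_amplitudes": amps,
    }
    return EnvelopeMatrix(values=scaled, normalization="synergy"), truth


# ---------------------------------------------------------------------------
# Kinematic / kinetic stream synthesis
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _gauss(t: np.ndarray, c: float, s: float) -> np.ndarray:
    return np.exp(-((t - c) ** 2) / (2 * s * s))


@dataclass(frozen=True)
class CycleTruth:
    """Generative event times (s, from recording start) of one repetition."""

    lift_off: float
    touchdown: float
    steady_state: float


def _metatarsal_accel(t: np.ndarray, t_lo: float, t_td: float) -> np.ndarray:
    """Designed vertical acceleration: positive maximum 40 ms before the
    lift-off, jerk-zero acceleration minimum exactly at the lift-off, and a
    gentle mid-swing lift bump."""
    a = 30.0 * _gauss(t, t_lo - 0.040, 0.012)
    a -= 15.0 * _gauss(t, t_lo, 0.010)
    a += 3.0 * _gauss(t, 0.5 * (t_lo + t_td), 0.060)
    a -= 3.0 * _gauss(t, t_td - 0.040, 0.050)  # set the foot back down
    return a


def _knee_flexion_profile(t: np.ndarray, truth: CycleTruth,
                          plateau: float = 60.0) -> np.ndarray:
    """Flexion angle (deg): rest, swing rise, post-touchdown flexion peak,
    linear settling and an exact plateau from the steady-state time on."""
    theta = np.full(t.shape, 10.0)
    t_lo, t_td, t_ss = truth.lift_off, truth.touchdown, truth.steady_state
    sw = (t >= t_lo) & (t < t_td)
    theta[sw] = 10.0 + 10.0 * _smoothstep((t[sw] - t_lo) / (t_td - t_lo))
    t_max = t_td + 0.3 * (t_ss - t_td)
    peak = plateau + 10.0
    rise = (t >= t_td) & (t < t_max)
    theta[rise] = 20.0 + (peak - 20.0) * np.sin(
        0.5 * np.pi * (t[rise] - t_td) / (t_max - t_td)) ** 2
    settle = (t >= t_max) & (t < t_ss)
    theta[settle] = peak - (peak - plateau) * (t[settle] - t_max) / (t_ss - t_max)
    theta[t >= t_ss] = plateau
    return theta


def generate_kinematic_streams(spec: SyntheticSpec, kin_rate: float = 250.0,
                               analog_rate: float = 1000.0,
                               peak_force: float = 700.0,
                               grf_noise_sd: float = 0.0,
                               knee_noise_sd: float = 0.0,
                               pre_roll_s: float = 0.9,
                               post_roll_s: float = 0.4
                               ) -> tuple[dict, CycleTruth]:
    """One repetition's GRF, fifth-metatarsal height and knee angle streams.

    Returns ({"grf", "metatarsal_z", "knee_flexion", "t_kin", "t_analog",
    "kin_rate", "analog_rate"}, truth). The GRF (analog rate) is exactly
    zero before the generative touchdown; the metatarsal and knee traces are
    at the kinematic rate.
    """
    rng = np.random.default_rng(spec.seed + 1)
    t_lo = pre_roll_s
    t_td = t_lo + spec.swing_ms / 1000.0
    t_ss = t_td + spec.stance_ms / 1000.0
    total = t_ss + post_roll_s
    truth = CycleTruth(lift_off=t_lo, touchdown=t_td, steady_state=t_ss)

    t_a = np.arange(int(round(total * analog_rate))) / analog_rate
    t_k = np.arange(int(round(total * kin_rate))) / kin_rate

    # shift by half a sample so the force is already non-zero at the contact
    # sample itself ("first non-zero value" convention) and float fuzz at the
    # preceding sample cannot tip it positive
    ramp = _smoothstep((t_a - t_td + 0.5 / analog_rate) / 0.020)
    fz = peak_force * ramp * (1.0 - 0.1 * _smoothstep((t_a - t_td - 0.2) / 0.4))
    fx = 0.12 * fz
    grf = np.column_stack([fx, np.zeros_like(fz), fz])
    if grf_noise_sd > 0:
        grf[t_a >= t_td] += rng.normal(0.0, grf_noise_sd,
                                       size=(int((t_a >= t_td).sum()), 3))
        grf[t_a >= t_td] = np.clip(grf[t_a >= t_td], 0.0, None)

    acc = _metatarsal_accel(t_k, t_lo, t_td)
    vel = np.cumsum(acc) / kin_rate
    z = 0.05 + np.cumsum(vel) / kin_rate  # m above ground
    metatarsal_z = z * 1000.0  # mm

    knee = _knee_flexion_profile(t_k, truth)
    if knee_noise_sd > 0:
        knee = knee + rng.normal(0.0, knee_noise_sd, size=knee.shape)

    streams = {"grf": grf, "metatarsal_z": metatarsal_z,
               "knee_flexion": knee, "t_kin": t_k, "t_analog": t_a,
               "kin_rate": kin_rate, "analog_rate": analog_rate}
    return streams, truth


def _markers_from_flexion(knee_flexion: np.ndarray, metatarsal_z: np.ndarray
                          ) -> dict[str, np.ndarray]:
    """Marker set realizing a given knee-flexion trace (thigh held vertical)
    and the given fifth-metatarsal height. Positions in mm."""
    n = knee_flexion.size
    thigh_l, shank_l = 450.0, 430.0  # mm
    hip = np.tile([0.0, 0.0, 900.0], (n, 1))
    knee = hip + [0.0, 0.0, -thigh_l]
    # thigh vertical: knee->ankle at angle flexion from straight-down gives
    # an inter-segment knee angle of 180 - flexion degrees
    theta = np.radians(knee_flexion)
    ankle = knee + shank_l * np.column_stack(
        [np.sin(theta), np.zeros(n), -np.cos(theta)])
    calc = ankle + [-50.0, 0.0, -60.0]
    met5 = ankle + [140.0, 0.0, 0.0]
    met5[:, 2] = metatarsal_z
    toe = met5 + [60.0, 0.0, -5.0]
    return {"greater_trochanter": hip, "lateral_epicondyle": knee,
            "lateral_malleolus": ankle, "calcaneus": calc,
            "fifth_metatarsal": met5, "toe_tip": toe}


def _raw_emg_from_envelope(env: np.ndarray, rate: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated band-limited noise whose linear envelope is
    proportional to ``env``."""
    carrier = rng.normal(0.0, 1.0, size=env.shape)
    carrier = butter_zero_phase(carrier, 60.0, rate, btype="highpass")
    return env * carrier


def generate_trial(spec: SyntheticSpec, participant: str = "S01",
                   direction: str = "forward", ground: str = "stable",
                   body_mass: float = 75.0, limb_length: float = 0.90,
                   kin_rate: float = 250.0, analog_rate: float = 1000.0,
                   emg_rest: float = 0.02
                   ) -> tuple[TrialRecording, dict]:
    """Full multi-repetition TrialRecording with per-repetition truth.

    Repetition blocks (pre-roll, swing, stance, post-roll) are concatenated;
    the GRF unloads between repetitions so the loading-episode splitter can
    recover them. Raw EMG is band-limited noise amplitude-modulated by the
    generative primitive mixture mapped onto real time (swing points 0-50,
    stance points 50-200).
    """
    rng = np.random.default_rng(spec.seed)
    w = np.column_stack([s.weights for s in spec.synergies])
    rep_spec = replace(spec, n_cycles=1)

    grf_parts, met_parts, knee_parts, env_parts = [], [], [], []
    truths: list[CycleTruth] = []
    offset_s = 0.0
    for c in range(spec.n_cycles):
        streams, truth = generate_kinematic_streams(
            replace(rep_spec, seed=spec.seed + 101 * c),
            kin_rate=kin_rate, analog_rate=analog_rate)
        n_a = streams["grf"].shape[0]
        t_a = streams["t_analog"]
        # generative primitives for this repetition
        h, centers, amps = _primitive_rows(
            replace(rep_spec, seed=spec.seed + 101 * c + 7),
            np.random.default_rng(spec.seed + 101 * c + 7))
        # map real time onto normalized cycle points
        pts = np.full(n_a, np.nan)
        sw = (t_a >= truth.lift_off) & (t_a < truth.touchdown)
        st = (t_a >= truth.touchdown) & (t_a <= truth.steady_state)
        pts[sw] = SWING_POINTS * (t_a[sw] - truth.lift_off) / (
            truth.touchdown - truth.lift_off)
        pts[st] = SWING_POINTS + (STANCE_POINTS - 1) * (
            t_a[st] - truth.touchdown) / (truth.steady_state - truth.touchdown)
        env = np.full((M.N_MUSCLES, n_a), emg_rest)
        inside = ~np.isnan(pts)
        grid = np.arange(CYCLE_POINTS, dtype=float)
        for m in range(M.N_MUSCLES):
            prof = w[m] @ h  # (200,)
            env[m, inside] += np.interp(pts[inside], grid, prof)
        if spec.noise_sd > 0:
            env += np.abs(rng.normal(0.0, spec.noise_sd * 0.1, size=env.shape))

        grf_parts.append(streams["grf"])
        met_parts.append(streams["metatarsal_z"])
        knee_parts.append(streams["knee_flexion"])
        env_parts.append(env)
        truths.append(CycleTruth(truth.lift_off + offset_s,
                                 truth.touchdown + offset_s,
                                 truth.steady_state + offset_s))
        offset_s += n_a / analog_rate

    grf = np.vstack(grf_parts)
    met_z = np.concatenate(met_parts)
    knee = np.concatenate(knee_parts)
    env = np.hstack(env_parts)
    raw = np.vstack([_raw_emg_from_envelope(env[m], analog_rate, rng)
                     for m in range(M.N_MUSCLES)])

    markers = _markers_from_flexion(knee, met_z)
    trial = TrialRecording(
        markers=markers, marker_rate=kin_rate,
        emg={m: raw[i] for i, m in enumerate(M.MUSCLES)},
        emg_rate=analog_rate, grf=grf, grf_rate=analog_rate,
        meta=TrialMeta(participant=participant, body_mass=body_mass,
                       limb_length=limb_length, direction=direction,
                       ground=ground))
    truth = {
        "cycles": truths,
        "modules": w,
        "centers": np.array([s.center for s in spec.synergies]),
        "sigmas": np.array([s.width_sigma for s in spec.synergies]),
        "event_samples_analog": [
            (int(round(t.lift_off * analog_rate)),
             int(round(t.touchdown * analog_rate)),
             int(round(t.steady_state * analog_rate))) for t in truths],
    }
    return trial, truth


def generate_static_kinetics_case(mass: float, thigh_l: float = 0.45,
                                  shank_l: float = 0.43, foot_l: float = 0.19,
                                  grf: tuple[float, float] = (0.0, 700.0),
                                  cop_offset: float = 0.10,
                                  params: SegmentParameters | None = None,
                                  n_frames: int = 50, rate: float = 250.0
                                  ) -> tuple[dict, dict]:
    """Motionless posture with constant GRF and its equilibrium-truth moments.

    The limb stands vertically (hip over knee over ankle); the foot axis is
    horizontal and centered on the ankle so the foot weight has no ankle
    lever. ``cop_offset`` places the CoP that far anterior (+x, m) of the
    ankle. Returns ({"markers", "grf", "cop", "mass", "params"}, expected
    moments in N m from the static-equilibrium oracle).
    """
    if min(mass, thigh_l, shank_l, foot_l) <= 0:
        raise ValueError("mass and segment lengths must be positive")
    params = params or SegmentParameters()
    ankle = np.array([0.0, 0.0, 80.0])
    frame = {
        "greater_trochanter": ankle + [0.0, 0.0, (shank_l + thigh_l) * 1000],
        "lateral_epicondyle": ankle + [0.0, 0.0, shank_l * 1000],
        "lateral_malleolus": ankle,
        # foot axis centered on the ankle: CoM (fraction 0.5) under the joint
        "calcaneus": ankle + [-foot_l * 500, 0.0, -60.0],
        "fifth_metatarsal": ankle + [foot_l * 500, 0.0, -60.0],
        "toe_tip": ankle + [foot_l * 500 + 40, 0.0, -65.0],
    }
    markers = {k: np.tile(v, (n_frames, 1)).astype(float)
               for k, v in frame.items()}
    fvec = np.array(grf, dtype=float)
    cop = np.array([ankle[0] / 1000.0 + cop_offset, 0.0])
    expected = static_equilibrium_moments(frame, fvec, cop, mass, params)
    grf3 = np.tile([fvec[0], 0.0, fvec[1]], (n_frames * 4, 1))
    cop_trace = np.tile(cop, (n_frames * 4, 1))
    case = {"markers": markers, "grf": grf3, "cop": cop_trace,
            "mass": mass, "params": params, "kin_rate": rate,
            "analog_rate": rate * 4}
    return case, expected
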