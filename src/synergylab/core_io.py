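"""Domain types and tabular I/O for lunge-trial recordings.

A trial is one continuous multirate capture: 3-D marker trajectories (mm) at
the kinematic rate (nominally 250 Hz), 13 surface-EMG channels and a triaxial
ground-reaction-force trace at the analog rate (nominally 1 kHz), plus
participant metadata. The interchange format is a single wide TSV/CSV with a
kinematic column block (``time_kin``, ``<marker>_{x,y,z}``) and an analog
block (``time_analog``, ``GRF_{x,y,z}``, ``EMG_<muscle>``); the shorter block
is NaN-padded at the bottom, and metadata travel in ``# key: value`` header
comments. Every downstream stage consumes the in-memory types defined here;
no stage re-reads files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .muscles import MUSCLES, REQUIRED_MARKERS

logger = logging.getLogger(__name__)

DIRECTIONS = ("forward", "backward")
GROUNDS = ("stable", "unstable")


class SchemaError(ValueError):
    """A required channel, marker or metadata field is missing or invalid."""


class FormatError(ValueError):
    """The file exists but violates the tabular dialect (e.g. bad time axis)."""


@dataclass(frozen=True)
class TrialMeta:
    participant: str
    body_mass: float  # kg
    limb_length: float  # m
    direction: str  # forward | backward
    ground: str  # stable | unstable

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise SchemaError("body_mass must be positive")
        if self.limb_length <= 0:
            raise SchemaError("limb_length must be positive")
        if self.direction not in DIRECTIONS:
            raise SchemaError(f"direction must be one of {DIRECTIONS}")
        if self.ground not in GROUNDS:
            raise SchemaError(f"ground must be one of {GROUNDS}")


@dataclass
class TrialRecording:
    """One continuous capture holding >= 1 lunge repetitions.

    markers map name -> (n, 3) array in mm; emg maps muscle -> (m,) array in
    arbitrary units; grf is (m, 3) in N. Kinematic and analog streams may have
    different lengths and rates.
    """

    markers: dict[str, np.ndarray]
    marker_rate: float
    emg: dict[str, np.ndarray]
    emg_rate: float
    grf: np.ndarray
    grf_rate: float
    meta: TrialMeta

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for rate, what in ((self.marker_rate, "marker"), (self.emg_rate, "emg"),
                           (self.grf_rate, "grf")):
            if not rate > 0:
                raise SchemaError(f"{what} sampling rate must be > 0")
        missing = [m for m in REQUIRED_MARKERS if m not in self.markers]
        if missing:
            raise SchemaError(f"missing required markers: {missing}")
        if not self.markers:
            raise SchemaError("marker set is empty")
        nk = None
        for name, arr in self.markers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
                raise SchemaError(f"marker {name!r} must be a non-empty (n, 3) array")
            if nk is None:
                nk = arr.shape[0]
            elif arr.shape[0] != nk:
                raise SchemaError("all markers must share one length")
            self.markers[name] = arr
        extra = sorted(set(self.emg) - set(MUSCLES))
        missing_m = [m for m in MUSCLES if m not in self.emg]
        if missing_m or extra:
            raise SchemaError(
                f"EMG channels must be exactly {list(MUSCLES)}; "
                f"missing={missing_m}, unexpected={extra}")
        na = None
        for name in MUSCLES:
            arr = np.asarray(self.emg[name], dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise SchemaError(f"EMG channel {name!r} must be a non-empty vector")
            if na is None:
                na = arr.size
            elif arr.size != na:
                raise SchemaError("all EMG channels must share one length")
            self.emg[name] = arr
        self.grf = np.asarray(self.grf, dtype=float)
        if self.grf.ndim != 2 or self.grf.shape[1] != 3 or self.grf.shape[0] == 0:
            raise SchemaError("grf must be a non-empty (n, 3) array")
        if self.grf.shape[0] != na:
            raise SchemaError("GRF and EMG must share the analog timebase")

    @property
    def n_kinematic(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def n_analog(self) -> int:
        return self.grf.shape[0]


@dataclass(frozen=True)
class LungeCycle:
    """Event indices bounding one lunge repetition on a single timebase.

    swing = [lift_off, touchdown), stance = [touchdown, steady_state_end].
    """

    lift_off: int
    touchdown: int
    steady_state_end: int
    rate: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.lift_off < self.touchdown < self.steady_state_end):
            raise ValueError(
                "cycle events must satisfy lift_off < touchdown < steady_state_end, "
                f"got {self.lift_off}, {self.touchdown}, {self.steady_state_end}")
        if self.lift_off < 0:
            raise ValueError("event indices must be non-negative")

    @property
    def swing_slice(self) -> slice:
        return slice(self.lift_off, self.touchdown)

    @property
    def stance_slice(self) -> slice:
        return slice(self.touchdown, self.steady_state_end + 1)

    def to_rate(self, rate: float) -> "LungeCycle":
        """Convert event indices to another sampling rate (round half up)."""
        if rate == self.rate:
            return self
        r = rate / self.rate
        conv = lambda i: int(math.floor(i * r + 0.5))
        return LungeCycle(conv(self.lift_off), conv(self.touchdown),
                          conv(self.steady_state_end), rate=rate)


def kinematic_to_analog_index(idx: int, kin_rate: float, analog_rate: float) -> int:
    """Map a kinematic-rate sample index onto the analog timebase, round half up."""
    return int(math.floor(idx * analog_rate / kin_rate + 0.5))


def fill_marker_gaps(positions: np.ndarray, max_gap: int = 10) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap in an (n, 3) trace.

    Longer runs (and leading/trailing NaNs) are left in place; differentiating
    code must refuse them.
    """
    out = np.array(positions, dtype=float)
    n = out.shape[0]
    for c in range(out.shape[1]):
        col = out[:, c]
        isnan = np.isnan(col)
        if not isnan.any():
            continue
        idx = np.flatnonzero(isnan)
        # split into contiguous runs
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        good = np.flatnonzero(~isnan)
        for run in splits:
            if run.size == 0 or run.size > max_gap:
                continue
            lo, hi = run[0] - 1, run[-1] + 1
            if lo < 0 or hi >= n:
                continue  # boundary gap: cannot bracket
            col[run] = np.interp(run, [lo, hi], [col[lo], col[hi]])
        out[:, c] = col
    return out


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------

_AXES = ("x", "y", "z")
_META_KEYS = ("participant", "body_mass", "limb_length", "direction", "ground",
              "marker_rate", "analog_rate")


def load_schema(path) -> dict[str, str]:
    """Load a YAML column-name mapping {user column -> canonical column}."""
    with open(path, "r", encoding="utf-8") as fh:
        schema = yaml.safe_load(fh) or {}
    if not isinstance(schema, dict):
        raise SchemaError("schema YAML must be a flat mapping of column names")
    return {str(k): str(v) for k, v in schema.items()}


def read_trial(path, schema: dict[str, str] | None = None) -> TrialRecording:
    """Read one trial file (TSV or CSV) into a validated TrialRecording.

    ``schema`` optionally renames user columns to the canonical ones before
    interpretation. Unit conventions: markers mm, GRF N, time seconds.
    """
    meta_raw: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = 0
        for line in fh:
            if line.startswith("#"):
                pos += 1
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta_raw[k.strip()] = v.strip()
            else:
                break
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if schema:
        df = df.rename(columns=schema)

    for key in _META_KEYS:
        if key not in meta_raw:
            raise SchemaError(f"missing metadata header field {key!r}")
    meta = TrialMeta(
        participant=meta_raw["participant"],
        body_mass=float(meta_raw["body_mass"]),
        limb_length=float(meta_raw["limb_length"]),
        direction=meta_raw["direction"],
        ground=meta_raw["ground"],
    )
    marker_rate = float(meta_raw["marker_rate"])
    analog_rate = float(meta_raw["analog_rate"])

    for col in ("time_kin", "time_analog"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    kin_mask = df["time_kin"].notna().to_numpy()
    t_kin = df.loc[kin_mask, "time_kin"].to_numpy(dtype=float)
    if t_kin.size and np.any(np.diff(t_kin) <= 0):
        raise FormatError("time_kin column is not strictly increasing")
    analog_mask = df["time_analog"].notna().to_numpy()
    t_analog = df.loc[analog_mask, "time_analog"].to_numpy(dtype=float)
    if t_analog.size and np.any(np.diff(t_analog) <= 0):
        raise FormatError("time_analog column is not strictly increasing")

    marker_names = sorted({c[:-2] for c in df.columns
                           if c.endswith(("_x", "_y", "_z"))
                           and not c.startswith(("GRF", "EMG"))})
    markers = {}
    for name in marker_names:
        cols = [f"{name}_{ax}" for ax in _AXES]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"marker {name!r} missing axis columns {missing}")
        markers[name] = df.loc[kin_mask, cols].to_numpy(dtype=float)

    grf_cols = [f"GRF_{ax}" for ax in _AXES]
    missing = [c for c in grf_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing GRF columns {missing}")
    grf = df.loc[analog_mask, grf_cols].to_numpy(dtype=float)

    emg = {}
    missing_emg = [m for m in MUSCLES if f"EMG_{m}" not in df.columns]
    if missing_emg:
        raise SchemaError(f"missing EMG channels: {missing_emg}")
    for m in MUSCLES:
        emg[m] = df.loc[analog_mask, f"EMG_{m}"].to_numpy(dtype=float)

    return TrialRecording(markers=markers, marker_rate=marker_rate,
                          emg=emg, emg_rate=analog_rate,
                          grf=grf, grf_rate=analog_rate, meta=meta)


def write_trial(trial: TrialRecording, path) -> None:
    """Write a TrialRecording in the tabular dialect read_trial understands."""
    trial.validate()
    for name, arr in trial.markers.items():
        if np.isnan(arr).any():
            logger.warning("marker %r contains NaN gaps; preserved on write", name)

    nk, na = trial.n_kinematic, trial.n_analog
    nrows = max(nk, na)

    def pad(v: np.ndarray) -> np.ndarray:
        out = np.full(nrows, np.nan)
        out[: v.size] = v
        return out

    data: dict[str, np.ndarray] = {}
    data["time_kin"] = pad(np.arange(nk) / trial.marker_rate)
    for name in sorted(trial.markers):
        for j, ax in enumerate(_AXES):
            data[f"{name}_{ax}"] = pad(trial.markers[name][:, j])
    data["time_analog"] = pad(np.arange(na) / trial.grf_rate)
    for j, ax in enumerate(_AXES):
        data[f"GRF_{ax}"] = pad(trial.grf[:, j])
    for m in MUSCLES:
        data[f"EMG_{m}"] = pad(trial.emg[m])

    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(data)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# participant: {trial.meta.participant}\n")
        fh.write(f"# body_mass: {trial.meta.body_mass!r}\n")
        fh.write(f"# limb_length: {trial.meta.limb_length!r}\n")
        fh.write(f"# direction: {trial.meta.direction}\n")
        fh.write(f"# ground: {trial.meta.ground}\n")
        fh.write(f"# marker_rate: {trial.marker_rate!r}\n")
        fh.write(f"# analog_rate: {trial.grf_rate!r}\n")
        df.to_csv(fh, sep=sep, index=False, float_format="%.10g", na_rep="NaN")
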