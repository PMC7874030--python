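"""End-to-end orchestration over a directory of trial recordings.

For every participant x direction x ground condition the pipeline segments
lunge cycles, applies the repetition bookkeeping (drop the first and last
cycle, keep up to the central 50), computes averaged envelopes,
coactivation, joint angles and moments over the 200-point normalized
cycles, extracts muscle synergies from the concatenated cycles, classifies
them across conditions, and splits CoA/FWHM into early/late cycle blocks.
Summary tables carry descriptive statistics (mean +/- sd) only; group-level
inferential statistics are deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import muscles as M
from .core_io import LungeCycle, TrialRecording, read_trial, fill_marker_gaps
from .emg import (CYCLE_POINTS, CoactivationSeries, EnvelopeMatrix,
                  coactivation, envelope, normalize_for_synergies,
                  normalize_per_direction, time_normalize_cycle)
from .kinetics import SegmentParameters, inverse_dynamics, joint_angles
from .segmentation import EventDetectionConfig, segment_cycles
from .synergy import (COMBINED, ClassifiedSynergy, SynergyNMF, classify,
                      compute_coa, compute_fwhm, overlaps)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str | Path = "."
    output_dir: str | Path | None = None
    events: EventDetectionConfig = field(default_factory=EventDetectionConfig)
    seed: int = 0
    n_restarts: int = 10
    max_rank: int | None = None  # None -> round(0.75 * n_muscles)
    similarity_threshold: float = 0.80
    drop_first_last: bool = True
    central_cycles: int = 50
    early_late_size: int = 25

    def __post_init__(self) -> None:
        if self.central_cycles < 1 or self.early_late_size < 1:
            raise ValueError("cycle policy sizes must be positive")


def central_window(n: int, drop_first_last: bool, central: int) -> slice:
    """Indices of retained cycles: drop first/last, keep a centered window."""
    lo, hi = (1, n - 1) if (drop_first_last and n > 2) else (0, n)
    span = hi - lo
    if span > central:
        extra = span - central
        lo += extra // 2
        hi = lo + central
    return slice(lo, hi)


def early_late_blocks(n: int, size: int) -> tuple[slice, slice]:
    """First/last repetition blocks of ``size`` (capped at half the cycles).

    With a single cycle both blocks degenerate to that cycle.
    """
    k = min(size, max(1, n // 2))
    return slice(0, k), slice(n - k, n)


def _cop_under_metatarsal(trial: TrialRecording, max_gap: int) -> np.ndarray:
    """Fallback center of pressure: ground point under the fifth metatarsal."""
    met5 = fill_marker_gaps(trial.markers["fifth_metatarsal"], max_gap=max_gap)
    x_kin = met5[:, 0] / 1000.0
    n_a = trial.n_analog
    idx = np.minimum(
        np.floor(np.arange(n_a) * trial.marker_rate / trial.grf_rate + 0.5
                 ).astype(int), x_kin.size - 1)
    return np.column_stack([x_kin[idx], np.zeros(n_a)])


@dataclass
class ConditionResult:
    """Everything computed for one participant x direction x ground."""

    key: tuple[str, str, str]
    cycles: list[LungeCycle]
    retained: slice
    envelope_mean: np.ndarray  # (13, 200) per-direction-max normalized
    coactivation_mean: CoactivationSeries
    v: EnvelopeMatrix
    nmf: SynergyNMF
    classified: list[ClassifiedSynergy] = field(default_factory=list)
    angles_mean: dict[str, np.ndarray] | None = None
    moments_mean: dict[str, np.ndarray] | None = None
    early_late: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict)
    overlap_mean: np.ndarray | None = None


def run_pipeline(config: RunConfig, trials: list[TrialRecording] | None = None
                 ) -> dict:
    """Run every stage over a directory (or an in-memory list) of trials.

    Stage errors are collected per trial and the pipeline continues; the
    returned bundle maps condition keys to ConditionResult plus a failure
    log and structured per-stage timings.
    """
    t0 = time.perf_counter()
    log: list[dict] = []
    failures: list[str] = []
    if trials is None:
        trials = []
        paths = sorted(Path(config.input_dir).glob("*.tsv")) + \
            sorted(Path(config.input_dir).glob("*.csv"))
        for p in paths:
            try:
                trials.append(read_trial(p))
            except Exception as exc:  # noqa: BLE001 - contract: log and go on
                failures.append(f"{p.name}: {exc}")
                logger.warning("unreadable trial %s: %s", p.name, exc)
    if not trials:
        raise ValueError("no readable trials")

    # --- segmentation + envelopes per recording -------------------------
    per_condition: dict[tuple, dict] = {}
    for trial in trials:
        key = (trial.meta.participant, trial.meta.direction, trial.meta.ground)
        try:
            cycles, cyc_failures = segment_cycles(trial, config.events)
            failures += [f"{key}: {f}" for f in cyc_failures]
            if not cycles:
                raise ValueError("no valid cycles")
            env = np.vstack([envelope(trial.emg[m], trial.emg_rate)
                             for m in M.MUSCLES])
            per_condition.setdefault(key, {"trial": trial, "cycles": [],
                                           "envelopes": []})
            per_condition[key]["cycles"] += cycles
            per_condition[key]["envelopes"].append(env)
            per_condition[key]["trial"] = trial
        except Exception as exc:  # noqa: BLE001
            failures.append(f"{key}: {exc}")
            logger.warning("condition %s failed: %s", key, exc)
    log.append({"stage": "segmentation", "t": time.perf_counter() - t0})

    results: dict[tuple, ConditionResult] = {}
    # per-direction normalization shares maxima across ground conditions
    directions = {(k[0], k[1]) for k in per_condition}
    for pd_key in sorted(directions):
        keys = [k for k in per_condition
                if (k[0], k[1]) == pd_key]
        env_sets = [per_condition[k]["envelopes"][0] for k in keys]
        cycle_sets = []
        for k in keys:
            info = per_condition[k]
            win = central_window(len(info["cycles"]), config.drop_first_last,
                                 config.central_cycles)
            info["retained"] = win
            cycle_sets.append(info["cycles"][win])
        try:
            dir_norm = normalize_per_direction(
                env_sets, cycle_sets, rate=per_condition[keys[0]]["trial"].grf_rate)
        except ValueError as exc:
            failures.append(f"{pd_key}: {exc}")
            continue
        for k, dn in zip(keys, dir_norm):
            per_condition[k]["direction_normalized"] = dn

    for key in sorted(per_condition):
        info = per_condition[key]
        if "direction_normalized" not in info:
            continue
        trial: TrialRecording = info["trial"]
        cycles = info["cycles"][info["retained"]]
        try:
            v = normalize_for_synergies(info["envelopes"][0], cycles,
                                        rate=trial.grf_rate)
            est = SynergyNMF(n_restarts=config.n_restarts,
                             random_state=config.seed)
            est.fit(v)
            dn: EnvelopeMatrix = info["direction_normalized"]
            coact = coactivation(dn.mean_cycle())
            ang = joint_angles(trial.markers,
                               max_gap=config.events.max_marker_gap)
            cop = _cop_under_metatarsal(trial, config.events.max_marker_gap)
            moments = inverse_dynamics(
                trial.markers, trial.marker_rate, trial.grf, trial.grf_rate,
                cop, trial.meta.body_mass,
                lpf_cutoff=config.events.lpf_cutoff,
                max_gap=config.events.max_marker_gap)
            ang_mean = {j: np.mean([time_normalize_cycle(
                ang[j], c, rate=trial.marker_rate) for c in cycles], axis=0)
                for j in ("hip", "knee", "ankle")}
            mom_mean = {j: np.mean([time_normalize_cycle(
                moments[j], c, rate=trial.marker_rate) for c in cycles],
                axis=0) for j in ("hip", "knee", "ankle")}
            results[key] = ConditionResult(
                key=key, cycles=info["cycles"], retained=info["retained"],
                envelope_mean=dn.mean_cycle(), coactivation_mean=coact,
                v=v, nmf=est, angles_mean=ang_mean, moments_mean=mom_mean)
        except Exception as exc:  # noqa: BLE001
            failures.append(f"{key}: {exc}")
            logger.warning("condition %s failed: %s", key, exc)
    log.append({"stage": "synergies", "t": time.perf_counter() - t0})

    # --- classification across conditions --------------------------------
    keys = sorted(results)
    if len(keys) >= 2:
        classified = classify([results[k].nmf.decomposition_ for k in keys],
                              similarity_threshold=config.similarity_threshold)
        for cs in classified:
            results[keys[cs.trial_index]].classified.append(cs)
    elif len(keys) == 1:
        logger.warning("only one condition: skipping shape classification")

    # --- early/late CoA/FWHM and overlaps --------------------------------
    for key in keys:
        res = results[key]
        dec = res.nmf.decomposition_
        n_cyc = dec.h.shape[1] // CYCLE_POINTS
        early, late = early_late_blocks(n_cyc, config.early_late_size)
        h3 = dec.h.reshape(dec.rank, n_cyc, CYCLE_POINTS)
        for cs in res.classified:
            if cs.label == COMBINED:
                continue
            res.early_late.setdefault(cs.label, {})
            for name, block in (("early", early), ("late", late)):
                mp = h3[cs.synergy_index, block].mean(axis=0)
                try:
                    res.early_late[cs.label][name] = (
                        compute_coa(mp), float(compute_fwhm(mp)))
                except ValueError:
                    res.early_late[cs.label][name] = (np.nan, np.nan)
        fund = [cs.primitive for cs in res.classified if cs.is_fundamental]
        if len(fund) >= 2:
            _, res.overlap_mean = overlaps([fund])
    log.append({"stage": "metrics", "t": time.perf_counter() - t0})

    bundle = {"results": results, "failures": failures, "log": log,
              "config": config}
    if config.output_dir is not None:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def summarize(bundle: dict) -> dict[str, pd.DataFrame]:
    """Descriptive summary tables: CoA/FWHM per synergy label x ground x
    early/late, and the number of extracted synergies per condition."""
    results: dict[tuple, ConditionResult] = bundle["results"]
    labels = ("swing", "touchdown", "weight_acceptance", "stabilization")
    rows = []
    conditions = sorted({(k[1], k[2]) for k in results})
    for direction, ground in conditions:
        conds = [r for k, r in results.items()
                 if (k[1], k[2]) == (direction, ground)]
        for label in labels:
            for metric, mi in (("FWHM", 1), ("CoA", 0)):
                for block in ("early", "late"):
                    vals = [r.early_late[label][block][mi] for r in conds
                            if label in r.early_late
                            and np.isfinite(r.early_late[label][block][mi])]
                    if vals:
                        mean = float(np.mean(vals))
                        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                        cell = f"{mean:.1f} ± {sd:.1f}"
                    else:
                        cell = "n.a."
                    rows.append({"direction": direction, "ground": ground,
                                 "synergy": label, "metric": metric,
                                 "block": block, "value": cell})
    table1 = pd.DataFrame(rows)
    counts = pd.DataFrame(
        [{"participant": k[0], "direction": k[1], "ground": k[2],
          "n_synergies": r.nmf.rank_, "r2": r.nmf.r2_,
          "n_cycles": len(r.cycles)} for k, r in sorted(results.items())])
    return {"table1": table1, "synergy_counts": counts}


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = summarize(bundle)
    tables["table1"].to_csv(out_dir / "summary_table1.tsv", sep="\t",
                            index=False)
    tables["synergy_counts"].to_csv(out_dir / "synergy_counts.tsv", sep="\t",
                                    index=False)
    with open(out_dir / "run_log.jsonl", "w", encoding="utf-8") as fh:
        for entry in bundle["log"]:
            fh.write(json.dumps(entry) + "\n")
        for f in bundle["failures"]:
            fh.write(json.dumps({"failure": f}) + "\n")
    for key, res in bundle["results"].items():
        sub = out_dir / "_".join(key)
        sub.mkdir(exist_ok=True)
        dec = res.nmf.decomposition_
        pd.DataFrame(dec.w, index=M.MUSCLES).to_csv(
            sub / "modules.tsv", sep="\t", header=False)
        np.savetxt(sub / "primitives.tsv", dec.h, delimiter="\t")
        metrics = [{"label": cs.label, "coa": cs.coa, "fwhm": cs.fwhm}
                   for cs in res.classified]
        with open(sub / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump({"rank": dec.rank, "r2": dec.r2,
                       "synergies": metrics,
                       "early_late": res.early_late}, fh, indent=1)
        if res.overlap_mean is not None:
            np.savetxt(sub / "overlaps.tsv", res.overlap_mean, delimiter="\t")
        if res.nmf.r2_curve_:
            pd.Series(res.nmf.r2_curve_).to_csv(sub / "rank_curve.tsv",
                                                sep="\t", header=False)
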