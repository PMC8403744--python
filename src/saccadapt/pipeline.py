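"""End-to-end orchestration: design -> simulate -> process -> validate -> analyze.

A run is fully described by a :class:`RunConfig` (JSON/YAML serialisable)
and is deterministic given its master seed: the same config produces a
byte-identical report. Group statistics are reported as mean +/- SD.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import psychometrics as psy
from .design import experiment_spec
from .gaze import EXCLUSION_REASONS
from .observer import ObserverParams, generate_dataset, observer_params_from_dict


@dataclass
class RunConfig:
    """Reproducible specification of one simulated experiment run."""

    experiment: int = 1
    n_participants: int = 16
    seed: int = 0
    observer: dict = field(default_factory=dict)   # ObserverParams overrides
    n_bootstrap: int = 0
    subset_analyses: bool = False
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (yaml.safe_dump(self.to_dict(), sort_keys=True)
                if path.suffix in (".yml", ".yaml")
                else json.dumps(self.to_dict(), indent=2, sort_keys=True))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Structured results of a run; every statistic traces back to the records."""

    config: RunConfig
    records: pd.DataFrame
    exclusion_summary: pd.DataFrame
    participant_fits: pd.DataFrame | None
    group_stats: dict
    t_tests: dict
    decay: dict | None = None
    running_average: pd.DataFrame | None = None
    subset_pses: dict | None = None

    def summary_dict(self) -> dict:
        """JSON-serialisable core of the report (used for hashing and export)."""
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash,
            "group_stats": _jsonable(self.group_stats),
            "t_tests": _jsonable(self.t_tests),
            "decay": _jsonable(self.decay),
            "exclusions": _jsonable(
                self.exclusion_summary.loc["group"].to_dict()
                if "group" in self.exclusion_summary.index else {}),
        }

    @property
    def report_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.summary_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _jsonable(obj):
    if obj is None or isinstance(obj, (str, bool, int)):
        return obj
    if isinstance(obj, float):
        return round(float(obj), 12)
    if isinstance(obj, np.generic):
        return _jsonable(obj.item())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, psy.TTestResult):
        return {"t": _jsonable(obj.t), "df": _jsonable(obj.df), "p": _jsonable(obj.p)}
    return str(obj)


def summarize_exclusions(records: pd.DataFrame) -> pd.DataFrame:
    """Exclusion fractions (percent) per participant and reason, plus totals.

    A trial violating several rules counts once in ``total``, so the
    per-reason columns sum to at least the total.
    """
    rows = {}
    for pid, sub in records.groupby("participant"):
        reasons = sub["exclusion_reasons"].fillna("")
        row = {r: 100.0 * reasons.str.contains(r).mean() for r in EXCLUSION_REASONS}
        row["total"] = 100.0 * (~sub["valid"]).mean()
        row["n_trials"] = len(sub)
        rows[pid] = row
    table = pd.DataFrame(rows).T
    group = table.drop(columns="n_trials").mean()
    group["n_trials"] = table["n_trials"].sum()
    table.loc["group"] = group
    return table


def _fit_participants(records: pd.DataFrame, by: list[str],
                      n_bootstrap: int = 0) -> pd.DataFrame:
    rows = []
    for keys, sub in records.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        try:
            f = psy.fit_psychometric(sub["delta_c"].to_numpy(),
                                     sub["response_anti_higher"].to_numpy(),
                                     n_bootstrap=n_bootstrap)
            rows.append(dict(zip(by, keys)) | {
                "pse": f.pse, "jnd": f.jnd, "lapse": f.lapse,
                "n_trials": f.n_trials,
                "ci_pse_lo": f.ci_pse[0] if f.ci_pse else np.nan,
                "ci_pse_hi": f.ci_pse[1] if f.ci_pse else np.nan,
            })
        except psy.DegenerateFitError:
            rows.append(dict(zip(by, keys)) | {
                "pse": np.nan, "jnd": np.nan, "lapse": np.nan,
                "n_trials": len(sub), "ci_pse_lo": np.nan, "ci_pse_hi": np.nan})
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig) -> RunReport:
    """Execute all pipeline stages for one experiment and assemble the report."""
    spec = experiment_spec(config.experiment)
    params = observer_params_from_dict(config.observer)
    records = generate_dataset(spec, config.n_participants, params, config.seed)
    exclusions = summarize_exclusions(records)
    valid = records[records["valid"]]

    group_stats: dict = {
        "experiment": config.experiment,
        "n_participants": config.n_participants,
        "n_trials_total": int(len(records)),
        "n_trials_valid": int(len(valid)),
        "median_saccade_latency_ms": float(
            valid.groupby("participant")["saccade_latency_ms"].median().mean()),
        "mean_adaptation_duration_ms": float(
            valid.groupby("participant")["adaptation_duration_ms"].mean().mean()),
    }
    t_tests: dict = {}
    fits = None
    decay = None
    run_avg = None
    subset_pses = None

    if config.experiment in (1, 5):
        fits = _fit_participants(valid, ["participant"], config.n_bootstrap)
        group_stats |= _group_pse_jnd(fits)
        pses = fits["pse"].dropna()
        if pses.size >= 2:
            t_tests["pse_vs_zero"] = psy.t_test(pses, mode="one-sample", tail="less")
        if config.subset_analyses and config.experiment == 1:
            subset_pses = {}
            for factor in ("f_anti", "correlated_position"):
                sf = _fit_participants(valid, ["participant", factor])
                subset_pses[factor] = {
                    str(level): float(sub["pse"].mean())
                    for level, sub in sf.groupby(factor)}

    elif config.experiment == 2:
        per = [psy.running_average(sub["adaptation_duration_ms"].to_numpy(),
                                   sub["response_anti_higher"].to_numpy())
               for _, sub in valid.groupby("participant")]
        frames = [pd.DataFrame({"bin_center_ms": c.bin_centers_ms, "prop": c.proportions})
                  for c in per]
        run_avg = (pd.concat(frames).groupby("bin_center_ms", as_index=False)
                   .mean().rename(columns={"prop": "prop_anti_higher"}))
        short = valid[valid["adaptation_duration_ms"] <= 100.0]
        per_short = short.groupby("participant")["response_anti_higher"].mean()
        group_stats["prop_anti_higher_short_adaptation"] = float(per_short.mean())
        group_stats["sd_prop_anti_higher_short_adaptation"] = float(per_short.std(ddof=1))

    elif config.experiment == 3:
        fits = _fit_participants(valid, ["participant", "blank_duration_ms"],
                                 config.n_bootstrap)
        mean_by_blank = fits.groupby("blank_duration_ms")["pse"].mean()
        group_stats["pse_by_blank_ms"] = {str(int(k)): float(v)
                                          for k, v in mean_by_blank.items()}
        group_stats["jnd_by_blank_ms"] = {
            str(int(k)): float(v)
            for k, v in fits.groupby("blank_duration_ms")["jnd"].mean().items()}
        d = psy.fit_log_decay(mean_by_blank.index.to_numpy(),
                              mean_by_blank.to_numpy())
        decay = {"A": d.A, "B": d.B, "domain_ms": list(d.domain_ms)}
        longest = fits[fits["blank_duration_ms"] == fits["blank_duration_ms"].max()]
        pses = longest["pse"].dropna()
        if pses.size >= 2:
            t_tests["pse_longest_blank_vs_zero"] = psy.t_test(
                pses, mode="one-sample", tail="less")

    elif config.experiment == 4:
        fits = _fit_participants(valid, ["participant", "slice_condition"],
                                 config.n_bootstrap)
        for cond, sub in fits.groupby("slice_condition"):
            group_stats[f"mean_pse_{cond}"] = float(sub["pse"].mean())
            group_stats[f"mean_jnd_{cond}"] = float(sub["jnd"].mean())
        wide = fits.pivot(index="participant", columns="slice_condition",
                          values="pse").dropna()
        if {"center", "periphery"} <= set(wide.columns) and len(wide) >= 2:
            t_tests["center_vs_periphery"] = psy.t_test(
                wide["center"], wide["periphery"], mode="paired")

    report = RunReport(config=config, records=records, exclusion_summary=exclusions,
                       participant_fits=fits, group_stats=group_stats,
                       t_tests=t_tests, decay=decay, running_average=run_avg,
                       subset_pses=subset_pses)
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def _group_pse_jnd(fits: pd.DataFrame) -> dict:
    return {
        "mean_pse": float(fits["pse"].mean()),
        "sd_pse": float(fits["pse"].std(ddof=1)),
        "mean_jnd": float(fits["jnd"].mean()),
        "sd_jnd": float(fits["jnd"].std(ddof=1)),
    }


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write the run's CSV/JSON artifacts: records, exclusions, fits, summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.records.to_csv(out / "trial_records.csv", index=False)
    report.exclusion_summary.to_csv(out / "exclusions.csv")
    if report.participant_fits is not None:
        report.participant_fits.to_csv(out / "psychometric_fits.csv", index=False)
    if report.running_average is not None:
        report.running_average.to_csv(out / "running_average.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(report.summary_dict(), indent=2, sort_keys=True))
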