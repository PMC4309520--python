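"""End-to-end experiment orchestration.

``run_experiment`` simulates (or loads) fields per condition, runs the
requested analyses, and writes a manifest echoing every parameter plus
per-field and per-track tables, so each reported statistic is recomputable
from the manifest and inputs alone.  Given the same configuration and seed
the outputs are reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import migrate, synthgen
from .core import ConfigurationError, write_json
from .synthgen import GeneratorConfig

logger = logging.getLogger("chemotirf")

#: Track metrics summarised per condition (means over migrated tracks).
MIGRATION_METRICS = ("path_um", "distance_um", "velocity_um_h",
                     "elliptical_factor")


@dataclass
class RunConfig:
    """Configuration of one simulate-and-analyse experiment."""

    seed: int
    conditions: list[str] = field(default_factory=lambda: ["control"])
    control: str = "control"
    n_fields: int = 36
    analyses: list[str] = field(default_factory=lambda: ["migration"])
    generator: dict = field(default_factory=dict)   # GeneratorConfig overrides
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "seed" not in d:
            raise ConfigurationError("run config must set an explicit seed")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SummaryReport:
    """Per-condition tables plus percent changes and tests versus control."""

    field_counts: pd.DataFrame          # condition, field, migrated count
    track_metrics: pd.DataFrame         # per migrated track
    comparison: pd.DataFrame            # metric, condition, percent decrease, p


def simulate_condition(name: str, config: RunConfig) -> list[synthgen.FieldGroundTruth]:
    """Simulate ``n_fields`` fields of one condition with per-field seeds
    derived deterministically from the run seed."""
    import zlib

    treat = synthgen.preset(name)
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(zlib.crc32(name.encode()),))
    seeds = ss.generate_state(config.n_fields)
    fields = []
    for k in range(config.n_fields):
        gc = GeneratorConfig(**{**config.generator,
                                "seed": int(seeds[k] % (2 ** 31))})
        fields.append(synthgen.make_spot_field(gc, treat))
    return fields


def run_experiment(config: RunConfig) -> SummaryReport:
    """Simulate every condition, measure migration metrics and compare to
    control.  Deterministic given the config seed."""
    if config.control not in config.conditions:
        raise ConfigurationError(
            f"control condition {config.control!r} not in conditions")
    if not config.analyses:
        warnings.warn("no analyses selected; returning an empty report",
                      stacklevel=2)
        empty = pd.DataFrame()
        return SummaryReport(empty, empty, empty)
    for a in config.analyses:
        if a not in ("migration",):
            raise ConfigurationError(f"unknown analysis {a!r}")

    count_rows = []
    metric_rows = []
    for cond in config.conditions:
        logger.info("simulating %d fields for condition %s",
                    config.n_fields, cond)
        for k, gt in enumerate(simulate_condition(cond, config)):
            n_mig = migrate.count_migrated(gt.tracks, gt.spot)
            count_rows.append({"condition": cond, "field": k,
                               "migrated": n_mig, "n_cells": len(gt.tracks)})
            summary = migrate.summarize_tracks(gt.tracks, gt.spot)
            summary = summary[summary["migrated"]]
            summary.insert(0, "field", k)
            summary.insert(0, "condition", cond)
            metric_rows.append(summary)
    field_counts = pd.DataFrame(count_rows)
    track_metrics = pd.concat(metric_rows, ignore_index=True)

    comparison = compare_conditions(field_counts, track_metrics, config.control)
    report = SummaryReport(field_counts, track_metrics, comparison)
    if config.outdir:
        _write_report(config, report)
    return report


def compare_conditions(field_counts: pd.DataFrame, track_metrics: pd.DataFrame,
                       control: str) -> pd.DataFrame:
    """Percent decrease of each metric mean versus control, with a
    Mann-Whitney U test per metric and Holm-adjusted p-values alongside
    (no correction is applied to the raw column; both are reported).

    Comparisons are made against the control only, not all pairs.
    """
    from scipy import stats

    if control not in set(field_counts["condition"]):
        raise ConfigurationError(f"unknown control label {control!r}")
    ctrl_counts = field_counts.loc[field_counts["condition"] == control,
                                   "migrated"].to_numpy(dtype=float)
    ctrl_metrics = track_metrics[track_metrics["condition"] == control]
    rows = []
    for cond in field_counts["condition"].unique():
        if cond == control:
            continue
        tr_counts = field_counts.loc[field_counts["condition"] == cond,
                                     "migrated"].to_numpy(dtype=float)
        rows.append({
            "condition": cond, "metric": "migrated_count",
            "control_mean": ctrl_counts.mean(), "treated_mean": tr_counts.mean(),
            "percent_decrease": migrate.percent_decrease(ctrl_counts.mean(),
                                                         tr_counts.mean()),
            "p_value": _mwu(ctrl_counts, tr_counts),
        })
        tr_metrics = track_metrics[track_metrics["condition"] == cond]
        for m in MIGRATION_METRICS:
            a = ctrl_metrics[m].dropna().to_numpy()
            b = tr_metrics[m].dropna().to_numpy()
            rows.append({
                "condition": cond, "metric": m,
                "control_mean": a.mean() if len(a) else np.nan,
                "treated_mean": b.mean() if len(b) else np.nan,
                "percent_decrease": migrate.percent_decrease(a.mean(), b.mean())
                if len(a) and len(b) else np.nan,
                "p_value": _mwu(a, b),
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = _holm(df["p_value"].to_numpy())
    return df


def _mwu(a: np.ndarray, b: np.ndarray) -> float:
    from scipy import stats

    if len(a) == 0 or len(b) == 0:
        return np.nan
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(running, 1.0)
    out[ok] = adj
    return out


def _write_report(config: RunConfig, report: SummaryReport) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json({"config": config.to_dict()}, outdir / "manifest.json")
    report.field_counts.to_csv(outdir / "field_counts.csv", index=False)
    report.track_metrics.to_csv(outdir / "track_metrics.csv", index=False)
    report.comparison.to_csv(outdir / "comparison.csv", index=False)
    logger.info("report written to %s", outdir)
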