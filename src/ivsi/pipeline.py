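"""Pipeline orchestration: simulate -> process -> stats with a manifest.

A run is described by a YAML/RunConfig: simulator cohort settings, filter
settings, the metric panel to model, and a seed.  Deterministic stages are
bit-identical on rerun with the same config; every output artifact is
checksummed into ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

import ivsi

from .core_io import (IvsiError, ParameterError, TraceDialect,
                      read_trace_table, read_valve_events, read_cohort_table,
                      read_metrics_table, write_metrics_table,
                      write_stats_table, write_cohort_table,
                      validate_cohort_table)
from .signalproc import FilterSpec, butterworth_lowpass, ivsi_extract
from .simulator import CohortParams, CycleParams, simulate_cohort, write_cohort
from .stats import LMMSpec, bh_fdr, fit_lmm

logger = logging.getLogger("ivsi")

#: default metric panel for the statistical stage
DEFAULT_PANEL = [
    {"direction": "radial", "layer": "endocardial", "kind": "strain_rate",
     "metric": "min_accel", "signed": False},
    {"direction": "radial", "layer": "endocardial", "kind": "strain_rate",
     "metric": "max_accel", "signed": False},
    {"direction": "radial", "layer": "endocardial", "kind": "strain",
     "metric": "min_value", "signed": False},
    {"direction": "radial", "layer": "endocardial", "kind": "strain",
     "metric": "max_value", "signed": False},
]


def panel_metric_name(entry: dict) -> str:
    suffix = "" if entry.get("signed") else "_abs"
    return (f"{entry['direction']}_{entry['layer']}_{entry['kind']}"
            f"_{entry['metric']}{suffix}_segavg")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    out_dir: str = "ivsi_run"
    seed: int = 0
    cohort: CohortParams = field(default_factory=CohortParams)
    filter: FilterSpec = field(default_factory=FilterSpec)
    panel: list = field(default_factory=lambda: [dict(e) for e in
                                                 DEFAULT_PANEL])
    lmm: LMMSpec = field(default_factory=LMMSpec)
    log_level: str = "INFO"
    write_traces: bool = False   # per-animal CSVs are bulky; opt in

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        if "out_dir" in raw:
            cfg.out_dir = str(raw["out_dir"])
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "log_level" in raw:
            cfg.log_level = str(raw["log_level"])
        if "write_traces" in raw:
            cfg.write_traces = bool(raw["write_traces"])
        if "panel" in raw:
            cfg.panel = list(raw["panel"])
        cyc = CycleParams(**raw.get("cycle", {}))
        co = dict(raw.get("cohort", {}))
        cfg.cohort = CohortParams(cycle=cyc, **co)
        cfg.filter = FilterSpec(**raw.get("filter", {}))
        cfg.lmm = LMMSpec(**raw.get("lmm", {}))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def process_cohort(records, filter_spec: FilterSpec, panel: list
                   ) -> tuple[list, pd.DataFrame]:
    """Filter + extract IVSI metrics for every animal-day record; returns the
    per-animal-day IVSIMetrics and a long cohort table for the panel."""
    metrics_list = []
    rows = []
    for rec in records:
        cyc = rec["cycle"]
        filtered = [butterworth_lowpass(tr, filter_spec)
                    for tr in cyc.traces]
        m = ivsi_extract(filtered, cyc.events, animal_id=rec["animal_id"],
                         day=rec["day"])
        metrics_list.append(m)
        for entry in panel:
            rows.append({"animal_id": rec["animal_id"],
                         "group": rec["group"], "day": rec["day"],
                         "metric_name": panel_metric_name(entry),
                         "value": m.get(entry["direction"], entry["kind"],
                                        entry["metric"],
                                        layer=entry["layer"],
                                        signed=bool(entry.get("signed")))})
    return metrics_list, validate_cohort_table(pd.DataFrame(rows))


def stats_stage(cohort_table: pd.DataFrame, lmm_spec: LMMSpec) -> list:
    """Fit the LMM per panel metric and BH-adjust the fixed-effect p-values
    as one family across the whole panel."""
    results = []
    for name in sorted(cohort_table.metric_name.unique()):
        spec = LMMSpec(metric_name=name, ci_level=lmm_spec.ci_level,
                       df_method=lmm_spec.df_method)
        results.extend(fit_lmm(cohort_table, spec))
    non_intercept = [r for r in results if r.effect != "intercept"]
    if non_intercept:
        adj = bh_fdr([r.p_value for r in non_intercept])
        for r, a in zip(non_intercept, adj):
            r.p_adjusted = float(a)
    return results


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> process -> stats; returns the artifact manifest.

    Partial outputs are removed if a stage fails.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(),
                                      logging.INFO),
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    written: list[Path] = []
    t_start = time.time()
    try:
        logger.info("stage simulate: %d animals/group x %d days, seed %d",
                    config.cohort.n_per_group, len(config.cohort.days),
                    config.seed)
        cohort_params = CohortParams(**{**{k: v for k, v in
                                           asdict(config.cohort).items()
                                           if k != "cycle"},
                                        "seed": config.seed},
                                     cycle=config.cohort.cycle)
        cohort = simulate_cohort(cohort_params)
        if config.write_traces:
            trace_manifest = write_cohort(cohort, out / "traces")
            artifacts.update({k: v for k, v in trace_manifest.items()})
            written.extend(Path(v) for v in trace_manifest.values())
        gt_path = out / "ground_truth.json"
        gt_path.write_text(json.dumps(cohort.ground_truth, indent=2))
        written.append(gt_path)
        artifacts["ground_truth"] = str(gt_path)

        logger.info("stage process: filter %.0f Hz order %d (%s)",
                    config.filter.cutoff_hz, config.filter.order,
                    config.filter.application)
        t0 = time.time()
        metrics_list, cohort_table = process_cohort(
            cohort.records, config.filter, config.panel)
        logger.info("processed %d animal-days in %.1f s",
                    len(metrics_list), time.time() - t0)
        metrics_path = out / "metrics.tsv"
        write_metrics_table(metrics_list, metrics_path)
        written.append(metrics_path)
        artifacts["metrics"] = str(metrics_path)
        cohort_path = out / "cohort_metrics.csv"
        write_cohort_table(cohort_table, cohort_path)
        written.append(cohort_path)
        artifacts["cohort_metrics"] = str(cohort_path)

        logger.info("stage stats: LMM + BH-FDR over %d metrics",
                    cohort_table.metric_name.nunique())
        results = stats_stage(cohort_table, config.lmm)
        stats_path = out / "stats.tsv"
        write_stats_table(results, stats_path)
        written.append(stats_path)
        artifacts["stats"] = str(stats_path)
    except IvsiError:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    manifest = {
        "version": ivsi.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "runtime_s": round(time.time() - t_start, 3),
        "artifacts": {name: {"path": p, "sha256": _sha256(Path(p))}
                      for name, p in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("wrote %d artifacts to %s", len(artifacts), out)
    return manifest


def process_directory(traces_dir, events_path, filter_spec: FilterSpec,
                      out_path, dialect: TraceDialect | None = None) -> int:
    """Process pre-exported trace CSVs against one valve-event table."""
    traces_dir = Path(traces_dir)
    events = read_valve_events(events_path)[0]
    metrics_list = []
    for tpath in sorted(traces_dir.glob("*_traces.csv")):
        traces = read_trace_table(tpath, dialect)
        filtered = [butterworth_lowpass(tr, filter_spec) for tr in traces]
        stem = tpath.stem.replace("_traces", "")
        animal_id, _, day = stem.partition("_day")
        metrics_list.append(ivsi_extract(
            filtered, events, animal_id=animal_id,
            day=int(day) if day.isdigit() else None))
    if not metrics_list:
        raise ParameterError(f"no '*_traces.csv' files in {traces_dir}")
    write_metrics_table(metrics_list, out_path)
    return len(metrics_list)


def stats_from_cohort_csv(cohort_path, out_path,
                          lmm_spec: LMMSpec | None = None) -> int:
    """Run the statistics stage on an existing long cohort CSV."""
    table = read_cohort_table(cohort_path)
    results = stats_stage(table, lmm_spec or LMMSpec())
    write_stats_table(results, out_path)
    return len(results)
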