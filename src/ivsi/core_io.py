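"""Data model and delimited-text I/O for the IVSI pipeline.

The pipeline consumes per-segment myocardial deformation signals exported as
wide CSV tables (one time column plus one column per segment/layer/direction),
valve-event annotations, and cohort metadata, and emits long-format metric and
statistics tables.  All times are seconds internally; readers convert
millisecond files on request.

Sign convention for deformation signals: contraction during systole is
positive, relaxation in diastole negative.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ivsi")

# Tolerated relative jitter in the sample grid of a uniformly sampled trace.
TIME_JITTER_TOL = 1e-6

DIRECTIONS = ("radial", "longitudinal")
LAYERS = ("endocardial", "epicardial", "midwall")
KINDS = ("strain", "strain_rate", "velocity", "acceleration")

#: canonical unit per signal kind; derived traces advance along these chains.
CANONICAL_UNITS = {
    "strain": "%",
    "strain_rate": "%/s",
    "velocity": "mm/s",
    "acceleration": "%/s^2",
}

#: differentiation advances (kind, unit) along these chains
_DERIV_KIND = {"strain": "strain_rate", "strain_rate": "acceleration",
               "velocity": "acceleration"}
_DERIV_UNIT = {"%": "%/s", "%/s": "%/s^2", "1/s": "1/s^2", "mm/s": "mm/s^2"}


class IvsiError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IvsiError):
    """Malformed input file (non-monotone or jittery time grid, bad table)."""


class HeaderError(FormatError):
    """A trace column name does not parse under the header grammar."""


class DataError(IvsiError):
    """Unrecoverable data defect (long NaN runs, non-finite values)."""


class EventError(IvsiError):
    """Valve-event ordering violation."""


class ParameterError(IvsiError):
    """Invalid parameter value (bad phase fractions, cutoff >= Nyquist...)."""


class ResolutionError(IvsiError):
    """A phase window spans too few samples at the trace's frame rate."""


class DomainError(IvsiError):
    """Input outside the mathematical domain of an operation."""


class SampleSizeError(IvsiError):
    """Too few observations for a statistical operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _check_uniform_time(time: np.ndarray) -> float:
    """Validate a strictly increasing, uniform time grid; return the step."""
    if time.ndim != 1 or time.size < 2:
        raise FormatError("time grid needs at least 2 samples")
    steps = np.diff(time)
    if np.any(steps <= 0):
        raise FormatError("time must be strictly increasing")
    dt = float(np.mean(steps))
    if np.max(np.abs(steps - dt)) > TIME_JITTER_TOL * max(dt, abs(time[-1])):
        raise FormatError("time grid is not uniform (relative jitter > 1e-6)")
    return dt


@dataclass
class StrainTrace:
    """A uniformly sampled per-segment deformation signal.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing with constant step.
    values : ndarray
        Signal samples (strain in %, strain rate in %/s, velocity in mm/s,
        acceleration in %/s^2 — the unit tag is carried explicitly).
    direction : {"radial", "longitudinal"}
    layer : {"endocardial", "epicardial", "midwall"}
    segment_id : int
        Segment index, 1-based.
    kind : {"strain", "strain_rate", "velocity", "acceleration"}
    unit : str
        Physical unit of ``values``; free-form for imported data but must be
        consistent with ``kind`` when it is one of the canonical units.
    """

    time: np.ndarray
    values: np.ndarray
    direction: str
    layer: str
    segment_id: int
    kind: str
    unit: str | None = None
    sample_rate: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        dt = _check_uniform_time(self.time)
        if self.values.shape != self.time.shape:
            raise FormatError("values and time must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise DataError("trace values must be finite")
        if self.direction not in DIRECTIONS:
            raise ParameterError(f"unknown direction {self.direction!r}")
        if self.layer not in LAYERS:
            raise ParameterError(f"unknown layer {self.layer!r}")
        if self.kind not in KINDS:
            raise ParameterError(f"unknown kind {self.kind!r}")
        if self.unit is None:
            self.unit = CANONICAL_UNITS[self.kind]
        inferred = 1.0 / dt
        if self.sample_rate:
            if abs(self.sample_rate - inferred) > 1e-6 * inferred:
                raise FormatError("sample_rate inconsistent with time step")
        self.sample_rate = inferred
        # unit/kind consistency enforced only for canonical units; imported
        # instrument exports may carry free-form unit strings.
        canon = set(CANONICAL_UNITS.values()) | set(_DERIV_UNIT.values())
        if self.unit in canon and self.kind == "strain" and self.unit != "%":
            raise ParameterError(f"unit {self.unit!r} inconsistent with strain")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n(self) -> int:
        return int(self.time.size)

    def with_values(self, values: np.ndarray, *, kind: str | None = None,
                    unit: str | None = None) -> "StrainTrace":
        """Copy of this trace with new samples (same grid and metadata)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       kind=kind or self.kind, unit=unit or self.unit,
                       sample_rate=0.0)

    def label(self) -> str:
        return format_trace_column(self.direction, self.layer,
                                   self.segment_id, self.kind)


@dataclass
class ValveEvents:
    """Cycle-anchored valve-event times (seconds) bounding the IVRT.

    IVRT is the period from aortic valve closure (``avc_time``) to mitral
    valve opening (``mvo_time``).  ``e_end`` optionally marks the end of the
    early-filling (E) wave for early-diastole windowing.
    """

    cycle_start: float
    avc_time: float
    mvo_time: float
    cycle_end: float
    e_end: float | None = None

    def __post_init__(self) -> None:
        if not (self.cycle_start < self.avc_time < self.mvo_time
                <= self.cycle_end):
            raise EventError(
                "valve events must satisfy cycle_start < AVC < MVO <= cycle_end"
                f" (got {self.cycle_start}, {self.avc_time}, {self.mvo_time},"
                f" {self.cycle_end})")
        if self.e_end is not None and not (self.mvo_time < self.e_end
                                           <= self.cycle_end):
            raise EventError("e_end must lie between MVO and cycle end")

    @property
    def ivrt(self) -> float:
        """Isovolumic relaxation time in seconds (MVO − AVC)."""
        return self.mvo_time - self.avc_time


@dataclass
class PressureTrace:
    """Uniformly sampled left-ventricular pressure (mmHg)."""

    time: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        _check_uniform_time(self.time)
        if self.pressure.shape != self.time.shape:
            raise FormatError("pressure and time must have the same length")
        if not np.all(np.isfinite(self.pressure)):
            raise DataError("pressure values must be finite")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])


@dataclass
class ConventionalEcho:
    """Conventional M-mode / Doppler measurements (units in field names).

    LVIDd/LVIDs in mm, E/A/e_prime in mm/s, IVRT/IVCT/ET in ms, LAA in mm^2,
    heart rate in bpm.
    """

    lvidd: float
    lvids: float
    e_wave: float
    a_wave: float
    e_prime: float
    ivrt_ms: float = float("nan")
    ivct_ms: float = float("nan")
    et_ms: float = float("nan")
    laa_mm2: float = float("nan")
    heart_rate: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("lvidd", "lvids", "e_wave", "a_wave", "e_prime"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if self.lvids >= self.lvidd:
            raise DomainError("LVIDs must be smaller than LVIDd")


@dataclass
class StatResult:
    """One statistical comparison: estimate, CI, test statistic and p-values."""

    estimate: float
    ci_low: float
    ci_high: float
    statistic: float
    df: float
    p_value: float
    method: str
    p_adjusted: float | None = None
    effect: str = ""
    metric: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high or
                any(math.isnan(v) for v in (self.ci_low, self.estimate,
                                            self.ci_high))):
            raise IvsiError("confidence interval must bracket the estimate")
        if not (0.0 <= self.p_value <= 1.0):
            raise IvsiError("p-value outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise IvsiError("adjusted p-value cannot be below the raw p-value")


@dataclass
class IVSIMetrics:
    """IVRT-windowed extrema for every input signal of one animal-day.

    ``table`` is a long-format DataFrame with columns
    ``direction, layer, kind, segment_id, metric, signed, abs`` where
    ``metric`` is one of ``max_value, min_value, max_accel, min_accel`` and
    ``segment_id`` is an integer or the string ``"mean"`` for the unweighted
    across-segment average of per-segment values.
    """

    table: pd.DataFrame
    animal_id: str = ""
    day: int | None = None

    def get(self, direction: str, kind: str, metric: str,
            layer: str = "endocardial", segment: int | str = "mean",
            signed: bool = False) -> float:
        """Look up one metric value; ``signed=False`` returns |value|."""
        t = self.table
        sel = ((t.direction == direction) & (t.kind == kind)
               & (t.metric == metric) & (t.layer == layer)
               & (t.segment_id.astype(str) == str(segment)))
        rows = t[sel]
        if len(rows) != 1:
            raise KeyError(
                f"metric lookup ({direction},{layer},{kind},{metric},"
                f"seg={segment}) matched {len(rows)} rows")
        return float(rows.iloc[0]["signed" if signed else "abs"])

    def min_accel_radial_strain_rate(self, *, layer: str = "endocardial",
                                     signed: bool = False) -> float:
        """Headline metric: minimal acceleration of radial strain rate,
        averaged over segments (absolute value by default)."""
        return self.get("radial", "strain_rate", "min_accel", layer=layer,
                        signed=signed)


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long cohort table (animal_id, group, day, metric_name, value).

    Enforces uniqueness of (animal_id, day, metric_name), group membership in
    {sham, TAC}, and that group is constant within each animal.
    """
    required = ["animal_id", "group", "day", "metric_name", "value"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table missing columns {missing}")
    if table.duplicated(["animal_id", "day", "metric_name"]).any():
        raise FormatError("(animal_id, day, metric_name) must be unique")
    bad = set(table["group"].unique()) - {"sham", "TAC"}
    if bad:
        raise FormatError(f"unknown group labels {sorted(bad)}")
    per_animal = table.groupby("animal_id")["group"].nunique()
    if (per_animal > 1).any():
        raise FormatError("group must be constant within animal_id")
    out = table[required].copy()
    out["day"] = out["day"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Header grammar
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(
    r"^(?P<direction>[a-z]+)_(?P<layer>[a-z]+)_seg(?P<segment>\d+)"
    r"_(?P<kind>[a-z_]+)$")


def format_trace_column(direction: str, layer: str, segment_id: int,
                        kind: str) -> str:
    """Column name for one trace: ``<direction>_<layer>_seg<k>_<kind>``."""
    return f"{direction}_{layer}_seg{segment_id}_{kind}"


def parse_trace_column(name: str) -> tuple[str, str, int, str]:
    """Inverse of :func:`format_trace_column`; raises HeaderError."""
    m = _HEADER_RE.match(name)
    if not m:
        raise HeaderError(f"column {name!r} does not match "
                          "'<direction>_<layer>_seg<k>_<kind>'")
    direction, layer, kind = m["direction"], m["layer"], m["kind"]
    if direction not in DIRECTIONS or layer not in LAYERS or kind not in KINDS:
        raise HeaderError(f"column {name!r} has unknown direction/layer/kind")
    return direction, layer, int(m["segment"]), kind


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

@dataclass
class TraceDialect:
    """How to interpret a wide trace CSV.

    time_unit "ms" converts the time column to seconds on read; max_gap is
    the longest run of missing samples repaired by linear interpolation.
    """

    time_column: str = "time_s"
    time_unit: str = "s"   # "s" or "ms"
    unit_by_kind: dict | None = None
    max_gap: int = 3


def _fill_short_gaps(col: np.ndarray, max_gap: int, name: str) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap, else DataError."""
    isnan = np.isnan(col)
    if not isnan.any():
        return col
    if isnan[0] or isnan[-1]:
        raise DataError(f"column {name!r} starts or ends with missing data")
    idx = np.flatnonzero(isnan)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    if max(len(r) for r in runs) > max_gap:
        raise DataError(
            f"column {name!r} has a missing-data run longer than {max_gap}")
    x = np.arange(col.size)
    out = col.copy()
    out[isnan] = np.interp(x[isnan], x[~isnan], col[~isnan])
    return out


def read_trace_table(path, dialect: TraceDialect | None = None
                     ) -> list[StrainTrace]:
    """Read a wide trace CSV into one StrainTrace per data column.

    The header grammar is ``<direction>_<layer>_seg<k>_<kind>``; the time
    column is named by the dialect (default ``time_s``).  The sample rate is
    inferred from the time column and validated uniform.
    """
    dialect = dialect or TraceDialect()
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect.time_column not in df.columns:
        raise FormatError(f"missing time column {dialect.time_column!r}")
    time = df[dialect.time_column].to_numpy(dtype=float)
    if dialect.time_unit == "ms":
        time = time / 1000.0
    elif dialect.time_unit != "s":
        raise ParameterError(f"unknown time unit {dialect.time_unit!r}")
    _check_uniform_time(time)
    traces = []
    for name in df.columns:
        if name == dialect.time_column:
            continue
        direction, layer, seg, kind = parse_trace_column(name)
        vals = _fill_short_gaps(df[name].to_numpy(dtype=float),
                                dialect.max_gap, name)
        unit = (dialect.unit_by_kind or {}).get(kind, CANONICAL_UNITS[kind])
        traces.append(StrainTrace(time=time, values=vals, direction=direction,
                                  layer=layer, segment_id=seg, kind=kind,
                                  unit=unit))
    if not traces:
        raise FormatError("trace table contains no data columns")
    return traces


def write_trace_table(traces: Sequence[StrainTrace], path) -> None:
    """Write traces sharing one grid to a wide CSV (full float precision)."""
    if not traces:
        raise IvsiError("no traces to write")
    time = traces[0].time
    for tr in traces[1:]:
        if tr.n != traces[0].n or abs(tr.time[0] - time[0]) > 1e-12:
            raise FormatError("all traces must share one time grid")
    df = pd.DataFrame({"time_s": time})
    for tr in traces:
        df[tr.label()] = tr.values
    df.to_csv(path, index=False, float_format="%.17g")


def read_valve_events(path) -> list[ValveEvents]:
    """Read a valve-event CSV with columns cycle_start, avc, mvo, cycle_end
    (optional e_end); one validated ValveEvents per row."""
    df = pd.read_csv(path)
    required = ["cycle_start", "avc", "mvo", "cycle_end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"valve-event table missing columns {missing}")
    events = []
    for _, row in df.iterrows():
        e_end = float(row["e_end"]) if "e_end" in df.columns and \
            np.isfinite(row.get("e_end", np.nan)) else None
        events.append(ValveEvents(cycle_start=float(row["cycle_start"]),
                                  avc_time=float(row["avc"]),
                                  mvo_time=float(row["mvo"]),
                                  cycle_end=float(row["cycle_end"]),
                                  e_end=e_end))
    return events


def write_valve_events(events: Sequence[ValveEvents], path) -> None:
    rows = [{"cycle_start": e.cycle_start, "avc": e.avc_time,
             "mvo": e.mvo_time, "cycle_end": e.cycle_end,
             "e_end": np.nan if e.e_end is None else e.e_end}
            for e in events]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


#: fixed float precision of the long-format output tables
TABLE_FLOAT_FORMAT = "%.10g"

METRICS_COLUMNS = ["animal_id", "day", "direction", "layer", "kind",
                   "segment_id", "metric", "signed", "abs"]


def write_metrics_table(metrics: Iterable[IVSIMetrics], path) -> None:
    """Write IVSI metrics as one long tab-separated table.

    Deterministic column order; an empty metric set produces a header-only
    file and logs a warning.
    """
    frames = []
    for m in metrics:
        t = m.table.copy()
        t.insert(0, "animal_id", m.animal_id)
        t.insert(1, "day", -1 if m.day is None else m.day)
        frames.append(t[METRICS_COLUMNS])
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        logger.warning("writing empty metrics table to %s", path)
        out = pd.DataFrame(columns=METRICS_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format=TABLE_FLOAT_FORMAT)


def read_metrics_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metrics table missing columns {missing}")
    return df


STATS_COLUMNS = ["metric", "effect", "estimate", "ci_low", "ci_high",
                 "statistic", "df", "p", "p_fdr", "method"]


def write_stats_table(results: Iterable[StatResult], path) -> None:
    """Write statistical results as a long tab-separated table."""
    rows = [{"metric": r.metric, "effect": r.effect, "estimate": r.estimate,
             "ci_low": r.ci_low, "ci_high": r.ci_high,
             "statistic": r.statistic, "df": r.df, "p": r.p_value,
             "p_fdr": np.nan if r.p_adjusted is None else r.p_adjusted,
             "method": r.method} for r in results]
    if not rows:
        logger.warning("writing empty stats table to %s", path)
    pd.DataFrame(rows, columns=STATS_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=TABLE_FLOAT_FORMAT)


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a long cohort CSV."""
    return validate_cohort_table(pd.read_csv(path))


def write_cohort_table(table: pd.DataFrame, path) -> None:
    validate_cohort_table(table).to_csv(path, index=False,
                                        float_format="%.17g")
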