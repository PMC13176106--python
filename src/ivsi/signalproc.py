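"""Filtering, differentiation, phase windowing, and IVSI metric extraction.

The processing chain mirrors how speckle-tracking strain exports are treated:
raw strain is smoothed once with a low-pass Butterworth filter (default
20 Hz, order 2), derivatives are taken by second-order central differences,
and extrema are read off inside valve-event-defined phase windows — above
all the isovolumic relaxation window [AVC, MVO], where the minimal
acceleration of the radial strain-rate curve is the headline diastolic
metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .core_io import (DomainError, IVSIMetrics, ParameterError,
                      PressureTrace, ResolutionError, StrainTrace,
                      ValveEvents, ConventionalEcho,
                      _DERIV_KIND, _DERIV_UNIT)

__all__ = [
    "FilterSpec", "PhaseWindow", "HemoMetrics", "butterworth_lowpass",
    "differentiate", "window_trace", "ivsi_extract", "peak_phase_metric",
    "hemodynamics", "conventional_ratios",
]


@dataclass
class FilterSpec:
    """Low-pass Butterworth filter settings.

    ``application="zero_phase"`` runs the filter forward and backward
    (no group delay, squared magnitude response); ``"single_pass"`` applies
    it once, matching a strict causal replication of instrument smoothing.
    """

    cutoff_hz: float = 20.0
    order: int = 2
    application: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ParameterError("cutoff must be positive")
        if self.application not in ("zero_phase", "single_pass"):
            raise ParameterError(
                f"unknown filter application {self.application!r}")


WINDOW_LABELS = ("ivrt", "early_diastole", "systole", "full_diastole")


@dataclass
class PhaseWindow:
    """A labelled sub-interval of the cardiac cycle (seconds)."""

    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.label not in WINDOW_LABELS:
            raise ParameterError(f"unknown window label {self.label!r}")
        if not self.t_start < self.t_end:
            raise ParameterError("window start must precede window end")


@dataclass
class HemoMetrics:
    """Pressure-derived indices: dP/dt extrema (mmHg/s) and Weiss tau (ms)."""

    dpdt_max: float
    dpdt_min: float
    tau_weiss: float

    def __post_init__(self) -> None:
        if not (self.dpdt_min < 0 < self.dpdt_max):
            raise DomainError("expected dpdt_min < 0 < dpdt_max")
        if not self.tau_weiss > 0:
            raise DomainError("tau_weiss must be positive")


# ---------------------------------------------------------------------------
# Filtering and differentiation
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=64)
def _butter_coeffs(order: int, cutoff_hz: float, fs: float):
    return sps.butter(order, cutoff_hz, btype="low", fs=fs)


def butterworth_lowpass(trace: StrainTrace,
                        spec: FilterSpec | None = None) -> StrainTrace:
    """Low-pass Butterworth smoothing on the trace's own grid.

    DC gain is 1; per pass the magnitude response follows
    ``|H(f)| = (1 + (f/fc)^(2*order))^(-1/2)`` up to bilinear-transform
    discretisation.  Zero-phase mode preserves feature timing.
    """
    spec = spec or FilterSpec()
    nyq = trace.sample_rate / 2.0
    if spec.cutoff_hz >= nyq:
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyq} Hz")
    b, a = _butter_coeffs(spec.order, spec.cutoff_hz, trace.sample_rate)
    if spec.application == "zero_phase":
        filtered = sps.filtfilt(b, a, trace.values)
    else:
        filtered = sps.lfilter(b, a, trace.values)
    return trace.with_values(filtered)


def differentiate(trace: StrainTrace) -> StrainTrace:
    """Time derivative by second-order central differences (one-sided,
    second-order stencils at the ends).  Advances the kind and unit tags
    (strain -> strain_rate -> acceleration; % -> %/s -> %/s^2)."""
    if trace.n < 3:
        raise ResolutionError("differentiation needs at least 3 samples")
    deriv = np.gradient(trace.values, trace.dt, edge_order=2)
    if trace.kind not in _DERIV_KIND:
        raise ParameterError(f"cannot differentiate a {trace.kind!r} trace")
    kind = _DERIV_KIND[trace.kind]
    unit = _DERIV_UNIT.get(trace.unit, f"({trace.unit})/s")
    return trace.with_values(deriv, kind=kind, unit=unit)


# ---------------------------------------------------------------------------
# Phase windows
# ---------------------------------------------------------------------------

def _window_bounds(events: ValveEvents, label: str) -> tuple[float, float]:
    if label == "ivrt":
        return events.avc_time, events.mvo_time
    if label == "systole":
        return events.cycle_start, events.avc_time
    if label == "full_diastole":
        return events.mvo_time, events.cycle_end
    if label == "early_diastole":
        # MVO to end of E-wave; without an annotated E-wave end, take 40% of
        # the filling period as a documented convention.
        e_end = events.e_end
        if e_end is None:
            e_end = events.mvo_time + 0.4 * (events.cycle_end
                                             - events.mvo_time)
        return events.mvo_time, e_end
    raise ParameterError(f"unknown window label {label!r}")


def window_trace(trace: StrainTrace, events: ValveEvents,
                 label: str = "ivrt") -> tuple[PhaseWindow, StrainTrace]:
    """Slice the closed window [t_start, t_end] out of a trace.

    Boundaries snap to the nearest samples (closed interval, so boundary
    samples are kept — the IVRT is short and dropping its edges biases the
    extrema).  Fewer than 3 samples in the window is a resolution error:
    the frame rate is too low to resolve the phase.
    """
    t_start, t_end = _window_bounds(events, label)
    if t_start < trace.time[0] - trace.dt or \
            t_end > trace.time[-1] + trace.dt:
        raise ParameterError(
            f"{label} window [{t_start:.4f}, {t_end:.4f}] s outside trace "
            f"span [{trace.time[0]:.4f}, {trace.time[-1]:.4f}] s")
    # the window must genuinely contain >= 3 sample instants, otherwise the
    # frame rate cannot resolve the phase
    tol = 1e-9 * trace.dt
    n_inside = int(np.count_nonzero((trace.time >= t_start - tol)
                                    & (trace.time <= t_end + tol)))
    if n_inside < 3:
        raise ResolutionError(
            f"{label} window contains {n_inside} samples at "
            f"{trace.sample_rate:.0f} Hz; need >= 3 (frame rate too low)")
    i0 = int(np.argmin(np.abs(trace.time - t_start)))
    i1 = int(np.argmin(np.abs(trace.time - t_end)))
    sub = StrainTrace(time=trace.time[i0:i1 + 1],
                      values=trace.values[i0:i1 + 1],
                      direction=trace.direction, layer=trace.layer,
                      segment_id=trace.segment_id, kind=trace.kind,
                      unit=trace.unit)
    return PhaseWindow(label=label, t_start=t_start, t_end=t_end), sub


# ---------------------------------------------------------------------------
# IVSI extraction
# ---------------------------------------------------------------------------

#: derivatives needed to reach the deformation's second derivative
_ACCEL_DERIVS = {"strain": 2, "strain_rate": 1, "velocity": 1}

_METRIC_NAMES = ("max_value", "min_value", "max_accel", "min_accel")


def _accel_of(trace: StrainTrace) -> StrainTrace:
    """Acceleration of a signal: d(rate)/dt, i.e. two derivatives of strain,
    one of strain rate or velocity."""
    if trace.kind not in _ACCEL_DERIVS:
        raise ParameterError(
            f"acceleration undefined for kind {trace.kind!r}")
    out = trace
    for _ in range(_ACCEL_DERIVS[trace.kind]):
        out = differentiate(out)
    return out


def ivsi_extract(traces: Iterable[StrainTrace], events: ValveEvents, *,
                 derive_rates: bool = True, animal_id: str = "",
                 day: int | None = None) -> IVSIMetrics:
    """Extract IVRT-windowed extrema for every input signal.

    For each signal: the maximal and minimal value inside the IVRT window,
    and the maximal and minimal acceleration (the signal differentiated to
    the deformation's second derivative *before* windowing, so window edges
    do not corrupt the stencils).  Signed values and their absolute values
    are both reported, per segment plus the unweighted across-segment mean
    of the per-segment values.  When ``derive_rates`` is true, each strain
    trace also contributes a derived strain-rate signal, so the headline
    metric — the minimal acceleration of the radial strain rate — is always
    available from strain-only input.
    """
    traces = list(traces)
    signals: list[StrainTrace] = []
    for tr in traces:
        signals.append(tr)
        if derive_rates and tr.kind == "strain":
            signals.append(differentiate(tr))
    rows = []
    for tr in signals:
        _, vals = window_trace(tr, events, "ivrt")
        accel = _accel_of(tr)
        _, acc = window_trace(accel, events, "ivrt")
        for metric, arr, fn in (("max_value", vals.values, np.max),
                                ("min_value", vals.values, np.min),
                                ("max_accel", acc.values, np.max),
                                ("min_accel", acc.values, np.min)):
            v = float(fn(arr))
            rows.append({"direction": tr.direction, "layer": tr.layer,
                         "kind": tr.kind, "segment_id": tr.segment_id,
                         "metric": metric, "signed": v, "abs": abs(v)})
    table = pd.DataFrame(rows)
    # unweighted mean of per-segment values (not the metric of the mean curve)
    mean = (table.groupby(["direction", "layer", "kind", "metric"],
                          as_index=False)[["signed", "abs"]].mean())
    mean["segment_id"] = "mean"
    table = pd.concat([table, mean[table.columns]], ignore_index=True)
    return IVSIMetrics(table=table, animal_id=animal_id, day=day)


def peak_phase_metric(trace: StrainTrace, events: ValveEvents,
                      label: str, statistic: str = "peak") -> float:
    """Peak of a signal inside a phase window.

    Diastolic windows return the signed extremum matching the relaxation
    sign convention (the most negative value); the systolic window returns
    the positive extremum.  ``statistic="mean"`` averages the window instead.
    """
    _, sub = window_trace(trace, events, label)
    if statistic == "mean":
        return float(np.mean(sub.values))
    if statistic != "peak":
        raise ParameterError(f"unknown statistic {statistic!r}")
    if label == "systole":
        return float(np.max(sub.values))
    return float(np.min(sub.values))


def average_peak(traces: Sequence[StrainTrace], events: ValveEvents,
                 label: str) -> float:
    """"Average peak": unweighted mean of per-segment peaks."""
    if not traces:
        raise ParameterError("no traces supplied")
    return float(np.mean([peak_phase_metric(tr, events, label)
                          for tr in traces]))


# ---------------------------------------------------------------------------
# Pressure-derived metrics
# ---------------------------------------------------------------------------

def hemodynamics(pressure: PressureTrace, events: ValveEvents) -> HemoMetrics:
    """dP/dt extrema over the full cycle and the Weiss relaxation constant.

    Weiss method: ordinary least squares of ln P on t over the isovolumic
    relaxation segment [AVC, MVO]; tau = -1/slope, reported in ms.  The
    log-linear fit makes tau invariant to pressure rescaling.
    """
    t = pressure.time
    dt = t[1] - t[0]
    dpdt = np.gradient(pressure.pressure, dt, edge_order=2)
    i0 = int(np.argmin(np.abs(t - events.avc_time)))
    i1 = int(np.argmin(np.abs(t - events.mvo_time)))
    if i1 - i0 + 1 < 3:
        raise ResolutionError("IVRT spans fewer than 3 pressure samples")
    seg = pressure.pressure[i0:i1 + 1]
    if np.any(seg <= 0):
        raise DomainError("non-positive pressure inside the Weiss fit window")
    fit = spstats.linregress(t[i0:i1 + 1], np.log(seg))
    if fit.slope >= 0:
        raise DomainError("pressure does not decay over the IVRT window")
    return HemoMetrics(dpdt_max=float(np.max(dpdt)),
                       dpdt_min=float(np.min(dpdt)),
                       tau_weiss=float(-1000.0 / fit.slope))


def conventional_ratios(echo: ConventionalEcho) -> dict:
    """Conventional calculated indices.

    FS = 100 (LVIDd - LVIDs)/LVIDd; LV volumes by the Teichholz formula
    V = 7.0/(2.4 + D) * D^3 (µL for D in mm); EF = 100 (Vd - Vs)/Vd;
    E/A and E/E' elementwise.
    """
    def teichholz(d: float) -> float:
        return 7.0 / (2.4 + d) * d ** 3

    vd, vs = teichholz(echo.lvidd), teichholz(echo.lvids)
    return {
        "FS": 100.0 * (echo.lvidd - echo.lvids) / echo.lvidd,
        "EF": 100.0 * (vd - vs) / vd,
        "LV_Vold": vd,
        "LV_Vols": vs,
        "E_A": echo.e_wave / echo.a_wave,
        "E_Eprime": echo.e_wave / echo.e_prime,
    }
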