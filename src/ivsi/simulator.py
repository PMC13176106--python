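"""Parametric murine cardiac-cycle simulator.

Generates synthetic per-segment strain (and velocity) traces, valve events,
and left-ventricular pressure for one cardiac cycle, plus longitudinal
sham-vs-TAC cohorts, so the whole IVSI pipeline is testable without
instrument data.

Model sketch (one cycle of length T = 60/HR, radial strain, one segment):

* systole: strain rises 0 -> peak along a cosine ramp ending at the
  relaxation onset t0, a few ms before aortic valve closure (AVC);
* relaxation: from t0, strain decays as ``peak * exp(-g(u)/tau)`` with the
  smooth onset ``g(u) = u - b*(1 - exp(-u/b))`` (g(0)=g'(0)=0, g -> u - b),
  so the decay is asymptotically exponential with time constant ``tau``
  through the IVRT and E-wave and the strain-rate acceleration is smooth
  across the IVRT window;
* the E-wave is a raised-cosine taper of the decay to zero after mitral
  valve opening (MVO), strain is zero through diastasis, and a small
  sin^2 atrial-kick bump returns to zero at the cycle end — the curve is
  C^1-periodic;
* longitudinal strain mirrors the radial curve in sign at reduced amplitude;
  endocardial gain exceeds epicardial gain; per-segment multiplicative gains
  model segment heterogeneity.

``tau`` (``tau_active``) is the active-relaxation time constant, the
simulator's stand-in for impaired sarcoplasmic Ca2+ reuptake; pressure decays
as ``P_avc * exp(-u/tau)`` during isovolumic relaxation, so the Weiss method
applied to the pressure trace recovers ``tau`` exactly.  TAC (pressure
overload) is modelled as a prolongation of ``tau``, with an optional
peak-strain reduction for late-stage disease.  No quantitative relaxation
kinetics for TAC mice exist to calibrate against; the defaults below are
physiologically plausible stand-ins and are documented as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (ParameterError, StrainTrace, ValveEvents, PressureTrace,
                      write_trace_table, write_valve_events,
                      validate_cohort_table)

__all__ = [
    "CycleParams", "CohortParams", "SimulatedCycle", "SimulatedCohort",
    "simulate_cycle", "simulate_cohort", "write_cohort",
    "simulate_linear_cohort", "closed_form_radial_strain",
]

#: minimum frame rate (Hz) for resolving the murine IVRT window
MIN_FRAME_RATE = 200.0


@dataclass
class CycleParams:
    """Parameters of one simulated cardiac cycle.

    Defaults describe an anaesthetised mouse at 420 bpm imaged at 1000
    frames/s with an 18 ms IVRT.  Phase fractions are fractions of the cycle
    length; ``a_wave_frac=None`` means "remainder of the cycle".
    """

    heart_rate: float = 420.0          # bpm
    frame_rate: float = 1000.0         # Hz, must exceed MIN_FRAME_RATE
    peak_radial_strain: float = 25.0   # %, positive (systolic thickening)
    ivct_frac: float = 0.07
    ejection_frac: float = 0.35
    ivrt_ms: float = 18.0
    e_wave_frac: float = 0.21
    diastasis_frac: float = 0.13
    a_wave_frac: float | None = None   # None -> remainder
    tau_active: float = 12.0           # ms, active-relaxation time constant
    relax_onset_lead_ms: float = 3.0   # relaxation onset before AVC
    relax_blend_ms: float = 5.0        # smooth-onset blend constant b
    a_wave_amp_frac: float = 0.06      # atrial-kick amplitude / peak strain
    longitudinal_scale: float = -0.6   # longitudinal amplitude relative to radial
    layer_gains: dict = field(default_factory=lambda: {"endocardial": 1.0,
                                                       "epicardial": 0.8})
    segment_gains: tuple = (1.06, 0.97, 1.10, 0.92, 1.02, 0.95)
    noise_sd: float = 0.5              # additive Gaussian sigma on strain (%)
    # pressure model (mmHg)
    p_max: float = 90.0
    p_avc: float = 60.0
    p_ed: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= MIN_FRAME_RATE:
            raise ParameterError(
                f"frame_rate must exceed {MIN_FRAME_RATE} Hz to resolve IVRT")
        if self.tau_active <= 0:
            raise ParameterError("tau_active must be positive")
        if self.peak_radial_strain <= 0:
            raise ParameterError("peak_radial_strain must be positive")
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate must be positive")
        fr = (self.ivct_frac + self.ejection_frac + self.ivrt_frac
              + self.e_wave_frac + self.diastasis_frac)
        if self.a_wave_frac is None:
            rem = 1.0 - fr
            if rem <= 0:
                raise ParameterError("phase fractions exceed the cycle length")
            self.a_wave_frac = rem
        elif abs(fr + self.a_wave_frac - 1.0) > 1e-9:
            raise ParameterError(
                f"phase fractions sum to {fr + self.a_wave_frac:.6f}, not 1")

    @property
    def cycle_length(self) -> float:
        """Cycle length in seconds (60 / heart rate)."""
        return 60.0 / self.heart_rate

    @property
    def ivrt_frac(self) -> float:
        return self.ivrt_ms / 1000.0 / self.cycle_length

    def valve_events(self) -> ValveEvents:
        T = self.cycle_length
        avc = (self.ivct_frac + self.ejection_frac) * T
        mvo = avc + self.ivrt_ms / 1000.0
        return ValveEvents(cycle_start=0.0, avc_time=avc, mvo_time=mvo,
                           cycle_end=T, e_end=mvo + self.e_wave_frac * T)


def closed_form_radial_strain(t: np.ndarray, p: CycleParams,
                              gain: float = 1.0) -> np.ndarray:
    """Noiseless radial strain (%) for one segment at times ``t`` (seconds).

    This is the analytic kinematic model the simulator samples; evaluating it
    on a dense grid is the reference for pipeline-vs-oracle tests.
    """
    t = np.asarray(t, dtype=float)
    T = p.cycle_length
    ev = p.valve_events()
    tau = p.tau_active / 1000.0
    b = p.relax_blend_ms / 1000.0
    t0 = ev.avc_time - p.relax_onset_lead_ms / 1000.0
    if t0 <= 0:
        raise ParameterError("relaxation onset before cycle start")
    peak = p.peak_radial_strain * gain
    t_e = ev.e_end
    a0 = t_e + p.diastasis_frac * T
    s = np.zeros_like(t)

    m = t <= t0
    s[m] = peak * 0.5 * (1.0 - np.cos(np.pi * t[m] / t0))

    m = t > t0
    u = t[m] - t0
    g = u - b * (1.0 - np.exp(-u / b))
    decay = peak * np.exp(-g / tau)
    taper = np.ones_like(u)
    tt = t[m]
    sel = (tt > ev.mvo_time) & (tt <= t_e)
    taper[sel] = 0.5 * (1.0 + np.cos(np.pi * (tt[sel] - ev.mvo_time)
                                     / (t_e - ev.mvo_time)))
    taper[tt > t_e] = 0.0
    s[m] = decay * taper

    sel = t > a0
    s[sel] += (p.a_wave_amp_frac * peak
               * np.sin(np.pi * (t[sel] - a0) / (T - a0)) ** 2)
    return s


def _pressure_curve(t: np.ndarray, p: CycleParams) -> np.ndarray:
    """Noiseless LV pressure (mmHg): cosine systolic rise/fall around an
    ejection peak, exact exponential isovolumic decay from AVC, raised-cosine
    settling to end-diastolic pressure after MVO."""
    T = p.cycle_length
    ev = p.valve_events()
    tau = p.tau_active / 1000.0
    t_pk = p.ivct_frac * T + 0.5 * p.ejection_frac * T
    out = np.empty_like(t)

    m = t <= t_pk
    out[m] = p.p_ed + (p.p_max - p.p_ed) * 0.5 * (
        1.0 - np.cos(np.pi * t[m] / t_pk))
    m = (t > t_pk) & (t <= ev.avc_time)
    out[m] = p.p_avc + (p.p_max - p.p_avc) * 0.5 * (
        1.0 + np.cos(np.pi * (t[m] - t_pk) / (ev.avc_time - t_pk)))
    # isovolumic relaxation: P = P_avc * exp(-u/tau) (Weiss-exact)
    m = (t > ev.avc_time) & (t <= ev.mvo_time)
    out[m] = p.p_avc * np.exp(-(t[m] - ev.avc_time) / tau)
    # filling: settle from P(MVO) to end-diastolic pressure
    p_mvo = p.p_avc * np.exp(-ev.ivrt / tau)
    m = t > ev.mvo_time
    frac = (t[m] - ev.mvo_time) / (T - ev.mvo_time)
    out[m] = p.p_ed + (p_mvo - p.p_ed) * 0.5 * (1.0 + np.cos(np.pi * frac))
    return out


@dataclass
class SimulatedCycle:
    """One simulated beat: traces, valve events, pressure, and parameters."""

    traces: list
    events: ValveEvents
    pressure: PressureTrace
    params: CycleParams


def simulate_cycle(params: CycleParams | None = None, *,
                   directions: Sequence[str] = ("radial", "longitudinal"),
                   layers: Sequence[str] = ("endocardial", "epicardial"),
                   kinds: Sequence[str] = ("strain",),
                   rng: np.random.Generator | None = None) -> SimulatedCycle:
    """Simulate one cardiac cycle sampled at ``frame_rate`` over [0, T).

    Emits one strain trace per direction x layer x segment (and optionally
    a velocity trace, proportional to the strain rate of a 2 mm wall).
    With ``noise_sd=0`` the samples equal the closed-form kinematics; the
    same seed yields bit-identical output.
    """
    p = params or CycleParams()
    if rng is None:
        rng = np.random.default_rng(p.seed)
    T = p.cycle_length
    dt = 1.0 / p.frame_rate
    n = int(round(T / dt))
    t = np.arange(n) * dt
    ev = p.valve_events()
    traces = []
    wall_mm = 2.0  # nominal wall dimension converting strain rate to mm/s
    for direction in directions:
        dir_scale = 1.0 if direction == "radial" else p.longitudinal_scale
        for layer in layers:
            lg = p.layer_gains.get(layer, 1.0)
            for seg, sg in enumerate(p.segment_gains, start=1):
                base = closed_form_radial_strain(t, p, gain=dir_scale * lg * sg)
                noisy = base
                if p.noise_sd > 0:
                    noisy = base + rng.normal(0.0, p.noise_sd, n)
                if "strain" in kinds:
                    traces.append(StrainTrace(
                        time=t, values=noisy, direction=direction,
                        layer=layer, segment_id=seg, kind="strain", unit="%"))
                if "velocity" in kinds:
                    vel = np.gradient(noisy, dt, edge_order=2) * wall_mm / 100.0
                    traces.append(StrainTrace(
                        time=t, values=vel, direction=direction, layer=layer,
                        segment_id=seg, kind="velocity", unit="mm/s"))
    pressure = PressureTrace(time=t, pressure=_pressure_curve(t, p))
    return SimulatedCycle(traces=traces, events=ev, pressure=pressure,
                          params=p)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Longitudinal sham-vs-TAC cohort design.

    TAC animals carry a prolonged active-relaxation constant
    (``tau_tac``, optionally growing by ``tau_tac_day_slope`` ms/day) and an
    optional late-stage peak-strain reduction.  Each animal receives a
    Gaussian random offset on tau (``animal_tau_sd``), constant across days
    (the between-animal random intercept).
    """

    n_per_group: int = 10
    days: tuple = tuple(range(1, 15))
    tau_sham: float = 12.0             # ms
    tau_tac: float = 24.0              # ms
    tau_tac_day_slope: float = 0.0     # ms per postoperative day
    animal_tau_sd: float = 1.0         # ms, between-animal SD
    tac_peak_strain_scale: float = 1.0  # late-stage systolic decline if < 1
    seed: int = 0
    cycle: CycleParams = field(default_factory=CycleParams)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ParameterError("need at least 2 animals per group")
        if self.tau_sham <= 0 or self.tau_tac <= 0:
            raise ParameterError("tau values must be positive")
        if not self.days:
            raise ParameterError("need at least one postoperative day")


@dataclass
class SimulatedCohort:
    """Simulated animal-day records plus the latent ground truth."""

    records: list               # dicts: animal_id, group, day, cycle
    ground_truth: dict          # every latent parameter, JSON-serialisable
    skeleton: pd.DataFrame      # animal_id, group, day rows (metrics unfilled)


def simulate_cohort(params: CohortParams | None = None, *,
                    directions: Sequence[str] = ("radial", "longitudinal"),
                    layers: Sequence[str] = ("endocardial",),
                    kinds: Sequence[str] = ("strain",)) -> SimulatedCohort:
    """Simulate every animal x day of a sham/TAC cohort (deterministic under
    ``params.seed``)."""
    p = params or CohortParams()
    rng = np.random.default_rng(p.seed)
    records = []
    truth_animals = []
    rows = []
    for group, tau0 in (("sham", p.tau_sham), ("TAC", p.tau_tac)):
        for i in range(p.n_per_group):
            animal_id = f"{group.lower()}{i + 1:02d}"
            tau_offset = float(rng.normal(0.0, p.animal_tau_sd))
            truth_animals.append({"animal_id": animal_id, "group": group,
                                  "tau_base": tau0, "tau_offset": tau_offset})
            for day in p.days:
                tau = tau0 + tau_offset
                peak_scale = 1.0
                if group == "TAC":
                    tau += p.tau_tac_day_slope * day
                    peak_scale = p.tac_peak_strain_scale
                cycle_params = replace(
                    p.cycle, tau_active=max(tau, 1.0),
                    peak_radial_strain=p.cycle.peak_radial_strain * peak_scale,
                    seed=p.cycle.seed)
                cyc = simulate_cycle(cycle_params, directions=directions,
                                     layers=layers, kinds=kinds, rng=rng)
                records.append({"animal_id": animal_id, "group": group,
                                "day": int(day), "cycle": cyc})
                rows.append({"animal_id": animal_id, "group": group,
                             "day": int(day)})
    truth = {"params": {k: v for k, v in asdict(p).items() if k != "cycle"},
             "cycle_params": asdict(p.cycle),
             "animals": truth_animals,
             "tau_group_difference": p.tau_tac - p.tau_sham}
    return SimulatedCohort(records=records, ground_truth=truth,
                           skeleton=pd.DataFrame(rows))


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict:
    """Write a simulated cohort to disk in the core_io dialects.

    Layout: ``<animal>_day<d>_traces.csv`` and ``..._events.csv`` per
    animal-day, ``cohort.csv`` metadata, ``ground_truth.json``.  Returns a
    manifest mapping artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for rec in cohort.records:
        stem = f"{rec['animal_id']}_day{rec['day']:02d}"
        tpath = out / f"{stem}_traces.csv"
        epath = out / f"{stem}_events.csv"
        write_trace_table(rec["cycle"].traces, tpath)
        write_valve_events([rec["cycle"].events], epath)
        manifest[f"{stem}_traces"] = str(tpath)
        manifest[f"{stem}_events"] = str(epath)
    meta = cohort.skeleton.copy()
    meta_path = out / "cohort.csv"
    meta.to_csv(meta_path, index=False)
    manifest["cohort"] = str(meta_path)
    gt_path = out / "ground_truth.json"
    gt_path.write_text(json.dumps(cohort.ground_truth, indent=2))
    manifest["ground_truth"] = str(gt_path)
    return manifest


def simulate_linear_cohort(*, n_per_group: int = 10,
                           days: Sequence[int] = tuple(range(1, 15)),
                           intercept: float = 0.0,
                           group_effect: float = -0.14,
                           day_slope: float = -0.004,
                           intercept_sd: float = 0.02,
                           resid_sd: float = 0.02,
                           metric_name: str = "metric",
                           rng: np.random.Generator | None = None,
                           seed: int = 0) -> pd.DataFrame:
    """Response-level longitudinal generator for statistical calibration.

    y = intercept + group_effect*[TAC] + day_slope*day + b_animal + e, with
    b ~ N(0, intercept_sd^2) per animal and e ~ N(0, resid_sd^2) per row.
    Returns a validated long cohort table.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    days = list(days)
    for group in ("sham", "TAC"):
        g = 1.0 if group == "TAC" else 0.0
        for i in range(n_per_group):
            b = rng.normal(0.0, intercept_sd)
            e = rng.normal(0.0, resid_sd, len(days))
            for d, eps in zip(days, e):
                rows.append({"animal_id": f"{group.lower()}{i + 1:02d}",
                             "group": group, "day": int(d),
                             "metric_name": metric_name,
                             "value": intercept + group_effect * g
                             + day_slope * d + b + eps})
    return validate_cohort_table(pd.DataFrame(rows))
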