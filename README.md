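# ivsi — isovolumic relaxation strain imaging

`ivsi` is a Python toolkit for quantifying **active diastolic dysfunction**
from speckle-tracking echocardiography strain exports, aimed at murine
pressure-overload studies (sham vs. transverse aortic constriction, TAC).

Early diastolic impairment is driven by slowed active relaxation
(sarcoplasmic Ca²⁺ reuptake), which conventional indices such as E/A and
E/E′ can miss or pseudonormalize. The isovolumic relaxation time (IVRT) —
the interval from aortic valve closure (AVC) to mitral valve opening (MVO)
— isolates active relaxation from filling, and the deformation signal
inside that window carries the earliest signature of disease. The package:

* reads per-segment strain/velocity traces (wide CSV, one column per
  `direction_layer_segK_kind`) and valve-event tables;
* smooths raw strain with a low-pass Butterworth filter (default 20 Hz,
  order 2; zero-phase or single-pass) and differentiates by second-order
  central differences;
* extracts, inside the IVRT window, the maximal/minimal value and
  maximal/minimal acceleration of each signal (strain, strain rate,
  velocity), per segment and segment-averaged, signed and absolute —
  the headline metric being **|min acceleration of radial strain rate|**,
  i.e. |min d(SR)/dt| over [AVC, MVO];
* computes pressure-derived references (dP/dt extrema, Weiss tau from the
  log-linear fit of isovolumic pressure decay) and conventional ratios
  (FS, Teichholz EF, E/A, E/E′);
* runs the statistics layer: Welch t-tests per day, linear mixed-effects
  models `value ~ group + day + (1 | animal)` fitted by REML with
  Satterthwaite degrees of freedom, Benjamini–Hochberg FDR, Cohen's d with
  exact noncentral-t sample-size calculation, ICC(A,1) and Bland–Altman
  agreement;
* ships a parametric murine cardiac-cycle simulator (420 bpm, 18 ms IVRT,
  exponential active relaxation with time constant τ) that generates
  single beats and full longitudinal sham/TAC cohorts, so the entire
  pipeline is testable without instrument data.

## Worked example

Simulate a small cohort (6 animals/group, days 1/4/7, TAC τ = 24 ms vs
sham 12 ms), extract the headline metric, and fit the longitudinal model:

```python
import ivsi
from ivsi.pipeline import process_cohort, DEFAULT_PANEL, panel_metric_name
from ivsi.stats import welch_by_day

params = ivsi.CohortParams(n_per_group=6, days=(1, 4, 7), seed=1)
cohort = ivsi.simulate_cohort(params, directions=("radial",),
                              layers=("endocardial",))
metrics, table = process_cohort(cohort.records, ivsi.FilterSpec(),
                                [DEFAULT_PANEL[0]])
name = panel_metric_name(DEFAULT_PANEL[0])
day4 = welch_by_day(table, name)[4]
print(f"day 4 Welch: diff={day4.estimate:.1f} %/s^2, t={day4.statistic:.2f}, "
      f"df={day4.df:.1f}, p={day4.p_value:.2e}")
for r in ivsi.fit_lmm(table, ivsi.LMMSpec(metric_name=name)):
    print(f"LMM {r.effect:11s} beta={r.estimate:10.2f}  "
          f"CI=({r.ci_low:.2f}, {r.ci_high:.2f})  df={r.df:.1f}  "
          f"p={r.p_value:.2e}")
```

Output:

```
day 4 Welch: diff=7914.5 %/s^2, t=18.30, df=10.0, p=5.24e-09
LMM intercept   beta=  51351.46  CI=(50634.15, 52068.76)  df=13.4  p=3.55e-23
LMM group[TAC]  beta=  -8167.51  CI=(-9160.97, -7174.05)  df=11.7  p=7.12e-10
LMM day         beta=     41.48  CI=(-3.27, 86.22)  df=26.1  p=6.78e-02
```

The Welch difference (sham − TAC) is positive: doubling τ lowers
|min accel of radial strain rate| in every TAC animal, and the mixed model
attributes a strongly negative group effect to TAC with a Satterthwaite df
close to the number of animals, as it should for a between-animal contrast.

A CLI wraps the same stages:

```bash
ivsi simulate --out sim/ --seed 1
ivsi process --traces sim/ --events sim/sham01_day04_events.csv \
             --filter-cutoff 20 --filter-order 2 --out metrics.tsv
ivsi stats --cohort cohort.csv --out stats.tsv
ivsi run --config run.yaml --out out/     # all-in-one, writes manifest.json
```

## Layout

```
src/ivsi/core_io.py     data model (traces, events, metrics, results) + CSV/TSV I/O
src/ivsi/simulator.py   cardiac-cycle and cohort simulator (closed-form kinematics)
src/ivsi/signalproc.py  filtering, differentiation, windowing, metric extraction
src/ivsi/stats.py       Welch/power/LMM-Satterthwaite/FDR/ICC/Bland–Altman
src/ivsi/pipeline.py    simulate → process → stats orchestration, manifest
src/ivsi/cli.py         `ivsi` command-line interface
docs/methods.md         model, assumptions, parameter choices, limitations
```
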