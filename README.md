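# mepkit

Scriptable analysis of **motor evoked potentials (MEPs)** and **stimulus–
response (recruitment) curves** for EMG electrophysiology: session
annotation and validation, epoch preprocessing, MEP quantification,
sigmoidal curve fitting, and comparison of recruitment curves across
experimental conditions and subjects — plus a synthetic-data generator so
the entire pipeline can be exercised and tested without any recordings.

## Who this is for

Labs that probe corticospinal or spinal excitability by stimulating at a
range of intensities (TMS, epidural cortical stimulation, spinal
stimulation, …) and recording evoked EMG responses. A *session* is one full
intensity sweep under one condition; a *record* collects the sessions of one
subject (the first session is always the baseline); a *master* groups
records across subjects that share the same condition sequence.

## The model

MEP magnitude *y* vs. stimulation intensity *x* follows a bounded sigmoid
(a two-state Boltzmann / generalized logistic):

```
y(x) = P + (M − P) / (1 + Q·exp(−e^L·(x − K)))
```

with lower asymptote *P*, upper asymptote (saturation) *M*, logarithmic
slope *L* (growth rate `e^L` per intensity unit), location *K* and a fixed
shape constant *Q* taken from the lowest-intensity response. The four free
parameters (*P, M, L, K*) are estimated by iterated Nelder–Mead from
heuristic initial values; the fit stops when the normalized error (residual
RMSE / data range) falls below a tolerance (default 0.1), when a round
improves the error by less than 0.01, or after 10 consecutive
non-improving rounds. Goodness of fit is reported as R², and a
least-squares line through the last three normalized points flags
non-saturated curves (slope ≥ 0.2 raises a warning).

Each trial is reduced to a scalar by one of four metrics: **AUC**
(trapezoidal integral of the rectified epoch), **RMS**, **peak-to-peak**,
or **latency** (time to a threshold crossing referenced to baseline).
Fitted curves are compared by three metrics, each normalized to the
baseline curve: **MEP%** (a vertical cut: responses at the intensity where
the baseline reaches M% of its maximum), **Stim%** (a horizontal cut:
intensities needed to match the baseline response at S% of maximum
stimulation), and **slope** (regression slope of the near-linear
mid-segment). Group results are means ± standard errors across subjects.

## Worked example

Simulate a four-subject study in which a conditioning stimulus shifts the
recruitment curve leftward (conditions `scs_9ms`…`scs_11ms` vs. baseline),
then quantify (peak-to-peak), fit and compare:

```
$ mepkit simulate --intensities 9 --trials 5 --seed 42 -o session.h5
$ mepkit fit session.h5 --metric p2p -o out
wrote out/rec_curve.csv and out/fit.json (R^2 = 0.9993, error = 0.0102)

$ mepkit analyze study/master.json --metric all -o results
MEP50:
  baseline: 100.00 +/- 0.00
  scs_9ms: 120.12 +/- 0.63
  scs_10ms: 143.63 +/- 0.18
  scs_11ms: 163.77 +/- 1.11
STIM50:
  baseline: 100.00 +/- 0.00
  scs_9ms: 89.51 +/- 0.65
  scs_10ms: 78.51 +/- 0.52
  scs_11ms: 67.02 +/- 1.00
SLOPE:
  baseline: 1.00 +/- 0.00
  scs_9ms: 1.08 +/- 0.03
  scs_10ms: 1.17 +/- 0.03
  scs_11ms: 1.16 +/- 0.03
```

Reading the numbers: at the intensity that evokes 50% of the baseline's
maximal MEP, the conditioned curves respond 20–64% more strongly (MEP50 >
100); they need 10–33% less stimulation to match the baseline response
(Stim50 < 100); and their recruitment slopes are up to 17% steeper. The
`results/` directory holds the same numbers as `bar_data.csv`, the full
per-trial and per-intensity tables, fitted-curve samples, an HDF5 results
bundle and a `diagnostics.json` with fit parameters and warnings.

The same operations are available as library functions
(`mepkit.quantify_session`, `mepkit.fit_sigmoid`, `mepkit.mep_metric`, …);
the CLI is a thin wrapper.

## Acceptance script

`scripts/acceptance.py` re-measures the toolbox's documented optimizer
behavior from scratch — it runs the curve fitter on data the objective
cannot improve and counts the consecutive non-improving optimizer rounds
before termination:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/mepkit/
  data_model.py   sessions, records, masters, validation, I/O (MAT/HDF5/CSV/JSON)
  preprocess.py   epoch extraction, zero-phase band-pass + notch, screening
  quantify.py     AUC / RMS / peak-to-peak / latency, per-intensity means
  curvefit.py     sigmoid model, initial estimates, Nelder-Mead fit, R², saturation
  analyze.py      MEP% / Stim% / slope metrics, group aggregation
  synth.py        ground-truth synthetic session generator
  cli.py          `mepkit` command-line interface
docs/methods.md   modelling and numerical details
```
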