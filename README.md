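# mandown

Man-down-situation (MDS) detection from wearable 6-DOF inertial
measurements.

Workers in mining, forestry, construction or fire-fighting often operate
alone; when an accident or sudden illness leaves them unconscious or
incapacitated, an automatic alarm is the only way help gets called.  A
single cue — detecting just falls, or just immobility — either misses
emergencies or drowns the control centre in false alarms.  This toolkit
implements a combinatorial strategy instead: it detects three *critical
states* from a body-worn accelerometer + gyroscope and declares a man-down
situation only when at least two of them co-occur within a time window.

- **F (fall):** free-fall dip in the acceleration norm, an impact spike and
  a rapid change of body inclination;
- **I (immobility):** sustained low variance of movement signals;
- **D (down):** near-horizontal body tilt.

## Method

From a calibrated recording, four physical signals are derived: the
acceleration norm `A(t) = ‖a(t)‖` (g), the rotational-speed norm
`W(t) = ‖ω(t)‖` (rad/s), the tilt angle `ρ(t) = arccos(g·v)` between the
device vertical `v = q* g q` (from a gradient-descent quaternion
orientation filter) and gravity, and its derivative `ρ̇(t)`.

Detection variables are *extreme-value signals*: sliding-window minima or
maxima of windowed means (fall, down) or windowed log10-variances
(immobility) of these signals, e.g. `E_Ā^min(t, τ) = min(Ā[t, t+τ])`.
Their distributions over critical-state occurrences are modelled with a
normal or Gumbel (type-I extreme-value) law — the family chosen by the
sign of the log ratio of maximized likelihoods — and each feature's density
is normalized by its analytic maximum so it contributes a weight in (0, 1].
The fall likelihood is the product over four features of the *maximum*
weight inside a fusion window; the immobility likelihood is the product
over three features of the *mean* weight (the state is sustained, not
transient); the down state thresholds the tilt extreme directly.
Thresholds `γ_F`, `γ_I` are trained by maximizing the Matthews correlation
coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

at scenario level, and `γ_D` fixes the miss rate at 1 % on state-positive
scenarios.  Pairwise combinatorial states apply a windowed AND-over-ANY,

    y_FD(t) = ⋁ y_F[t, t+τ_FD] ∧ ⋁ y_D[t, t+τ_FD]    (same for F-I, I-D)

and the man-down decision is their inclusive OR.  A seeded scenario
simulator (walks, bends, sits, jumps, crawls, falls with configurable
outcomes, slow collapses) provides labelled corpora with ground-truth
state intervals so the entire chain is testable without recorded data.

## Worked example

```python
from mandown import (generate_corpus, kfold_cv, train_detector_bank,
                     run_pipeline, compute_features)

recs, manifest = generate_corpus(n_adl=40, n_mds=40, seed=1)
cv = kfold_cv(recs, k=5, seed=42)
print(cv.summary[["pd_mean", "pfa_mean", "mcc_mean", "accuracy_mean"]].round(3))
```

```
       pd_mean  pfa_mean  mcc_mean  accuracy_mean
state
D        0.675      0.10     0.597          0.788
F        0.650      0.15     0.511          0.750
I        0.975      0.25     0.747          0.862
MDS      1.000      0.00     1.000          1.000
```

The F/I/D rows score each critical state *used alone* as the man-down
alarm against the MDS labels: each one either misses emergencies that do
not exhibit its state (a slow collapse has no fall) or fires on harmless
activities (sitting still is immobile, crawling is horizontal, a fall with
recovery is still a fall).  Fusing them removes every false alarm while
keeping full detection — the core claim of the method.  Training on the
same corpus and inspecting one collapse scenario:

```python
bank, _ = train_detector_bank(recs)
rec = next(r for r in recs if r.label == "slow_collapse")
result = run_pipeline(compute_features(rec), bank)
print(result.state_verdicts())
# {'F': False, 'I': True, 'D': True, 'F-D': False, 'F-I': False,
#  'I-D': True, 'MDS': True}
```

The worker never fell, so F and both fall pathways stay silent, but
immobility and down co-occur within the I-D window and the alarm fires.

The same flow is available from the shell:

```sh
mandown simulate --out corpus --n-adl 92 --n-mds 24 --seed 0
mandown train    --corpus corpus --out bank.yaml
mandown detect   --bank bank.yaml --corpus corpus --out detections
mandown evaluate --verdicts detections/verdicts.csv \
                 --labels corpus/manifest.csv --out metrics.csv
```

## Layout

| module | contents |
| --- | --- |
| `mandown.io_formats` | raw-count text dialect + native CSV/YAML recordings |
| `mandown.imu_core` | sensor calibration, orientation filter, feature signals |
| `mandown.features` | windowed statistics and extreme-value signals |
| `mandown.statmodels` | normal/Gumbel MLE fits, RML selection, normalized densities |
| `mandown.detectors` | F/I/D detectors, combinatorial fusion, MDS decision |
| `mandown.training_eval` | confusion metrics, MCC training, k-fold CV |
| `mandown.synthetic_data` | seeded scenario simulator with ground truth |
| `mandown.cli` | `mandown simulate / train / detect / evaluate` |

See `docs/methods.md` for modelling details, parameter defaults and known
limitations.
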