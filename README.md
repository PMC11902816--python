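# emgintent

Prediction of **non-cyclic upper-body motion intent** from six-channel
surface electromyography (sEMG), for researchers in myoelectric control
and human–robot interaction. Leader–follower exoskeleton control lags the
wearer; because a muscle's electrical activation precedes its mechanical
motion by the electromechanical delay (EMD, here taken as 50–190 ms), a
classifier that identifies the impending motion from early myoelectric —
or even pre-activation — signal content can, in principle, close that lag.

The package implements two complementary analyses over 12 motion classes
(6 motion types × 2 magnitudes):

1. **Change-point / slope-feature KNN.** Raw sEMG is conditioned
   (zero-phase 4th-order Butterworth bandstop 58–61 Hz → mean removal →
   bandpass 25–250 Hz → moving-RMS envelope), then change points are
   found by minimizing

       cost({i_k}) = Σ_k 1 / (|RMS_after(i_k) − RMS_before(i_k)| + ε)

   exactly (dynamic programming over a candidate grid, with the
   random-restart scheme as an option) while sweeping the number of
   points n. The OLS slope of the envelope at each change point, per
   muscle, forms a 12-entry feature vector classified by KNN and
   evaluated with leave-one-subject-out cross-validation; hyperparameters
   (k, distance metric, vote weighting) are tuned by Gaussian-process
   Bayesian optimization with the Expected Improvement acquisition
   EI = (best − μ)Φ(z) + σφ(z).

2. **Rolling-window neural classifier.** Raw channels are cut into 150 ms
   rolling windows, reduced to six per-channel least-squares slopes, and
   fed to a seven-layer feed-forward network that emits P(class) per
   window. A trial's *confident onset* (first sustained strict dominance
   of the true class) is compared against the detected myoelectric change
   point to yield a signed **lead time** — positive when the network
   predicts the motion before the EMG change point.

No recordings for this protocol are publicly deposited, so the package
includes a first-class synthetic generator (`emgintent.synth`) emulating
the protocol: six named muscles, 1 kHz sampling, five-burst recordings,
60 Hz mains, 25–250 Hz myoelectric bursts shaped by per-class synergy
patterns, uniform 50–190 ms EMD ground truth, and an optional 50 ms
quasi-DC pre-activation ramp on agonist channels (the feature that makes
anticipation possible). See `docs/methods.md` for the full model.

## Worked example

```python
from emgintent import study

# Change-point localization on 100 five-burst recordings
loc = study.localization_study(seed=1, n_recordings=100)
print(loc)   # {'mean_abs_offset_ms': 6.91, 'n_onsets': 500}

# KNN pipeline on 6 synthetic subjects x 12 classes x 25 motion trials
res = study.knn_study(seed=1)
print(res.default_accuracy_pct, res.optimized_accuracy_pct, res.best_config)
# 99.44 99.72 KNNConfig(k=6, metric='cityblock', weighting='uniform')

# Rolling-window network lead times
lead = study.lead_time_study(seed=1)
print(lead.mean_lead_ms, lead.n_confident, lead.n_test_trials)
# 25.4 48 48
```

Reading the numbers: detected change points sit 6.9 ms from the true
myoelectric onsets on average (the detector keys on local-RMS contrast,
so it lands just inside the activation rise); subject-wise 6-fold CV
accuracy is 99.4 % with the default KNN (k = 10, Euclidean) and 99.7 %
after 30 iterations of Bayesian optimization on this class-separable
synthetic dataset; and the network's confident predictions precede the
detected EMG change point by 25.4 ms on average over 48 confident
held-out trials — more than the change-point localization error, and on
top of the 50–190 ms EMD margin to physical motion.

The same stages are scriptable from a shell:

```bash
emgintent simulate --subjects 2 --trials-per-class 5 --seed 1 --out data/
emgintent changepoints --in data/ --out features.csv
emgintent knn --in data/ --optimize --budget 30 --seed 1 --report out/
emgintent dnn-leadtime --seed 1 --out leads.csv
emgintent report --leads leads.csv --out lead_table.csv
```

## Layout

```
src/emgintent/
  types.py        motion classes, subject profiles, trials, ground truth
  synth.py        synthetic sEMG generator (study conditions)
  sigproc.py      zero-phase filtering + envelope
  changepoint.py  flanking-RMS cost, exact DP solver, slope features
  knn.py          feature matrix, KNN, subject-wise CV, GP/EI optimization
  windownet.py    rolling windows, 7-layer classifier, lead times
  reporting.py    confusion matrix (TPR/FNR), per-motion lead tables
  study.py        end-to-end study protocols
  io.py, cli.py   CSV/HDF5 persistence and the `emgintent` CLI
```
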