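# nirscomp

Detection of compensatory trunk movements from multichannel **muscle
NIRS** (near-infrared spectroscopy) recordings, built as a tested,
reusable analysis pipeline for rehabilitation-engineering work.

Stroke survivors performing reaching tasks often recruit trunk muscles to
substitute for impaired upper-limb function — lean-forward (**LF**),
trunk-rotation (**TR**) and shoulder-elevation (**SE**) compensation,
versus uncompensated movement (**NC**). Six trunk muscles (left/right
obliquus externus abdominis, descending trapezius, erector spinae) are
monitored optically; each sensor yields two chromophore
concentration-change series, deoxyhemoglobin **Hb** and oxyhemoglobin
**HbO₂**, sampled at 16 Hz. The pipeline classifies the movement class
from windowed time-domain features of these signals.

## Method

1. **Preprocessing** — dropped samples are padded with the mean of the
   four preceding values; a sixth-order zero-phase Butterworth low-pass
   at 0.5 Hz removes broadband noise and the cardiac band; empirical mode
   decomposition (EMD) estimates and removes slow baseline drift.
2. **Signal improvement** — two decompositions of the (Hb, HbO₂) pair:

   - *CBSI* (correlation-based): α = std(HbO₂)/std(Hb),
     TNS = ½(HbO₂ + α·Hb), TFS = ½(HbO₂ − α·Hb);
   - *DBSI* (differential-based): CMS = ½(HbO₂ + Hb) tracks blood flow
     (common mode), DMS = ½(HbO₂ − Hb) tracks oxygen consumption
     (differential mode). DBSI is an exact linear bijection.

3. **Activation segmentation** — the linear fitting slope (LFS), the
   least-squares slope of a signal window against time, is evaluated on a
   sliding window (8 samples / 500 ms, stride 4 samples / 250 ms). Runs
   of same-sign, above-threshold window slopes whose mean agrees with the
   slope fitted over the whole run are activation (rising) or
   deactivation (falling) segments.
4. **Features** — per channel, per improved series, per window: mean
   (MEA) and population standard deviation (STD); 6 channels × 2 series
   × 2 statistics = 24 features per window, labeled with the trial's
   movement class.
5. **Classification** — one-vs-one soft-margin SVM with RBF kernel and
   penalty C = 0.3, z-score normalisation fitted per training fold,
   stratified ten-fold cross-validation, reported as per-fold accuracies,
   a pooled confusion matrix and per-class precision/recall/F1.

Because no subject recordings are publicly deposited, the package ships a
first-class synthetic-trial generator (`nirscomp.simulate`) that builds
each channel's clean response in CMS/DMS space (logistic ramp to plateau,
class-specific amplitudes), maps it to (Hb, HbO₂) exactly, then layers on
baseline drift, a 1.2 Hz cardiac sinusoid, Gaussian noise and random
sample drop-outs — with full ground truth for every stage.

## Worked example

```python
from nirscomp.pipeline import (
    simulate_recordings, preprocess_dataset, dataset_features, evaluate_features,
)

recs = simulate_recordings(n_subjects=6, trials_per_class=20, seed=1)
cleaned = preprocess_dataset(recs)
feats = dataset_features(cleaned, "dbsi")   # active-window MEA/STD matrix
report = evaluate_features(feats, feature_mode="dbsi")
print(report.summary())
```

prints (abridged):

```
Compensatory-movement SVM cross-validation
==========================================================
kernel=rbf  C=0.3  folds=10  split=window  norm=zscore  seed=0
features: dbsi
----------------------------------------------------------
accuracy (mean of folds):   0.9976
accuracy (pooled):          0.9976
macro F1:                   0.9976
----------------------------------------------------------
 class  precision     recall         F1
    NC     0.9989     1.0000     0.9994
    LF     0.9952     0.9957     0.9955
    TR     0.9963     0.9945     0.9954
    SE     1.0000     1.0000     1.0000
```

i.e. with differential-mode (DBSI) features the four movement classes are
recovered from the synthetic six-subject dataset at 99.8 % ten-fold CV
accuracy; the residual confusions are almost all between LF and TR, whose activation
patterns share the executing-side obliquus externus abdominis.

The same sweep over signal types (`nirscomp run-all --out results --seed 1`)
emits the accuracy-per-signal-type comparison table (raw, CBSI, DBSI,
TNS, TFS, CMS, DMS).

## Command line

```bash
nirscomp simulate --out data --seed 1 --subjects 6 --trials-per-class 20
nirscomp preprocess --in data --out clean
nirscomp features --in data --out features.csv --signal-type dbsi
nirscomp evaluate --features features.csv --out report.json
nirscomp run-all --out results --seed 1
```

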