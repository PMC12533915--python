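# vcglvh

Electrovectorcardiographic detection of echocardiographic left ventricular
hypertrophy (LVH): vectorcardiogram (VCG) synthesis from the 12-lead ECG,
loop-shape feature extraction, the classical voltage criteria, interpretable
gain-ratio decision trees, and the statistics needed to compare all of them.

## Background

LVH — thickening of the left ventricular wall, usually diagnosed by
echocardiography — is an independent cardiovascular risk marker, and the ECG
is the cheap, ubiquitous screen for it. The classical voltage criteria
(Sokolow–Lyon, Cornell, Peguero–Lo Presti, Romhilt–Estes and friends) are
specific but notoriously insensitive: they look at a handful of R/S
amplitudes and miss most echocardiographic LVH.

The approach implemented here enriches the ECG with the *shape* of the heart
vector's trajectory. The eight independent leads of a median beat are
projected to a three-dimensional VCG with fixed 3×8 transforms (inverse
Dower, Kors, and two least-squares variants, each with and without Fourier
smoothing). Each wave (P, QRS, T) traces a loop in space; the loops are
summarized by per-decile magnitude, speed and orbital frequency plus global
descriptors (normalized vector area, planar rotation range, speed extrema,
terminal vector magnitude). These VCG features — alone or combined with
conventional ECG measurements — feed small C4.5-lineage decision trees whose
thresholds are reported in original units, so every model remains a readable
clinical rule. A cost-sensitive variant trades sensitivity for specificity.

Because real ECG/echo data cannot ship with the package, a parametric
synthetic generator produces cohorts of Gaussian-wavelet median beats with an
injected LVH voltage/repolarization effect, realistic between-patient
amplitude variability, and clinical covariates. Everything downstream
(features, trees, statistics) is generator-agnostic.

## Worked example

```python
import warnings

import vcglvh as v
from vcglvh import modeling

# 1. one synthetic median beat, classical criteria
beat, fid = v.make_beat(v.default_beat_spec(noise_sd_uv=0.0), rng=0)
m = v.measure_amplitudes(beat, fid)
cornell = v.cornell_voltage(m, "M")
print(f"RaVL + SV3 = {cornell.value:.2f} mV -> Cornell positive: {cornell.positive}")

# 2. VCG synthesis and QRS loop descriptors
vcg = v.synthesize(beat, "kors")
qrs = v.segment_loops(vcg, fid)["QRS"]
g = v.global_features(qrs)
print(f"QRS loop: GAV={g['GAV']:.3f}  RangeAng={g['RangeAng']:.1f} deg  "
      f"VelMax={g['VelMax']:.1f} uV/ms")

# 3. cohort -> features -> pinned trees -> held-out evaluation
cohort = v.make_cohort(v.CohortSpec(n=240, seed=5))
df = modeling.assign_split(v.cohort_feature_table(cohort), seed=5)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    models = modeling.build_models(df, seed=5, pinned=True)
test = df[df[modeling.SPLIT] == "test"]
feats = test.drop(columns=[modeling.LABEL, modeling.SPLIT])
y = test[modeling.LABEL].to_numpy(int)
probs, calls = models["vcg_ecg"].predict_frame(feats)
row = v.confusion_metrics(v.ConfusionCounts.from_calls(calls, y)).as_percent_row()
print(f"vcg_ecg held-out (n={len(test)}): accuracy {row['accuracy_pct']}%  "
      f"sensitivity {row['sensitivity_pct']}%  specificity {row['specificity_pct']}%  "
      f"AUC {v.auc(probs, y):.3f}")
print(v.render_rules(models["vcg_ecg"]))
```

Output (about half a minute on one CPU):

```
RaVL + SV3 = 1.20 mV -> Cornell positive: False
QRS loop: GAV=0.640  RangeAng=359.5 deg  VelMax=115.0 uV/ms
vcg_ecg held-out (n=72): accuracy 86.1%  sensitivity 78.6%  specificity 90.9%  AUC 0.870
T_AREA_DI <= 3.357:
  -> LVH p=0.976 [39 LVH / 0 non-LVH]
T_AREA_DI >  3.357:
  Ang_Term_Num <= 0.646:
    T_AREA_DI <= 5.471:
      Ang_Term_Num <= 0.474:
        Ang_Term_Num <= 0.383:
          -> LVH p=0.056 [0 LVH / 16 non-LVH]
        Ang_Term_Num >  0.383:
          Ang_Term_Num <= 0.398:
            -> LVH p=0.800 [3 LVH / 0 non-LVH]
          Ang_Term_Num >  0.398:
            -> LVH p=0.250 [1 LVH / 5 non-LVH]
      Ang_Term_Num >  0.474:
        -> LVH p=0.923 [11 LVH / 0 non-LVH]
    T_AREA_DI >  5.471:
      -> LVH p=0.012 [0 LVH / 79 non-LVH]
  Ang_Term_Num >  0.646:
    -> LVH p=0.938 [14 LVH / 0 non-LVH]
```

The rendered tree is the model: thresholds are in original feature units
(here the lead-I T-wave area and the terminal QRS angle number), and each
leaf carries its Laplace-smoothed LVH probability and training composition.

## Command line

The `vcglvh` entry point chains the same pipeline over files:

```
vcglvh synth --n 664 --seed 0 --out cohort/           # beat CSVs + manifest
vcglvh features cohort/ --out features.csv            # feature table
vcglvh criteria cohort/patient_0000.csv --sex M       # classical criteria
vcglvh train features.csv --model vcg-ecg --pinned --seed 0 --out model.json
vcglvh evaluate model.json features.csv --compare other_model.json
```

## Package map

| module | contents |
| --- | --- |
| `vcglvh.beats` | median-beat container and CSV I/O, fiducials, amplitude measurement, T-wave area |
| `vcglvh.transforms` | 3×8 VCG transforms (inverse Dower, Kors, least-squares variants), Fourier smoothing |
| `vcglvh.loops` | fiducial detection, P/QRS/T loop segmentation, decile and global loop features |
| `vcglvh.criteria` | classical ECG-LVH criteria registry (23 criteria) and continuous ECG features |
| `vcglvh.features` | full feature extraction (864 VCG descriptors + ECG block), pinned predictor sets |
| `vcglvh.trees` | gain-ratio decision trees: winnowing, pessimistic pruning, false-positive cost, JSON round-trip, rule rendering |
| `vcglvh.modeling` | split/impute/standardize, L1-logistic feature pruning, model grid search |
| `vcglvh.evaluation` | confusion metrics with exact CIs, DeLong, McNemar–Bonferroni, cross-validation, CCR tables, power |
| `vcglvh.synthetic` | beat and cohort generators, tabular feature-table generator |

Methodological details, parameter values and known limitations are in
[docs/methods.md](docs/methods.md).

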