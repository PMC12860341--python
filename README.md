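# paintriage

Multistage (stacked) machine learning for automated referral triage in
pain medicine — with imbalance-aware base learners, elbow-method stage
selection, calibration and stage-transition accounting, and an
argmax-with-review-margin triage decision rule.

## The problem

Patients referred to a pain-medicine service may be candidates for one of
several advanced procedures — peripheral nerve stimulation (PNS), spinal
cord stimulation (SCS), intrathecal pump (ITP), basivertebral
radiofrequency ablation (BVRF), or minimally invasive lumbar decompression
(MILD). In a typical two-year referral cohort of a few thousand patients,
each procedure is undergone by only a handful (tens out of thousands), so
predicting who will benefit from which procedure is a heavily imbalanced
binary classification problem, one per procedure, over a couple of
hundred structured EHR features plus binary NLP-concept flags from
clinical notes.

## The method

Let `x_j` (j = 1..n) be the referral features and `y_i` the predicted
probability vector at stage `i`. Stage 1 fits an imbalance-aware base
learner under stratified 10-fold cross-validation and pools the
out-of-fold probabilities into `y_1`. Stage 2 refits the same learner on
`[x_1..x_n, y_1]`; stage `i` on `[x_1..x_n, y_1..y_{i-1}]` (cumulative
stacking). Each stage's pooled out-of-fold true positive rate `p_i` forms
a trajectory, and the stage count is chosen by the elbow rule on the
slope change

```
s_i = |(p_i − p_{i−1}) − (p_{i+1} − p_i)|,      i* = argmax_i s_i
```

(ties break to the smallest stage) — stopping the stacking before the
ever-increasing TPR trajectory turns into overfitting. The deployed model
is the chain of full-data refits truncated at `i*`; at triage time a
referral is scored by all five procedure chains and scheduled for the
top-probability procedure only when its lead over the runner-up exceeds a
review margin; otherwise it is flagged for manual review.

One fold assignment is fixed up front and shared by all stages, and every
augmented `stage_prob` column is itself out-of-fold, so a patient's own
probability at any stage is produced by models that never trained on that
patient's fold.

Because no patient-level data are public, the package ships a synthetic
cohort generator that reproduces the reference cohort shape — 3,552 patients, 192
structured + 39 NLP-flag features, positive counts 46/126/36/16/10 across
PNS/SCS/ITP/BVRF/MILD — with sparse planted linear-plus-interaction
signal so the stacking has genuine headroom.

## Worked example

```python
from paintriage import (BaseLearnerSpec, CohortConfig, MultistageTriage,
                        generate_cohort)
from paintriage.triage import decide

cfg = CohortConfig(n_patients=800, n_structured=60, n_nlp=12,
                   outcome_spec={"SCS": 28, "ITP": 8}, seed=42)
features, outcomes = generate_cohort(cfg)

model = MultistageTriage(features, outcomes["SCS"],
                         base_spec=BaseLearnerSpec("easy_ensemble"),
                         k=10, m_max=4, procedure="SCS")
res = model.fit(seed=0)
print(res.summary())
```

prints

```
Multistage stacked classifier
================================================================
procedure: SCS   base learner: easy_ensemble
patients: 800   positives: 28   features: 72
folds: 10   stages trained: 4   selected stage i*: 2   threshold: 0.5
----------------------------------------------------------------
 stage    tpr    tnr    auc  slope_change  selected
     1 0.8214 0.8549 0.8898           NaN     False
     2 0.8214 0.8575 0.8472        0.0357      True
     3 0.7857 0.8575 0.8416        0.0357     False
     4 0.7857 0.8575 0.8442           NaN     False
----------------------------------------------------------------
final stage 2 (pooled out-of-fold):
  precision 0.1729   recall 0.8214   F1 0.2857
  AUC 0.8549 +/- 0.1475  [0.7494, 0.9603] (95% CI, 10 fold AUCs)
```

The trajectory column `tpr` is `p_1..p_4`; `slope_change` is `s_i`
(defined for interior stages only); the elbow picks stage 2 (ties break
small). The final block is the pooled out-of-fold confusion metrics of
the selected stage, with the AUC summarised across the 10 fold AUCs as
mean ± sample SD and a Student-t 95% interval. Downstream,

```python
acc = res.accounting()            # per-stage capture/loss counts
tab = res.calibration_table()     # 10 fixed-width reliability bins
d = decide({"SCS": 0.82, "ITP": 0.35, "PNS": 0.10, "BVRF": 0.05,
            "MILD": 0.02}, margin=0.10)
# -> scheduled -> SCS (lead 0.47 > margin 0.10)
```

The same pipeline is available from the shell:

```bash
paintriage simulate --config config.yaml --seed 0 --out cohort.csv
paintriage baselines --cohort cohort.csv --out baselines/
paintriage fit --cohort cohort.csv --out models/
paintriage evaluate --cohort cohort.csv --models models/ --out evaluation/
paintriage accounting --cohort cohort.csv --models models/ --out accounting/
paintriage triage --features cohort.csv --models models/ --out decisions.csv
```

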