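# fairskin

A fairness-audit toolkit for multi-class skin-disease classifiers,
including chat models that may abstain. It is aimed at researchers and
evaluators who need to answer, from a table of prediction records alone:
*does this classifier's accuracy depend on who the patient is?*

The setting is dermatoscopic diagnosis over three visually similar
lesion classes — melanoma (MEL), melanocytic nevi (NV) and benign
keratosis-like lesions (BKL) — with a fourth prediction outcome, NULL,
for free-text responses from which no diagnosis can be extracted. The
audited cohort structure mirrors the HAM10000-style metadata: one row
per test image with true label, predicted label, sex, and age.

## What it computes

**Performance decomposition.** For any stratum (sex group, age group,
or the whole cohort) the 3×4 confusion matrix yields class-conditional
accuracy (recall, with abstention scored as incorrect), per-class F1
(precision pooled over non-NULL predictions), overall accuracy, and an
abstention-aware micro-F1

    micro-F1 = harmonic mean of  trace / #non-NULL predictions  and  trace / n,

which equals plain accuracy exactly when the classifier never abstains.

**Chi-square independence test.** For each demographic factor and class
scope, a G×2 contingency table of (correct, incorrect) counts per group
is tested with Pearson's statistic, no continuity correction:

    χ² = Σᵢ (Oᵢ − Eᵢ)² / Eᵢ ,   df = G − 1.

**Rate-gap metrics.** With one-vs-rest group rates
TPRᵢ = P(Ŷ=c | Y=c, Gᵢ) and FPRᵢ = P(Ŷ=c | Y≠c, Gᵢ):

    avgTPRdiff = (2/n(n−1)) Σ_{i<j} |TPRᵢ − TPRⱼ|      (likewise for FPR)
    AOD        = (avgTPRdiff + avgFPRdiff) / 2

plus disparate impact (min pairwise positive-rate ratio), the equal-
opportunity gap (max pairwise TPR gap) and the equalized-odds gap (max
of the TPR and FPR gaps). A factor is adjudicated **biased** iff any
scope's chi-square p-value falls below the significance level (default
α = 0.05).

**Simulation.** A seeded generator builds cohorts with exact published
margins (972 records: 335/305/332 by disease, 411/561 by sex,
112/375/484 by age group) and simulates classifiers from row-normalized
confusion profiles, optionally with an injected per-group TPR offset δ.
A calibration engine measures the verdict's type-I error and power and
the sampling behavior of the gap estimator.

## Worked example

```python
import fairskin as fs

# the published chat-model confusion matrix, scored against the
# declared class supports (335 / 305 / 332)
cm = fs.confusion_from_counts(
    fs.fixtures.CONFUSION_MATRICES["chatgpt4-web"],
    support=fs.fixtures.CLASS_SUPPORTS,
)
om = fs.overall_metrics(cm)
print(round(om.accuracy, 4), round(om.micro_f1, 4), om.n_abstained)
# 0.4835 0.4881 18

# chi-square on the sex x correctness table for melanocytic nevi,
# reconstructed from per-group accuracies and supports
counts = fs.fixtures.reconstructed_group_correct_counts("sex", "NV")
res = fs.chi_square_test(fs.contingency_from_counts(counts))
print(counts, round(res.p_value, 3))
# {'FEMALE': (63, 82), 'MALE': (83, 77)} 0.141
```

Accuracy 0.4835 means 470 of 972 test images were diagnosed correctly;
micro-F1 is slightly higher because the 18 abstentions shrink the
precision pool but not the recall pool. The p-value 0.141 means the
female/male accuracy difference on nevi (63/145 vs 83/160 correct) is
compatible with chance at α = 0.05, so this scope does not flag bias.

The same pipeline from the shell:

```
fairskin simulate --fixture-profile chatgpt4-web --seed 1 --out records.tsv
fairskin evaluate --records records.tsv --out audit/
fairskin calibrate --study power --delta 0,0.1,0.3 --reps 1000 --seed 1 --out calib/
```

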