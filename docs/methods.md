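# Methods

## Data model

A prediction record is (Y, Ŷ, A): true diagnosis Y ∈ {MEL, NV, BKL},
predicted outcome Ŷ ∈ {MEL, NV, BKL, NULL}, and sensitive attributes A
(sex ∈ {female, male, unknown}; age group derived from integer age by
fixed bins Young 0–39, Middle-aged 40–59, Senior 60+; fractional ages
floor before binning). Records with an unknown level of a factor are
excluded from that factor's strata but always kept in pooled ("All")
statistics. Label strings are normalized through a single synonym
table; an unrecognized string is an error, never NULL — abstention is a
semantic outcome of the classifier, not a parse failure.

## Scoring conventions

* **Abstention is incorrect.** NULL contributes to every recall-type
  denominator and to no precision-type denominator; it is never a class
  of its own.
* **Per-class "accuracy" is recall** (class-conditional accuracy):
  diagonal count over class support.
* **Overall micro-F1 with abstention** is the harmonic mean of
  micro-precision (trace over non-NULL predictions) and micro-recall
  (trace over n). With zero abstentions it equals overall accuracy.
* **Declared supports.** A confusion matrix may carry per-class
  supports that differ from its row sums (three of the packaged printed
  matrices are internally inconsistent, with BKL rows summing to 337,
  328 and 331 against a support of 332). The matrix is kept as printed,
  a warning is emitted, and recall-type denominators use the declared
  supports while precision pools use the printed column sums.
* **Per-class F1 degeneracies.** Zero predictions of a class with
  positive support give F1 = 0; zero predictions *and* zero support
  give an undefined (NaN) F1, rendered as N/A in reports.
* Internal values are full precision; rounding (half-even) happens only
  in report layers.

## Fairness battery

* **Chi-square.** Pearson's statistic on the G×2 group-by-correctness
  table, expected counts from the margins, df = G−1, upper-tail p, no
  Yates continuity correction (the uncorrected form is what the audited
  published p-values reproduce). Expected cells below 5 set a warning
  flag but the test still runs — the audited study itself reports
  p-values for strata with expected counts ≈ 3.3. Groups with zero
  samples are dropped with a warning; fewer than two groups is an
  error. No multiplicity correction is applied across the per-disease
  tests, mirroring the audited design; raw p-values are reported.
* **Rate gaps.** One-vs-rest TPR/FPR per group; average TPR/FPR
  differences are means of absolute pairwise differences (for two
  groups they reduce to the single absolute difference); AOD is half
  their sum. Multi-group companion forms are conventions chosen here
  and labeled in output: DI = min pairwise positive-rate ratio, EOP =
  max pairwise TPR gap, EOD = max of TPR and FPR pairwise gaps.
* **Pooled scope.** The pooled chi-square crosses group with
  correctness over all three diseases' samples. The pooled AOD/EOP/EOD
  default to the unweighted mean of the per-class one-vs-rest values; a
  `micro` switch instead averages the group rates across classes before
  taking gaps. Pooled values are reported as descriptive summaries
  only — no published pooled construction could be confirmed, so they
  are never used as correctness anchors.
* **Verdict.** Biased iff any scope's p < α (default 0.05); the
  contributing scopes are listed. This "any significant" rule matches
  every published verdict in the audited tables.

## Synthetic cohorts and classifier profiles

The generator emulates the metadata level of the audited study; images
are never touched.

* **Cohort.** Two margins (sex×disease, age×disease) with per-disease
  totals required to agree; the default spec is the published test
  cohort (972 records). The published age margins cover 971 records —
  one BKL record carries an unknown age, and the generator reproduces
  that. Within each disease the sex and age streams are paired by a
  seeded shuffle: both margins are exact, the joint sex×age layout is
  randomized. No implemented statistic stratifies on sex and age
  jointly. Ages are uniform within their bin (seniors capped at 85);
  none of the statistics depend on within-bin age. `scaled(n)`
  reapportions the composition to any n by largest-remainder rounding.
* **Profiles.** A classifier is a per-true-class probability vector
  over the four outcomes, obtained by row-normalizing a confusion
  matrix. Bias is injected by raising one group's P(Ŷ=c | Y=c) by δ and
  rescaling the other three entries of that row proportionally, which
  preserves the profile's error structure; all other groups keep the
  base behavior. δ must keep the vector in [0,1].
* **What this does not emulate:** lesion-level correlation between
  images of one patient, image-feature-driven covariate shift between
  groups, and any dependence of classifier behavior on age *within* a
  bin. Passing calibration tests therefore speak to the statistical
  procedure at the study's stratum sizes, not to image-level realism.

## Calibration engine

Replicates are simulated at the level of per-(group, class) outcome
counts — multinomial draws from the profile — which is distributionally
identical to drawing one label per record (the audited statistics
depend on records only through these counts) and fast enough for
thousands of replicates; the record-level simulator remains the
reference path and the suite checks the two agree. Seeds derive from a
single root `SeedSequence` (one spawned stream per δ, logged in the
output), so every study is replayable component-wise. Replicates whose
table degenerates (a zero expected column) are skipped and counted, not
resampled. Rejection rates carry exact (Clopper–Pearson) binomial 95%
intervals.

Default problem sizes: 1000 replicates for power grids, 2000 for type-I
calibration, 500 at n = 10⁴ for gap recovery — enough for binomial
standard errors of ~0.005–0.01 on a rate, while keeping a full run in
seconds. The default injection class is NV: its mid-range baseline TPR
(≈0.48 in the default profile) leaves headroom for gap grids up to
δ ≈ 0.5, whereas a +0.3 offset on the MEL baseline (≈0.75) would be
infeasible.

The null rejection rate of the pooled chi-square verdict at α=0.05 and
the study's cohort size sits inside the exact binomial 95% interval
around 0.05; power rises steeply between δ=0.1 and δ=0.3. The
average-TPR-difference estimator is non-negatively biased under the
null (it is a mean of absolute differences of noisy rates); the bias
shrinks with n, and an injected δ=0.2 is recovered within Monte-Carlo
error at n = 10⁴. These statements are exactly what the test suite and
the acceptance script compute.

## Response interpretation

Free-text responses are digitized by an ordered keyword rule set, a
deterministic stand-in for manual/learned interpretation (learned
interpreters are out of scope; they require model weights and are not
reproducible from data alone). Precedence: (1) a final-answer-scoped
match nearest the end — the final-answer zone is the last 25% of the
text or the segment after the last conclusion marker (colon, "in
summary", "final answer", …), whichever starts later; (2) a unique
disease mentioned anywhere; (3) the most frequent disease mention, with
overlapping synonym matches merged into one mention and frequency ties
broken severity-first (MEL > NV > BKL, melanoma being the serious
class); (4) NULL. The precedence, the 25% constant and the tie order
are explicit design choices of this artifact, documented here because
no published hedging guideline exists. Dual-annotation adjudication
passes agreeing pairs through and requires an explicit resolution for
disagreements, reporting the raw agreement rate and per-class
disagreement counts.

## Known limitations

* Records are treated as independent; multiple images of one lesion
  would violate this and the audit cannot detect it from metadata.
* The reconstructed contingency tables depend on round-half-up of
  accuracy×support; a published p-value whose underlying counts
  rounded differently can disagree in the third decimal (one audited
  cell: 0.627 computed vs 0.626 printed).
* Per-group confusion matrices are not published, so per-group FPR-based
  quantities (published AOD cells) cannot be reconstructed and are not
  used as anchors.
* The random baseline is uniform over the three diseases; a
  frequency-weighted variant can be simulated from the packaged
  printed random-model profile instead.
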