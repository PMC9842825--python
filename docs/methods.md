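# Methods

## Evaluation model

`fuseroc` treats a screening study as a case table: one row per exam with a
three-level ground truth (`malignant` / `benign` / `normal`), one continuous
suspicion score per modality (`score_dm`, `score_abus`; higher = more
suspicious), and optionally ordinal BI-RADS categories from readers.  All
binary analyses use the malignant-vs-rest labelling: only biopsy-proven
malignant cases are positive; benign and normal cases are pooled as
negatives.  Benign cases are kept distinct from normals everywhere else
(generation, stratified resampling, subcohort construction) because enriched
study cohorts over-represent them relative to screening prevalence.

### ROC and AUC

The empirical ROC places one operating point per distinct score value under
the convention "recall iff score ≥ threshold", plus the two trivial
endpoints.  The AUC is the Mann–Whitney statistic with midrank tie handling
(ties count ½), computed from ranks in O(n log n); it equals the trapezoidal
area under the empirical curve (asserted to 1e-10 in tests).

### DeLong variance, covariance and paired test

Variances and the covariance of two correlated AUCs come from DeLong's
structural components: for each positive `i`, `V10_i` is the mean of the
tie-aware comparison kernel against all negatives, and symmetrically `V01_j`
for negatives.  Both are computed via the midrank identity
`V10_i = (R_i − r_i)/n_neg`, where `R_i` is the rank of positive `i` among
all cases and `r_i` its rank among positives.  Then
`var = S10/n_pos + S01/n_neg` with sample (co)variances (ddof = 1), and the
paired z-statistic is `(Â_a − Â_b)/√(v_a + v_b − 2c)` with a two-sided
normal p-value.  When the variance of the difference is zero (identical or
rank-equivalent scores) and the AUCs agree, the test returns z = 0, p = 1
rather than 0/0.  The implementation reproduces R `pROC`'s DeLong outputs to
nine decimals on a frozen dataset, and its variance tracks the Monte-Carlo
variance of the AUC within 15% at n = 60 in the acceptance suite.

### Youden operating points

`max_youden` scans the empirical curve for the maximum of
`J = sens + spec − 1`.  Ties are broken toward higher specificity, then
lower threshold — a deliberate, documented preference for the
low-recall-rate side, which is the operationally attractive corner for a
stand-alone screening reader.  A curve whose maximum J is 0 is flagged
`degenerate` and raises a warning.

### Bootstrap confidence intervals

Percentile bootstrap with case-level resampling, stratified by the
three-level truth class so every replicate keeps the cohort composition
(and, in particular, contains positives).  Default 2000 replicates at the
95% level.  A replicate on which the metric fails is redrawn and the redraw
count is recorded.  Percentile intervals can in principle fail to bracket
the point estimate in heavily skewed small samples; the reports tolerate
and surface this rather than switching methods.  Coverage for the AUC on
binormal cohorts (n = 200) is checked in the test suite against the nominal
95% within 3 binomial standard errors.

## Fusion

Scores are min–max normalized over the full analyzed cohort (a constant
score vector is a configuration error naming the modality).  The fused score
is the convex combination `w·dm + (1−w)·abus`, and `w` is selected on the
grid 0.01…0.99 in steps of 0.01 — the sweep evaluates the Mann–Whitney AUC
at every grid point (vectorized over the grid via axis-wise ranking).  AUC
ties at the optimum are broken toward 0.5, then toward the smaller weight,
so exchangeable modalities get a symmetric, stable answer.

Both the normalization bounds and the argmax weight are in-sample choices:
no train/test split is performed, so the reported fused AUC is the optimum
on the analysis cohort itself.  The acceptance suite therefore adds an
out-of-sample check the in-sample procedure does not provide: with the
default complementary-modality model at n = 430, the weight selected on one
cohort beats both single modalities on an independent replicate in ≥ 90% of
200 simulations.

## Reader strategies

Recall is defined as BI-RADS category ≥ a threshold in the suspicion order
1 < 2 < 3 < 4a < 4b < 4c < 5.  The default threshold is category 3: with
thresholds at 4a the simulated readers' specificities could not fall to the
20–60% range that characterizes sensitive human screeners on enriched
cohorts, so "probably benign" and above is treated as a recall.  Every
report names the threshold used, and it is configurable.

Either-recall double reading is the element-wise OR of two recall vectors —
by construction it can only raise sensitivity and lower specificity relative
to each constituent reader (asserted exactly).

The four-reader panel votes on categories first and thresholds the consensus
afterwards.  The voting rules: a category held by ≥ 3 readers wins; in a
2-1-1 split the modal category wins; a 2-2 split between two categories goes
to the more suspicious; four distinct categories yield the more suspicious
member of the median pair.  The consensus is always one of the cast votes
and is invariant to reader order (verified exhaustively over all 7⁴ = 2401
patterns).  Voting on recalls before combining is a plausible alternative
reading of "majority voting"; voting on categories was chosen because it
preserves the ordinal consensus for downstream thresholds, and the recall
rule is applied after.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
images or lesions.  Within each truth class the (dm, abus) score pair is
bivariate Gaussian — the binormal ROC model — which admits the closed-form
AUC `Φ((μ₁−μ₀)/√(σ₁²+σ₀²))` (mixed over the benign/normal composition for
the negative class) used as an exact oracle throughout the tests.

Defaults, chosen once as the package's reference conditions:

* composition 42 malignant / 114 benign / 274 normal (430 cases), observer
  subcohort = all 42 malignant + 30 benign + 80 normal (152 cases) drawn by
  seeded stratified subsampling;
* class means (dm, abus) = malignant (1.50, 1.55), benign (0.50, 0.50),
  normal (0, 0), all unit variance — giving analytic single-modality AUCs of
  0.828 (dm) and 0.837 (abus) against the default negative mixture, i.e.
  strong but imperfect detectors;
* inter-modality correlation ρ = 0.3 in every class: moderately
  complementary modalities, the regime in which score fusion helps;
* four reader profiles calibrated so that, at recall threshold 3, their
  expected operating points are (sens, spec) = (0.778, 0.454),
  (0.792, 0.571), (0.942, 0.221), (0.854, 0.379) — two mammography-like
  readers (moderate sensitivity, higher specificity) and two
  ultrasound-like readers (high sensitivity, low specificity).  Within the
  recall/no-recall halves the category mass follows fixed geometric shapes
  (malignant recalls skewed toward 4c/5, false recalls hugging the
  threshold); these shapes affect only majority voting, not recall rates.

What the generator does **not** emulate: lesion locations or sizes, reading
order or fatigue effects, inter-reader correlation beyond what the shared
truth induces, non-Gaussian score shapes (real AI scores are often bounded
and heavily skewed), and case-mix drift between sites.  Passing tests
therefore certify the statistical machinery under the binormal model, not
the behavior of any particular commercial AI system on clinical data.

## Reproducibility and numerics

Each generated table owns one RNG stream keyed by its seed; reader columns
consume sub-streams keyed by reader index, so appending a reader never
perturbs earlier columns.  The pipeline derives subcohort, reader and
bootstrap seeds from the single root seed by fixed offsets (reduced mod
2³¹−1), and two runs with the same config produce byte-identical reports;
the report's provenance block records the seed and a hash of the scientific
config (output location excluded).

Floating-point tie tolerance for argmax scans is 1e-12; Youden identities
hold to 1e-12; trapezoid/Mann–Whitney agreement to 1e-10.  Reported numbers
follow screening conventions: AUC and J to 3 decimals, sensitivity and
specificity as percentages to 1 decimal.

Problem sizes in the test and acceptance suites (5000 Monte-Carlo cohorts at
n = 60 for the variance check, 2000 replicates at n = 200 for type-I error,
500 cohorts with 600-replicate bootstraps for CI coverage, 200 replicate
studies at n = 430 for fusion dominance) were chosen so each statistical
assertion has at least 3-standard-error resolution while the whole suite
runs in a few minutes on one CPU core.

## Known limitations

* The fused AUC and its DeLong comparisons are in-sample with respect to
  the fusion weight; no optimism correction is applied because the procedure
  under evaluation is itself defined in-sample.
* Percentile bootstrap only; no BCa.
* Case-level analysis only — no lesion localization (FROC), no
  breast-level or view-level scores.
* The reader simulator draws categories independently across readers given
  the truth class; real readers correlate through image difficulty, which
  majority-vote specificity is sensitive to.
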