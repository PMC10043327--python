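# Methods

## Scores and cell labeling

The response is a binary 5-year recurrence status. A logistic null model
containing only the clinical covariates — stage (dummies, reference I),
tumor location (reference colon), adjuvant chemotherapy and radiotherapy
(0/1) — is fit by maximum likelihood; each patient's score is the residual
s_i = y_i − p̂_i. By the score equations these residuals sum to zero, and
they generalize case/control counts: with an empty covariate set s_i =
y_i − ȳ, and the cell-labeling rule below reproduces classic MDR's
case:control-ratio rule exactly (tested exhaustively on random small
datasets, using exact integer arithmetic on the classic side).

For a k-SNP combination each observed multilocus genotype is a cell
(≤ 3^k). A cell is HIGH risk when its training-sample score sum is
positive, LOW when negative. Two edge rules are deliberate and logged:

- **Exact ties → LOW.** A score sum within 1e-9 of the threshold counts as
  a tie. The tolerance absorbs float rounding of sums that are
  algebraically zero (common in the no-covariate case, where cell sums are
  rational numbers with small denominators); the smallest genuinely
  nonzero sum at cohort sizes in the hundreds is ~1/n, orders of magnitude
  above it.
- **EMPTY (unobserved in training) cells predict LOW at evaluation.** An
  unseen genotype combination cannot raise sensitivity spuriously; samples
  landing in EMPTY cells during risk assignment are flagged.

Separation in the null fit (possible in small strata) triggers a
ridge-stabilized refit with a warning rather than silent divergence.

## Search, cross-validation and selection

Folds are a random 5-part partition stratified by outcome status, keeping
the ~26/74 class split stable across parts (stratification is our choice;
it is not dictated by the procedure's published description). Within each
training fold every k-combination is scored by training balanced accuracy
(ties broken to the lexicographically first combination); each fold's
winner is evaluated on its held-out part. The reported model is the modal
fold winner; CVC counts the folds it won, and its TBA, sensitivity and
specificity are means over those folds. A fold whose test part lacks one
truth class has undefined TBA and is excluded from the mean with a
warning.

The search runs `repeats = 20` times under seeds derived as master + r;
candidates are ranked by identification frequency (exact unordered SNP-set
identity), then mean TBA, then mean CVC, then mean testing specificity —
the lexicographic order of the published tie-breaking sentence. Testing
(not training) specificity is our reading of the tie-break.

The 1-way analysis is iterative: select the top single-SNP model,
permutation-test it, and if significant remove that SNP and repeat until
the top model fails the gate. In the full pipeline, SNPs claimed by this
loop are excluded from the same network's 2-way/3-way searches
(configurable off).

Internally all combinations in a fold are evaluated at once: cell indices
for a block of combinations form an (n_samples × m) matrix and one
`bincount` per quantity yields per-cell score sums and class counts for
all m combinations; a naive dictionary-based implementation is kept in
the test suite as the independent oracle, and the two agree exactly for
every panel ≤ 8 SNPs, k ≤ 3.

## Permutation testing

The tested null is "no genotype effect given the covariates": the
(status, covariate) rows are shuffled jointly against the genotype rows.
Because the null-model fit depends only on the multiset of (y, x) pairs,
this is implemented as a permutation of the score vector. Each of the B
permutations re-runs the full exhaustive search at the same k, and
p = (1 + #{null TBA ≥ observed}) / (B + 1). B defaults to 1000, the
smallest round value resolving a 0.001 gate under the add-one estimator;
desk-scale runs use smaller B with correspondingly coarser resolvable
p-values (the code warns when B cannot resolve the requested α).

Two properties worth stating explicitly:

- **The selected model's TBA is biased above 0.5 under the null** (we
  measure ≈ +0.04 with 15 candidate pairs at n = 200): the modal-winner
  bookkeeping conditions each fold's test evaluation on wins in
  overlapping training sets. This is winner's curse, not leakage — a
  *fixed* combination's cross-validated test BA is unbiased at 0.5
  (verified by simulation), so the fold bookkeeping itself is leak-free.
  The permutation test is therefore the only valid significance gate, and
  its type-I error at α = 0.05 sits inside the binomial 99% interval over
  200 null replicates.
- Each permutation re-runs a **single** search repeat rather than all 20,
  a conservative tractability approximation (the observed statistic from
  20 repeats is selected at least as favorably as each null from 1);
  `full_repeats=True` restores the exact scheme.

## Risk-group validation

A selected model's full-data cell labels map every genotyped patient to
HIGH or LOW. Association with the outcome is verified by ML logistic
regression of status on the HIGH indicator plus the standard covariates;
we report exp(β) with symmetric-on-log-scale 95% Wald intervals (profile
likelihood would be asymmetric; Wald matches the reporting style of the
field's tables). With no covariates the fitted OR reproduces the 2×2
cross-product ratio to 1e-6. Regression is run only for
permutation-significant models; others carry a dash in the final report.
Kaplan–Meier curves (product-limit, via lifelines) and the two-group
log-rank test use the long-term follow-up data and re-include patients
censored at or before 5 years, who are excluded from the search because
their 5-year status is unknown.

## Quality control

Gates: MAF ≥ 0.05 (folded, computed from called genotypes), exact
Hardy-Weinberg p > 1e-4, and 0% missingness, applied in the order
missingness → MAF → HWE for reason reporting. The HWE test is the exact
conditional (Levene–Haldane) two-sided test using the plain — not mid- —
p-value: summing outcomes no more probable than observed is conservative
at the very permissive 1e-4 gate. It matches an exact-rational enumeration
oracle to 1e-12 for every genotype triple with total ≤ 50. The 0%
missingness default makes complete data a downstream contract: modules
after QC reject the missing sentinel rather than handling it.

LD pruning is greedy within a sliding window (defaults window 50 SNPs,
step 5, r² > 0.8 on composite-genotype dosage correlation): the
worst-offending pair loses its lower-MAF member (MAF tie → later
position) until the window is clean. The thresholds are configurable;
published analyses of this kind defer them to companion work, so the
defaults follow common practice.

## Synthetic cohorts

The generator emulates the target study's structure: n = 423; covariates
drawn independently at stage 19/44/37%, colon 64%, chemotherapy 59%,
radiotherapy 27%; marginal event prevalence 0.26. Genotypes are HWE draws
at MAFs uniform on [0.05, 0.5] (or fixed); optional LD blocks share one
MAF and copy the anchor haplotype with probability sqrt(r²_target), giving
pairwise dosage r² ≈ target. Interactions are planted through penetrance
tables; their effect enters the outcome logit additively with the
covariate effects as logit(penetrance of cell) − logit(HWE-expected
prevalence), keeping the covariate adjustment well-specified, and the
intercept is solved numerically (Brent) so realized-cohort mean event
probability equals the target. Covariate log-odds defaults (stage II
+0.35, III +0.80, rectum +0.15, chemo −0.20, radio +0.25) are modest
values making adjustment non-trivial without dominating genotype signal.

The default planted table is a parity ("XOR") pattern — cells with odd
dosage sum get baseline 0.12 + 0.38 — which has no marginal single-SNP
effect at MAF 0.5 and small marginals otherwise. These effect sizes were
calibrated once by simulation so that the full selection procedure
recovers a planted pair or triple in ≥ 90% of replicates at n = 2000,
then frozen; at the emulated cohort's n = 423 power is substantially
lower, mirroring the reality that desk-scale reruns cannot reproduce
registry-cohort findings, only the procedure's operating characteristics.

Survival times, when requested, are the simplest law consistent with the
binary 5-year endpoint: per-sample exponential rates solved so
P(T ≤ 60 months) equals the event probability, drawn conditionally on the
realized status, with late censoring and an optional early-censored
fraction whose 5-year status is set unknown. Survival realism beyond this
is a non-goal.

What passing tests on these cohorts do **not** show: robustness to
population structure, relatedness, genome-scale LD, genotyping error or
missingness patterns of real arrays — none of which the generator
emulates.

## Problem sizes and defaults

Acceptance-level simulations use the sizes at which the checked property
is statistically decidable in minutes: type-I calibration over 200 null
cohorts (n = 400, 10-SNP panel, B = 99), recovery over 50 replicates
(n = 2000, B = 99 with the add-one floor as the gate), composition checks
at n = 100,000. The bundled per-network panel sizes (526/213/118/89/63)
are a synthetic reconstruction — the unique five-part solution consistent
with the published two-way and three-way model totals — shipped so the
bookkeeping check is a computation rather than an asserted constant.

## Known limitations

- Exhaustive 3-way search over ~1,000-SNP panels (2.6×10⁷ models × 5
  folds × 20 repeats) is hours of compute at desk scale; the block
  evaluator is memory-bounded but single-threaded.
- Quantitative traits, family data and covariate missingness are out of
  scope; stage is treated as categorical, not ordinal.
- The permutation scheme assumes exchangeability of (status, covariate)
  rows against genotypes; confounding through population structure would
  violate it.
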