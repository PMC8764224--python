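# Methods

## Study model

The package targets paired two-timepoint intervention studies: each subject
belongs to one of four arms (SAL, GOP, VLCD, RYGB) and contributes a
baseline and a week-4 sample per biofluid. All modelling treats the feature
intensity on a log scale, with a subject-specific random intercept
absorbing the (large) stable between-person differences in metabolite
levels.

### Per-feature mixed model

For each feature,

```
log(intensity) = β0 + β_t·1{week4} + β_g + β_{t×g}·1{week4} + b_subject + ε,
b ~ N(0, σ²_subject),  ε ~ N(0, σ²_resid)
```

with treatment coding (reference level SAL, baseline). The quantity of
interest is the timepoint×group interaction β_{t×g}: the arm's change from
baseline over and above the control arm's change. Pairwise intervention
comparisons are Wald t contrasts of interaction coefficients.

*Estimation.* REML via the profiled variance ratio λ = σ²_subject/σ²_resid.
The model is rotated into a per-subject Helmert basis in which
V(λ) = I + λZZᵀ is diagonal, so each criterion evaluation is a weighted
least squares solve; λ is found by bounded Brent on log λ and then polished
by a root-find on the analytic REML gradient (the criterion is flat to
~√ε near its optimum, so a minimiser alone leaves λ with only half
machine precision). The σ²_subject = 0 boundary is always checked and
flagged. For the common case of complete balanced pairs the estimates have
a closed form through the orthogonal within-subject-difference and
subject-mean strata; this path is vectorised across features, agrees with
the iterative path to <1e-8, and is verified in the tests against a dense
GLS-with-λ-grid brute force and against an independent mixed-model
implementation.

*Inference.* Wald t with containment degrees of freedom
(n_subjects − n_groups). Containment is exact for the balanced paired
design (interaction contrasts live in the within-subject difference
stratum with exactly that df) and a standard conservative choice otherwise;
Satterthwaite was not implemented. BH-FDR is applied per contrast family
(one family = one group pair within one data-set grouping), matching
per-data-set significance summaries. Modelling is on the natural-log scale;
reported estimates carry a log2-converted column so fold-change displays
and model output share units. The conversion happens once, in the contrast
table.

*Confounder adjustment.* The adjusted variant appends four
`timepoint:group:factor` columns (one per arm, including the reference) for
a per-subject clinical delta. Rank-deficient columns (e.g. a factor with no
within-arm variance) are dropped by pivoted QR with a warning. Features
whose vs-SAL contrast loses q < 0.05 under adjustment are flagged
confounder-sensitive.

*Power analysis.* Bootstrap on the per-subject paired log-changes: the
target arm is resampled with replacement to the target size, the control
arm held fixed, the two-group contrast + BH rerun per resample, and the
distribution of significant-feature counts reported. The paired-difference
formulation is the balanced closed form of the mixed model restricted to
two arms, so resample counts match full refits.

### Fold-change PCA

Per-subject log2(week4/baseline) matrices are decomposed by SVD after mean
centering (unit-variance and Pareto scaling optional; centering is the
minimal choice and the default because the data are already on a
per-feature ratio scale). Sign convention: the largest-magnitude loading of
each component is positive. Missing fold-change cells are feature-mean
imputed for this stage only. Score separation between arms is tested per
component by one-way ANOVA plus pairwise Welch t, BH-adjusted within the
component.

### PLS against clinical factors

NIPALS PLS1 on column-centered, unit-variance-scaled X and centered y —
the chemometrics convention for metabolomic blocks; no random
initialisation, so the whole stage is deterministic given data and seed.
Q²Ŷ = 1 − PRESS/TSS from k-fold CV (default 7 folds, stratified by arm when
the full cohort is modelled) with centering/scaling refit inside each
training fold; TSS measures test deviations from the training-fold mean, so
a no-better-than-mean model scores ≤ 0. Model validity follows the
two-threshold rule Q²Ŷ > 0.15 and permutation p < 0.01 against B
mismatched-Y null models (default B = 1000; the validation battery uses
B = 200, whose add-one p floor 1/201 still resolves the 0.01 threshold).
The component count is fixed by the caller or chosen as the CV-Q² argmax
over 1..5.

*Feature selection.* Per-feature empirical p compares component-1 weights
between the true model and the B permutation nulls with the add-one
estimator, two-sided on |w| (a signed one-sided variant is available). The
comparison is made on the covariance scale X̃ᵀỹ rather than on per-model
unit-normalised weights: normalising divides every weight by the vector
norm, and when many features carry signal the true model's norm is inflated
relative to the nulls', shrinking every true weight and destroying the
calibration of the feature-wise comparison (measured: sensitivity drops
from 1.0 to ~0.4 and the null selection rate from 5% to 0 in the
200-informative-of-500 design). Selection is only reported for valid
models.

### Congruence and chain matching

Mean log2 fold change per feature per arm with t-based 95% CIs; Pearson r
(p via the t transform, two-sided) between arm pairs over all features in
the grouping. Categories partition features by the vs-SAL q-values:
shared (VLCD and RYGB both q < 0.05), unique to one intervention, or
nonsignificant; the VLCD–RYGB correlation is recomputed within each
category. Clinical correlations are per-feature Pearson r of fold change
vs clinical delta, cohort-wide or per arm, displayed at unadjusted
p < 0.05 (figure-legend convention) with an optional BH column; the PLS
stage is the stricter arbiter of clinical association.

Chain matching requires exact (carbons, double-bonds) equality. Free fatty
acids match acylcarnitines and lysophospholipids on their single chain,
phosphatidylcholines on the sn-2 chain read from name order (sum
compositions such as TG(48:1) and ambiguous names are excluded, not
guessed), and ceramides/sphingomyelins on the N-acyl chain. Each match
contributes one point per arm (x = FA mean fold change, y = partner's) and
Pearson r is pooled per partner class, with lysophospholipid subclasses
reported both separately and pooled. A very-long-chain flag (≥ C24)
propagates to match rows so the divergent behaviour of C24:0/C26:0 species
can be filtered.

## Synthetic-study generator

Log2 intensity: y = μ_f + b_subject + drift_f·1{wk4} + δ_{f,g}·1{wk4}
(+ slope·clinical_delta·1{wk4} for linked features) + ε; intensities are
2^y, hence strictly positive. Defaults and rationale:

| parameter | default | why |
|---|---|---|
| arm sizes | SAL 11, GOP 14, VLCD 22, RYGB 21 | the emulated cohort (68 subjects) |
| σ_subject | 0.8 log2 | between-person metabolite variation dominates |
| σ_resid | 0.4 log2 | within-person/technical variation over 4 weeks |
| baseline μ_f | U(8, 20) log2 | typical LC-MS dynamic range |
| fraction affected (VLCD/RYGB) | 1/3 | upper end of the observed altered fraction |
| effect magnitudes | {0.5, 1.0} log2 | plausible moderate/strong shifts; no published effect-size table exists, so these are calibration choices |
| VLCD–RYGB effect correlation | 0.9 | the two caloric-restriction arms act near-congruently |
| GOP effects | none | the infusion alters almost nothing |
| SAL drift | sd 0.05 log2 | small common time drift; cancels in interactions |

Correlated VLCD/RYGB effects are drawn from a bivariate normal (magnitudes
× template signs when a class template is used); the realised correlation
is recorded in the ground truth. The caloric-restriction template assigns
signs by metabolite class (acylglycerols −, fatty acids and acylcarnitines
+, phospho- and lysophospholipids −, ketone bodies and TCA intermediates
+; very-long-chain ≥ C24 fatty species flipped to −) and gives RYGB extra
effects (BCAAs, tyrosine and caffeine metabolites −, TMAO +). Clinical
deltas are drawn per arm with qualitative-pattern defaults (weight loss
deepening SAL→RYGB, glucose lowering largest for GOP, triglycerides down
with VLCD but slightly up with RYGB); they are config-overridable and
never used as acceptance values.

What the generator does *not* emulate: batch/run-order drift, missingness
mechanisms, heavy-tailed or correlated residuals across features,
retention-time structure, or real annotation error rates. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data pathologies.

## Validation battery and problem sizes

The operating-characteristic studies (in `metaboresponse.validation`, run
by the tests and re-reported by `scripts/acceptance.py`) use: 100 null
studies × 500 features for FDR calibration; 1000 features for effect-
recovery bias/coverage; 100 seeds × 500 features for PCA separation under
template effects; 200 null replicates + 100 validity runs (n = 60,
p = 100, B = 200) for PLS null behaviour and 100 runs for the strong-signal
(true R² = 0.9) case; 100 seeds of the 200-informative-of-500 design
(n = 60, weight-linked features, slope 0.3) for selection sensitivity and
specificity; 100 seeds × 500 features for congruence recovery at target
ρ = 0.9 and for the disjoint-effects sharing study; and a constructed
anti-correlated FA/(lyso)phospholipid panel for chain-match recovery. These
sizes give Monte-Carlo standard errors small relative to the asserted
margins while keeping the full battery to a few minutes on one core.

## Known limitations

- Both vs-SAL contrast families share the small control arm, so false
  discoveries are positively correlated between the VLCD and RYGB families
  (t-statistic correlation ≈ 0.3 at these arm sizes). In the
  disjoint-effects design this produces a spurious same-direction "shared"
  feature in roughly 9% of runs — a property of the vs-control design
  itself, invariant to the noise scale, worth remembering when reading
  shared/unique categorisations from studies with small control arms.
- One random intercept only: no crossed or nested random effects, no
  serial correlation, two timepoints only.
- Containment df is conservative for unbalanced missingness patterns.
- Lipid shorthand covers the classes listed in the grammar; ether lipids
  and plasmalogens are out of scope, and sn-position assignment trusts the
  annotation's name order.
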