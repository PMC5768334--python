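# Methods

## The screening model

The screen targets a specific expression pattern: a *subpopulation* of lung
tumors with very high expression of a transcript that is quiet in normal
lung.  Group means alone miss this pattern, so the unit of analysis is the
elevated subpopulation.

For each probeset, with log2 intensities `x` and lung-normal summary
statistics `avg_n`, `sd_n` (sample sd, n−1 denominator throughout):

* elevation cutoff: `c = avg_n + 3·sd_n`; a sample is elevated iff `x > c`
  (strictly; ties at the cutoff are not elevated).  Under a Gaussian null
  ~0.13% of normal samples exceed their own cutoff, so `% elevated_normal`
  is near zero unless the normal group is itself heavy-tailed.
* `% elevated_tumor`, `% elevated_normal` on the 0–100 scale.
  `% elevated_normal` is computed over **lung** normals — the group that
  defines the cutoff; non-lung tissues are reported as per-tissue means
  (`avg_<tissue>` columns) for toxicity triage but never enter the score.
* `avg_tumor_elevated`: mean over the elevated tumor samples only;
  undefined when no tumor sample is elevated, which makes the probe
  unrankable and fails the filter automatically.
* `log2 ratio elevated = avg_tumor_elevated − avg_n`.

Five filter criteria (defaults in `FilterCriteria`): `avg_tumor_elevated > 5`,
`% elevated_tumor > 25`, `log2 ratio elevated ≥ 2`, both Welch t and
Mann-Whitney U p-values `< α/N` (Bonferroni; `N` is always the number of
probes actually screened after the surface filter, never a constant), and
Gaussian Hellinger distance `> 1/3`.  Strict `>`/`<` everywhere except the
ratio, which is inclusive (`≥`).  Passing probes are ranked by descending
MarkerScore `(% elevated_tumor − % elevated_normal)·(log2 ratio elevated)`;
undefined scores sort last and ties break on probe id so output is
deterministic.

Statistical conventions, where more than one choice was defensible:

* **t-test** is Welch's (unequal variances): tumor and normal groups differ
  in both size and spread, and the pooled test gains nothing here.  Both
  groups constant and equal gives p = 1 by convention.
* **Mann-Whitney U** uses the two-sided normal approximation with tie
  correction and continuity correction.  At very small n this
  approximation is known to drift from the exact permutation distribution
  (worst |Δp| ≈ 0.031 at 4 vs 4, at mid-range U; below 0.01 for exact
  p < 0.3); at the screen's group sizes (tens of samples) the drift is
  negligible.
* **Hellinger distance** is computed in closed form between Gaussians fitted
  by group mean/sd:
  `H² = 1 − sqrt(2·s₁s₂/(s₁²+s₂²))·exp(−(m₁−m₂)²/(4(s₁²+s₂²)))`.
  A histogram-based estimator was rejected as bin-sensitive; the closed
  form is deterministic and verified against numerical quadrature to 1e-6.
  Probes with a zero-variance group get an undefined distance and fail the
  Hellinger criterion.
* **Dunnett** (lung tumor as control vs. normal tissues) and **Tukey**
  (between histologies) come from scipy and use pooled variances, as those
  procedures are defined; with a single comparison group Dunnett reduces to
  the pooled two-sided t-test.

## Compendium handling

Matrices are probe-major TSV with complete data; missing values are
rejected rather than imputed because every screen statistic assumes
complete per-group samples.  `normalize_to_reference` is a deliberate
simplification: each sample is median-shifted on the log2 scale to a
reference sample (or to the sample of median total intensity).  Full
between-array normalization of raw data is out of scope — real compendia
are expected to arrive already normalized — and the screen's statistics
depend only on relative per-probe group differences.  The surface filter is
a plain list intersection preserving matrix order; its retained count is
the Bonferroni `N`.

## IHC conventions

The heterogeneity score averages percent-cells over stained cores
(intensity ≥ 1) only.  A group with no stained core reports 100% ± 0% —
uniformly unstained is still uniform.  These two rules cannot be unified:
including unstained cores at 100% in mixed groups would contradict
observed single-stained-core summaries (e.g. one core at 5% among seven
unstained reports 5%, not 88%).  Printed percentages use half-up rounding
to integers, keeping one decimal only for values exact at that precision
(12.5% from 1/8).  One reference positivity cell (CA12 lung tumor) is
internally inconsistent in its source — counts 16/26/44/11 give
81/97 = 83.5% → 84, not the printed 83% — and is reported as recomputed.

## Survival layer

Overall survival in months; administrative censoring truncates times beyond
60 months and clears the event flag.  KM estimation and the k-sample
log-rank test are delegated to lifelines.  Splits: median (ties low —
deterministic and conventional), tertiles at the 1/3 and 2/3 empirical
quantiles (linear interpolation; 1..10 splits 4/3/3).

The metagene is PC1 of z-scored probe expression, computed by SVD; the
loading sign is fixed so its sum is positive (first nonzero loading
positive on an exact-zero sum), making the high/low dichotomization
reproducible across solvers.  Negating the entire input flips the scores,
so the median split yields the same partition with swapped labels — a
loading-sign convention cannot make the labels themselves invariant.

Martingale residuals of the covariate-free Cox model are
`event − H(t)` with `H` the Nelson–Aalen cumulative hazard, computed
directly (ties aggregated; censorings at an event time count as at risk for
it) so the residuals sum to zero to machine precision.  The survival tree
regresses these residuals on marker values: exhaustive search over
covariate midpoints maximizes the reduction in residual sum of squares,
and each chosen split reports
`chi_square = SSE reduction / (parent SSE/(n−1))`, a one-df chi-square
approximation to the split's significance.  Defaults `min_node=20`,
`max_depth=2` suit two-marker subgroup discovery; ties in the gain keep the
first covariate in column order and the smallest cutpoint.

## Synthetic data: what it does and does not emulate

`simulate_compendium` draws each probe as one Gaussian across all samples
(background mean uniform on 4–10 log2 units, sd 0.5 — the intensity range
and within-probe noise typical of normalized oligonucleotide array data),
then shifts a Bernoulli(`elevated_fraction`) subset of tumor samples by
`effect_log2` for each planted marker; subset membership is re-drawn per
seed and the realized subset recorded in the truth object, so the realized
elevated percentage is itself stochastic, as it is in patients.
`leak_tissues` shifts whole non-lung groups to model toxicity-relevant
background expression.  Default group sizes (60 tumor / 40 normal) are a
desk-scale stand-in for the compiled cohort (262/161/246); simulations in
the tests and the acceptance script use these sizes so they run in seconds.
Statistical power at 60/40 is materially lower than at the full cohort
scale — in particular, the rank-based U-test at a Bonferroni threshold is
the binding criterion for markers elevated in only half the tumors (pass
probability ≈ 0.65 per seed at effect 3, fraction 0.5, 500-probe
Bonferroni), whereas at 262/161 the same configuration passes essentially
always.  Recovery results at desk scale therefore bound the full-scale
behavior from below.

Not emulated: probe-level (CEL) structure, batch effects, platform
artifacts, heavy-tailed noise, correlated probes of one gene, or
nonproportional hazards.  Passing tests demonstrate the pipeline's
correctness and calibration under the stated generative model, not the
biological validity of any particular marker.

`simulate_ihc` draws intensities from a categorical distribution and
percent-stained from a normal (default 80 ± 20) truncated to (0, 100];
`simulate_survival` generates exponential event times with hazard
`baseline_rate · HR^z` (z the z-scored expression; default baseline 0.02
events/month puts median survival near 35 months, inside the five-year
window) and censors at the horizon.  All generators take explicit seeds and
never touch global random state.

## Numerical and degenerate-input choices

* Zero-variance groups: t-test p = 1 when means agree (0 otherwise);
  all-tied Mann-Whitney p = 1; Hellinger undefined.
* `elevation_stats` requires ≥ 2 normals (sd undefined otherwise) and ≥ 1
  tumor sample.
* Degenerate splits (all values identical; coincident tertile cutpoints)
  raise; the CLI reports them per covariate and continues.
* `censor_horizon = 0` in the generator yields an all-censored cohort at
  time 0 (valid but unanalyzable: the log-rank test then raises).
* KM at a time before the first observed time is 1 by definition.

## Known limitations

* The screen assumes pre-normalized, complete matrices; the provided
  normalization is a location shift only.
* Hellinger distances inherit the Gaussian fit; strongly bimodal tumor
  distributions (the very pattern planted markers produce) are summarized
  by a single inflated sd, which is conservative for the `> 1/3` criterion.
* The survival tree reports approximate chi-squares without honest
  post-selection inference; cutpoints are exploratory.
* Dunnett/Tukey assume homoscedastic groups; with strong variance
  heterogeneity their familywise control is approximate.
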