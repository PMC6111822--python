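# Methods

## Survival analysis

Patients are dichotomized at the **median** expression of the stratifying
gene: strictly above the median is "high", at or below is "low". The tie
rule (ties → low) is deterministic and matches the convention that "high"
means strictly above the cut-off; with no ties the groups differ in size
by at most one.

The survival curve per group is the product-limit (Kaplan–Meier) estimate
S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) with Greenwood variance
S(t)² Σ d_i/(n_i(n_i − d_i)). "Mean survival time" is reported as the
**restricted mean survival time** (RMST), the exact rectangle-sum area
under S from 0 to a truncation time τ. τ defaults to the largest observed
time (event or censored) and is configurable; when two groups are
compared the pipeline uses one shared τ so the areas are comparable. The
RMST standard error is the standard restricted-mean formula

    var(RMST) = Σ_i A_i² · d_i / (n_i (n_i − d_i)),   A_i = ∫_{t_i}^{τ} S,

and the confidence interval is the symmetric normal interval on the RMST
scale (no log transform). This is the convention of common clinical-stats
packages that print "mean survival" with a CI. The RMST to τ depends only
on data up to τ: censoring all follow-up at τ leaves it unchanged. Note
that *adding* subjects censored beyond τ does change the estimate — they
enlarge every earlier risk set — which is correct behaviour, not a bug.

The two-group comparison is the standard log-rank test (implemented via
`lifelines`), with a χ²(1) two-sided p-value.

## Signature derivation

Within each cohort, every gene (the driver excluded) is scored by a Welch
unequal-variance t statistic, high group minus low group, and ranked
descending (rank 1 = most up-regulated with the driver); ties break
lexicographically. A plain mean-difference ("fold change" on the log
scale) ranking is available behind a flag. Across cohorts, a gene's
**consistency score is its worst (maximum) rank** — a maximin rule: a
gene must rank well in *every* cohort to qualify. The k genes with the
smallest worst-rank (ties: sum of ranks, then symbol) join the driver,
driver first, all signs +1 by default, giving the m = k + 1 query
signature.

Gene–gene association uses the sample Pearson correlation with the exact
t-transform p-value (n − 2 degrees of freedom).

## Connectivity mapping

Reference profiles are complete signed rankings of the G-gene universe
(magnitude G = strongest response; the sign encodes direction). The
connection strength, its normalization, the null moments with
finite-population correction, and the replicate-combination rule (sum of
scores, sum of moments) are given in the README. Choices worth recording:

* **Null model.** Random signatures are m genes drawn uniformly without
  replacement with all signs +1; signature signs are equivalently
  absorbed into the profile's signed ranks. The default p-value is the
  one-tailed normal approximation Φ(z) (negative tail for reversal
  screens); enumeration over all C(G, m) signatures (exact, capped at
  10⁵ combinations) and seeded Monte-Carlo with the add-one estimator
  p = (1 + k)/(1 + n_draws) (so p > 0 always) serve as verification
  modes. At G ≥ 100, m ≤ 20 the analytic z matches the empirical null to
  well under 0.05; at toy sizes (G ≤ 10) the normal tail is inaccurate
  and the exact mode is the reference.
* **Replicate combination.** Scores and null moments are summed across a
  drug's replicates, treating null draws as independent per replicate;
  n identical replicates therefore gain a factor √n in |z|, the usual
  averaging gain.
* **Significance.** The per-drug threshold is exactly 1/N. The expected
  count of falsely significant drugs under the null is then one, which is
  verified by simulation (mean significant count over 200 null libraries
  within 3 standard errors of 1), and the reported "expected FDR" of a
  screen with n significant drugs is 1/n.
* **Perturbation stability** is the fraction of the m leave-one-out
  signatures under which the drug's p stays below the threshold; it takes
  values in {0, 1/m, …, 1} and "passing the stability test" means 1.0.
  Stability is computed analytically even when the headline p-value is
  Monte-Carlo: m re-samplings per drug would add cost with no accuracy
  gain in the CLT regime where the screen operates. The screening loop
  uses a closed-form leave-one-out update (drop the gene's contribution
  from c; shrink the null moments from m to m − 1 genes), verified in the
  tests against literal re-scoring.
* **Ranking** is ascending p, then descending stability, then ascending z
  (strongest reversal first), with the drug id as a final deterministic
  tie-break. The significance plot draws −log10(p) per drug with the
  threshold line at −log10(1/N) — 3.16 for N = 1432 — marking stable
  significant drugs (green) apart from unstable ones (red).

## Synthetic data

`simulate_cohort` draws the driver's expression standard normal per
sample; each of the `block_size` co-regulated genes is
ρ·driver + √(1−ρ²)·noise (ρ = `block_coupling`), one anti-gene gets the
same construction with a negative sign, and the remaining genes are
independent noise. Values are shifted by a constant 8.0 to mimic
log2-scale array intensities. Survival is exponential proportional
hazards: hazard = `baseline_hazard` · exp(`hazard_coef` · driver z-score),
so `hazard_coef` > 0 makes driver-high patients die sooner; defaults
(β = 0.7, baseline 0.01/month, n = 200, 1000 genes, 15 block genes at
ρ = 0.7, anti-gene at 0.4, 20 % censoring) give cohorts in which the
median split separates survival decisively and the block is recoverable,
comparable in size to the two ~230-patient cohorts the analysis design
assumes.

Censoring is by independent thinning: with probability `censor_rate` a
sample is censored at a uniform fraction of its event time. This is
simple and seed-reproducible but **informative** (the censoring time is
proportional to the event time), so KM estimates on heavily thinned
cohorts are biased slightly upward; the CI-coverage property of the RMST
machinery is therefore established under independent exponential
censoring, which is the assumption the product-limit estimator actually
makes. The generator does not attempt platform noise models, batch
effects, probe-level structure, or LINCS L1000 landmark inference.

`simulate_reference_library` draws per-replicate, per-gene differential
statistics i.i.d. standard normal and converts them to signed ranks; a
planted reverser has the signature genes' statistics shifted by
−`reversal_strength`·sign before ranking, so at strength 3 the signature
genes land near the top magnitudes with negative signs and the drug
scores z ≈ −6 or beyond with m = 16, G = 1000. Replicate counts are
uniform on `n_replicates_range`. Everything is deterministic given the
config seed.

What passing tests on this generator do **not** show: robustness to
correlated null genes, to incomplete profile coverage of the signature,
to platform-specific rank distortions, or to survival endpoints that
violate proportional hazards.

## Numerical and interface choices

* Probe collapsing keeps, per gene, the probe with the highest mean
  expression (ties: lexicographically smaller probe id); the rule is a
  documented, swappable default since array studies rarely state theirs.
* Readers validate and reject rather than repair: duplicate ids,
  non-numeric cells (reported with coordinates), rank permutation
  violations and empty sample intersections are hard errors.
* Expression/clinical files are joined on the intersection of samples,
  preserving expression-header order; dropped counts are logged.
* Degenerate inputs: a constant stratifying gene labels every sample
  "low" (warning); zero observed events make the KM estimate an error; a
  zero-variance null (m = G) is an estimation error; an m = 1 signature
  skips the stability test with a warning.
* The acceptance script scales the screen to a 1432-drug, 1000-gene
  library with five planted reversers and two cohorts of 226 and 232
  samples; these sizes keep a full end-to-end run in seconds while
  matching the screen geometry the method targets.

## Known limitations

* The analytic p-value is a CLT approximation; for tiny gene universes
  use the exact mode.
* The expected-false-positive rule controls E[false positives], not the
  family-wise error rate; the reported 1/n FDR is an approximation that
  assumes the null drugs dominate.
* No Cox regression or multivariate adjustment is provided; the survival
  module covers the two-group nonparametric comparison only.
* GEO series matrices must be stripped to the plain TSV dialect (probe
  rows, sample columns) before loading; there is no SOFT/CEL support.
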