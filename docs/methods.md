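# Methods

This note documents the statistical machinery behind `hetvar`: the models,
the samplers and their numerical choices, the synthetic-data generator, and
the design decisions that were genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data preparation

* **305-day adjustment.** Total yield is regressed on lactation length by
  OLS over all records; `MP305 = TMP + b(305 - LL)`. In
  `paper_replication` mode the slope is fixed at the reference constant
  5.47111 kg/day; the default (`reestimate`) refits it, since a slope is a
  property of the data at hand. Records longer than 305 days are adjusted
  downward — the formula is applied symmetrically.
* **Heterozygosity covariate.** `HTZ = s(1-d) + (1-s)d` from the parents'
  Murrah gene fractions: the expected proportion of loci with one Murrah
  and one other-breed allele, entering the model as a linear fixed
  covariate (a heterosis proxy).
* **Seasons and contemporary groups.** Calving month maps to quarters
  (Jan–Mar = 1, …, Oct–Dec = 4); `cg_id = herd:year:season`. Groups with
  fewer than three records are flagged and excluded from *every* later
  stage, including the class assignment. The order (filter first, classify
  second) is a package decision; the alternative order is not implemented.
* **SD classes.** MP305 means per retained group are standardized
  (unweighted by group size, sample variance with divisor n−1) and the sign
  of the standardized mean labels the group: > 0 HIGH, ≤ 0 LOW. Class
  labels are therefore invariant to any positive affine transform of the
  yields. Ties at exactly zero go LOW.

## Pedigree algebra

The numerator relationship matrix `A` is built by the tabular method only
for oracle-scale pedigrees; the samplers use the sparse `A^{-1}` assembled
directly by Henderson's rules, with Mendelian-sampling variances
`d_i = 0.5 − 0.25(F_s + F_d)` from a Meuwissen–Luo inbreeding pass
(`use_inbreeding=False` reproduces Henderson's original non-inbred rules,
exact only for non-inbred pedigrees — kept for textbook checks). Unknown
parents are a single sentinel; unknown-parent groups are out of scope. The
property `A^{-1} A = I` is tested on random inbred pedigrees.

## The Gibbs samplers

Both samplers use single-site Gauss–Seidel location updates: each fixed
effect and each breeding value is drawn from its scalar normal full
conditional given everything else, sweeping fixed effects then animals in
pedigree order. The hot loops run under numba on CSR arrays of `W'W`
(`W = [X Z]`) and `A^{-1}`; one 60,000-cycle bivariate chain on ~2,400
records / ~3,700 animals takes ~25 s on one CPU. Identical seeds give
bit-identical draws.

* **Fixed effects.** One indicator column per contemporary group (no
  intercept), the HTZ covariate, and age centered at the subset mean
  (conditioning only; fits are unchanged). No identifiability constraint is
  imposed — the full conditionals are proper, and all reported quantities
  (variances, EBVs) are invariant to the unidentified level.
* **Scalar variances.** Scaled inverse chi-square conditionals:
  `sigma2_a | · = (a'A^{-1}a + nu0*S0) / chi2(q + nu0)` and likewise for
  `sigma2_e` with `e'e` and `n + nu0`. Defaults `nu0 = −2, S0 = 0`: the
  flat-prior convention (prior density constant in the variance).
* **Bivariate genetic covariance.** `G0 | a ~ IW(S_a + S0, q + df0)` with
  `S_a = [a_t' A^{-1} a_u]`, drawn by the Bartlett construction (validated
  against `scipy.stats.invwishart`). Residual covariance across classes is
  fixed at zero: no animal, and no contemporary group, contributes records
  to both classes, so it is inestimable — the standard multiple-trait
  missing-record treatment.

### Prior for G0: why df = −2

The prior degrees of freedom for a 2x2 covariance matrix deserve care, and
this was the one place where the obvious choices fail:

* A proper inverse-Wishart with small scale (`eps*I`) and positive df has
  density `|G0|^{-(df+3)/2}` — an improper spike at singular matrices.
  Because every animal has a record in at most one class, the IW
  conditional is nearly data-blind about the correlation, and a chain that
  wanders near `|rg| = 1` is regenerated there indefinitely: the chain pins
  at the boundary even when started at the truth, while a direct likelihood
  profile of the same data peaks in the interior.
* "Flat on G0" (df = −3, density constant) removes the spike but its
  marginal on the variance pair, after integrating the covariance over its
  admissible range `|c| < sqrt(va*vb)`, grows as `sqrt(va*vb)` — an
  increasing improper prior that measurably inflates a weakly informed
  genetic variance.
* **df = −2, scale 0** (density `|G0|^{-1/2}`) is the unique choice whose
  variance marginals are flat — the coherent multivariate analogue of the
  scalar `nu0 = −2` convention used everywhere else in the package — and
  its correlation marginal `(1 − rg^2)^{-1/2}` is integrable at the
  boundary. This is the default; all prior constants are configurable
  through `GibbsPriors`.

### Interweaving (ASIS) move

Even with a well-behaved prior, the correlation mixes poorly under pure
data augmentation: the IW conditional sees the correlation only through the
current breeding values, most of whose coordinates (founders, and the
off-class coordinate of every recorded animal) are prior-generated. Each
bivariate cycle therefore ends with an ancillarity–sufficiency interweaving
step: writing `a_low = L11*u1`, `a_high = L21*u1 + L22*u2` with
`G0 = LL'`, the ancillaries `(u1, u2)` are held fixed and the Cholesky
entries are redrawn as regression coefficients of the records on `u` — a
conditional informed purely by data. The Gaussian likelihood proposal is
accepted on the ratio of the induced prior
`p(L) ∝ L11^{-(df0+1)} L22^{-(df0+2)}` (the IW density times the Jacobian
`4 L11^2 L22`), so the move is exact Metropolis-within-Gibbs and the
posterior is unchanged. The full sampler was cross-validated against a
brute-force 5-D grid integration of the exact integrated likelihood on a
small fixture, and its location conditionals against dense GLS/MME
solutions.

### Chain defaults and start values

The study-scale configuration is 600,000 cycles, 60,000 burn-in, thinning
20 (27,000 retained draws); tests and the acceptance script use a reduced
60,000 / 6,000 / 20 chain, which the recovery experiments show is ample for
these data sizes. Variance chains start at 0.4 / 0.6 of the phenotypic
variance after OLS removal of the fixed effects (raw `var(y)` is dominated
by the contemporary-group spread and would start the chains far from any
plausible value). A cycle `c` (1-indexed) is retained iff `c > burnin` and
`(c − burnin) mod thin = 0`.

## Posterior summaries and diagnostics

Summaries report the mean, the posterior SD, the Monte-Carlo standard error
of the mean, the median and the equal-tailed 95% interval (2.5/97.5
empirical quantiles; not HPD). The MCSE uses nonoverlapping batch means
with ~sqrt(n) batches, which doubles as the spectral-density-at-zero
estimate in the Geweke diagnostic: `z` compares the first 10% and last 50%
window means, standardized by the batch-means variances of the window
means. On IID chains the 5%-level test is calibrated to within the binomial
noise of 1,000 replicates (tested). Derived chains (`h2` per trait, `rg`)
are summarized exactly like the sampled variances.

## Cross-analysis comparison

* **Z-test on heritabilities.** Default inputs: posterior means, the
  batch-means variances of those means, and the retained-draw count. A
  second variant uses the raw posterior variances without the `/n` factor —
  the convention under which a difference of posterior means is judged
  against the posterior spread itself; both are reported because the two
  conventions differ by a factor `sqrt(n)` and the literature is not always
  explicit about which is meant.
* **Spearman correlations** (scipy, average ranks for ties) over all sires
  and over the sires with strictly positive general-analysis EBVs; a sire
  is any animal appearing as sire of a retained record, and pedigree
  propagation guarantees every sire an EBV in every analysis.
* **EBV regressions** are computed in both orientations (class on general
  and general on class) for both classes, since either direction is
  defensible and they answer different calibration questions.
* The **heterogeneity verdict** is deliberately strict: both variance CIs
  disjoint *and* Z-test p < 0.05. CI disjointness depends on posterior
  widths, so at reduced chain/data scale the verdict can stay off while
  every point estimate shows the heterogeneity; the report prints the
  component verdicts so this is visible.

## Synthetic-data generator

The generator emulates the design the analysis assumes, with every random
quantity derived from one seed:

* **Pedigree:** 77 founder sires and 1,196 founder dams (about two recorded
  daughters per dam — typical for first-lactation data), each of the 2,392
  recorded animals drawing one sire and one dam uniformly, which spreads
  every sire's offspring across herds and classes — the links that make the
  cross-class correlation estimable. Founders carry Murrah fractions
  (mostly purebred, some crossbred) that drive the HTZ covariate.
* **Contemporary groups:** 10 herds with unequal sizes x 4 years x 4
  seasons (uneven season probabilities), giving ~150–160 retained groups of
  variable size, a few below the 3-record threshold. CG effects come from a
  two-component normal mixture whose components sit at the LOW/HIGH class
  mean yields (offsets −198 / +373 kg, component SD 110 kg, LOW fraction
  0.565); larger groups are tilted toward the LOW component, mimicking the
  field pattern that large average herds dominate the low-variability
  class and producing a ~65/35 record split from a ~57/43 group split.
* **Genetics:** founder BV pairs ~ N(0, G0) with G0 at the default truth
  (353.51 / 1134.22, rg 0.61); offspring = parent average + Mendelian
  deviation with covariance `(0.5 − 0.25(F_s+F_d)) G0`. A record's genetic
  term is the component matching its group's mixture class; residuals use
  the class variance (1480.62 / 2180.15). Age ~ N(73.8, 36.61²) truncated
  above 20 months; lactation length ~ N(270, 40²) truncated to [120, 365];
  small nonzero covariate effects (50 kg per unit HTZ, 1.5 kg/month age)
  keep covariate estimation exercised. TMP is back-computed from MP305
  through the true slope so preprocessing recovers MP305 exactly.
* **Class labels are emergent** by default — the real preprocessing
  classifies the simulated groups, and agreement with the generating class
  exceeds 98% (only knife-edge groups flip). `apply_true_classes` forces
  the generating labels for recovery tests that need the two-trait
  structure exactly.

What the generator does **not** emulate: selection and genetic trend,
maternal/permanent-environment effects, multi-generation pedigrees (all
parents are founders), non-Gaussian residuals, and seasonal lactation-curve
shape. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated model, not robustness to these
departures.

## What the recovery experiments can and cannot show

At the emulated design scale (77 sires, one record per animal, disjoint
classes) the cross-class genetic correlation is weakly identified: direct
likelihood profiling of simulated datasets shows per-dataset maximum-
likelihood estimates scattering with SD ≈ 0.2 around the truth, and the
posterior-mean high-class heritability scatters with SD ≈ 0.09–0.10
across datasets. Single-dataset estimates are therefore noisy by nature;
the acceptance experiment reports medians across nine replicate datasets,
whose sampling error (~0.04 on h2) makes the recovery bands a check of
centering rather than of luck.

## Known limitations

* Single-chain design: convergence is judged by Geweke windows, not
  multi-chain R-hat.
* The dense `A` is restricted to a few thousand animals; the sparse path
  has no such limit but the samplers are O(nnz) per cycle, so very large
  pedigrees (>10^5 animals) would want block updates.
* Residual covariance between classes is structurally zero; if a dataset
  had animals recorded in both classes the model would reject it rather
  than estimate the covariance.
* EBV uncertainty is not reported (only posterior means of `a` are kept;
  retaining full location draws is available but memory-heavy).
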