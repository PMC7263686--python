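# Methods

## Generative model of an FTL cross

A detector line carries eGFP and dsRed seed-fluorescence transgenes at known
positions on one chromosome, in coupling (cis) phase. Crossed to wild type,
the F1 is doubly heterozygous with both markers on the same homolog, and the
marker content of each transmitted gamete is read out in the seed.

Crossovers along the bivalent are modelled on the genetic scale as a
stationary renewal point process whose inter-event distances are
Gamma-distributed with integer shape `nu` and mean fixed so that the
expected crossover count in the interval equals the bivalent mean
`2*lambda` (`lambda` = per-gamete mean, i.e. the genetic length of the
interval in Morgans for that sex). Shape `nu = 1` is the Poisson
(no-interference) case; larger `nu` regularises inter-crossover spacing —
crossover interference. Restricting `nu` to integers makes the count
distribution exact via the Poisson-skip construction: with
`M ~ Poisson(nu * 2*lambda)` underlying points and an independent uniform
phase `U` on `{0, ..., nu-1}`, the crossover count is
`floor((M + U) / nu)`, whose mean is exactly `2*lambda` (the identity
`sum_u floor((m+u)/nu) = m` makes stationarity exact, not asymptotic). The
same construction yields crossover *positions* as every `nu`-th order
statistic of uniform points, used for double-crossover spacing and
three-marker simulation.

Each crossover involves a given chromatid with probability 1/2,
independently (no chromatid interference), so the gamete crossover count is
a Binomial(n, 1/2) thinning of the bivalent count. Because a Binomial(n,
1/2) count is odd with probability 1/2 for any n >= 1, the recombinant-
gamete probability reduces to

    p_rec = (1 - P(bivalent count = 0)) / 2,

which under `nu = 1` is Haldane's mapping function
`(1 - exp(-2*lambda)) / 2`. Gamete class probabilities follow from coupling
symmetry: `p_R = p_G = p_rec/2`, `p_RG = p_NFS = (1 - p_rec)/2`. Seed
counts for a cross of `n` seeds are multinomial in these four classes.

Physical-to-genetic mapping within an interval is uniform (constant cM/Mb);
the location-based landscape module handles between-interval variation, but
no within-interval landscape is imposed.

## Parameters and defaults

- `lambda_m`, `lambda_f` (per line): per-gamete mean crossover counts
  (Morgans) for male and female meiosis. The default eight-line models
  invert the observed per-line male/female recombination frequencies
  (percent; e.g. 33.44/28.24 for the longest interval) through the model's
  `p_rec(lambda, nu)` map, so the generator reproduces the study's own
  rate regime (line ratios ~1.18-3.2, mean near the canonical ~1.8-2).
- `nu_m = 2`, `nu_f = 4` by default: female interference stronger than
  male, a qualitative constraint from the *Arabidopsis* literature; the
  exact values are free parameters, not published estimates.
- Age effects: multiplicative factors on `lambda` per sex and age (days
  after sowing, default ages 40/45/50/55), defaulting to 1.0 everywhere —
  the replicated finding is *no* age effect — and configurable for power
  studies.
- Design: 2 detector roles (female detector = emasculated detector
  pollinated by wild type; male detector = detector as pollen donor) x 4
  ages x 3 replicates, with a per-cell budget of 2200 seeds split evenly
  across replicates, matching the study's reported scoring scale. The
  replicate count is a free parameter because the source description of
  replication is ambiguous.
- Default marker intervals are **synthetic placeholders**: exact insertion
  coordinates are not available in machine-readable form, so coordinates
  were constructed once to honour the documented geometry — the long
  interval spans the chromosome-1 centromere at 10.5 Mb, the other seven
  average 4.71 Mb, and the three low-ratio lines have no subtelomeric
  overlap. Supply a BED-like interval file for real data.

## Estimation

RF = 100 (R+G)/(R+G+RG+NFS) per scored cross; it is kept dimensionless (no
cM conversion) because two-marker RF undercounts multiple crossovers and is
meaningful here as a *relative* rate. Aggregation to mCO/fCO is by
unweighted mean of per-replicate RFs (matching a replicate-level linear
model) with seed-weighted pooling as an option. Two ratio conventions are
implemented because published per-line ratios are not all consistent with
one rule: `ratio_of_means` (default; reproduces the printed ratios for the
lines CTL1.2, CTL1.18, CTL2.4 and CTL4.7 at printed rounding) and
`mean_of_ratios` (mean of per-age ratios). Four published lines
(Col3-4/20, 3158, 3162, CTL5.17) match neither convention exactly at
printed precision; the package reports the convention with every summary
and does not force agreement. Rounding happens only at presentation.

## Age/sex inference and multiplicity

Replicate RFs are the response unit (approximately normal at ~700+ seeds
per replicate). A Gaussian identity-link GLM — fitted as OLS on group
indicators via statsmodels, so fitted group means are arithmetic means — is
followed by all pairwise group contrasts with the pooled residual variance
and its degrees of freedom. The family (default: the 6 age pairs within one
line x role; families are not pooled across lines) is adjusted with the
single-step max-|t| method: `p_adj_j = P(max_k |T_k| >= |t_j|)` under the
joint central multivariate t with the design-implied contrast correlation
and the fit's degrees of freedom. The tail probability is evaluated by
Monte Carlo (default 100,000 draws, explicit seed): sample
`Z ~ MVN(0, R)` via eigendecomposition (PSD-singular correlation matrices
— the generic case for 6 contrasts spanning 3 dimensions — are handled
natively; a non-PSD input falls back to an equicorrelation approximation
with a recorded warning) and divide by a shared `sqrt(chi2_dof/dof)`.
One shared sample per family makes adjusted p-values monotone in |t| by
construction; they are additionally floored at the raw p. At 100,000 draws
the Monte-Carlo jitter of the 5% critical value is small enough that the
realised family-wise error on null simulations sits at the nominal 5%
(about 6% at 20,000 draws — the quantile noise inflates rejections
second-order, which is why the default is 10^5).

## Non-detection analysis

In a two-marker interval a gamete with an even crossover count looks
parental, so RF undercounts crossovers. Three quantifications:

1. **Accounting adjustment**: given per-sex counts of meioses with 0/1/2/3+
   crossovers and a non-detection level `f` (the probability that each
   crossover additional to the first goes undetected), expected detected
   crossovers are `sum_k n_k (1 + (k-1)(1-f))`; the male:female ratio is
   recomputed and the percent change reported. The "3+" class is scored as
   3. This per-crossover-additional formalisation of the verbal rule is
   stated explicitly so alternatives (e.g. all-or-none per gamete) can be
   added; `f = 0` is the exact identity and detected totals are linear in
   `f`. With male multi-crossover meioses at the cited 1-9% and female at
   <=1%, `f = 0.10` lowers the ratio by order 1%.
2. **Odd/even gap**: the exact shortfall `(lambda - p_rec)/lambda` of the
   recombinant probability below the per-gamete mean count; 0 at
   `lambda = 0`, growing with interval genetic length.
3. **Double-crossover spacing**: among simulated meioses with exactly two
   crossovers, the fraction with the pair within a physical distance; under
   `nu = 1` the two positions are iid uniform with closed form
   `2u - u^2`, `u = d/L`, and interference strictly reduces the close-pair
   fraction. Monte Carlo with explicit seed and reported standard error; a
   sample without double crossovers is flagged inestimable with its size.

## Landscape prediction and zones

Predicted interval rates are the unweighted mean of the in-interval
landscape points (closed endpoints) times interval length in Mb, per sex;
the predicted ratio is their quotient (length cancels). Whether the
original interval-level computation averaged point-wise or length-weighted
is not stated, so a trapezoid mode is provided as a labelled alternative
and neither is asserted as "the" published procedure. Zone overlap is
closed-range interval arithmetic with a centromere-spanning flag. Default
zone boundaries (3 Mb telomeric caps, ±2.5 Mb pericentromeric bands around
approximate centromere midpoints) are placeholders — the study-specific
boundaries are not published in machine-readable form. The synthetic
landscape generator boosts male rates subtelomerically and female rates
pericentromerically with Gaussian noise, reproducing the qualitative
geography that makes subtelomeric-overlapping intervals predict higher
ratios; it does not emulate fine-scale hotspot structure.

## What the simulator does and does not emulate

It reproduces multinomial seed-class sampling at study scale, sex-specific
rates and interference, age-factor injection, and replicate structure. It
does **not** model scoring error or ambiguous seeds, segregation
distortion, transgene silencing, between-plant (cross-level)
overdispersion beyond multinomial noise, or within-interval rate
landscapes. Passing tests therefore validate the estimators and the error
control under the stated stochastic model, not robustness to those
real-data artefacts; the replicate-level linear model would absorb modest
overdispersion, but that is untested here.

## Numerical choices and problem sizes

- Count pmfs truncate at tail mass < 1e-9 (no renormalisation); Haldane
  agreement is tested to 1e-9, means to 1e-6.
- OLS residual sums of squares below 1e-12 of the response scale are
  treated as exactly zero, and a zero pooled variance makes contrasts an
  explicit error rather than silent infinities.
- Monte-Carlo checks in the suite use 1e5-1e6 draws with 3-4 SE bands and
  fixed seeds. The family-wise error simulation uses 1000 null studies at
  full per-study adjustment (10^5 draws each), the parameter-recovery check
  1000 cells of 2200 seeds — sizes chosen to make binomial error bands a
  few times tighter than the effects being excluded.
- All randomness flows from explicit seeds through `numpy` generators;
  study simulation spawns per-cell seed sequences, so results are
  reproducible bit for bit and invariant to how records are later grouped.

## Known limitations

- Integer-only interference shape (the exact-pmf construction requires it).
- Coupling phase only; no repulsion-phase detectors, no pollen-scored
  (single-gamete) FTL mode, no chromosome-scale multi-interval simulation.
- The non-detection accounting treats "3+" as exactly 3 and applies one
  global `f` per analysis.
- Default intervals, zones and landscape are synthetic stand-ins intended
  for simulation studies and demonstrations, not biological reference data.
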