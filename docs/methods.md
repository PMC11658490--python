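# Methods

## Designs and estimators

All five schemes draw units **with replacement** from a finite frame of N
paired values (x, y), rank small sets by a cheap key, and measure the study
variable y of designated ranks only:

| scheme | units handled per cycle | measured per cycle | designated ranks |
|--------|------------------------|--------------------|------------------|
| srs    | n/r                    | n/r                | — |
| rss    | m²                     | m                  | i-th of set i |
| drss   | m³                     | m                  | i-th of RSS-screened set i |
| emrss  | (2m)²                  | 2m                 | extreme-median pattern |
| demrss | (2m)³                  | 2m                 | pattern, on RSS-screened sets |

The extreme-median pattern over 2m sets designates, for even m: m/2 minima
(rank 1), m/2 maxima (rank 2m), m/2 lower medians (rank m) and m/2 upper
medians (rank m+1); for odd m the extremes get (m−1)/2 sets each and the
two median ranks (m+1)/2 each, interleaved as sets
(1, 2m, m, m+1, m, …, m+1).  Two-stage ("double") variants first reduce
each group of k² units to one pre-screened set of k by the diagonal RSS
rule, then re-rank that set — an explicit re-sort that is a no-op under
perfect ranking but essential under imperfect ranking — before applying the
designated rank.

Every estimator is the arithmetic mean of the measured values.  The
measured sample size is n = rm (srs/rss/drss) or n = 2rm (emrss/demrss),
and all efficiency comparisons are at matched n: the SRS comparator
variance is the analytic with-replacement value σ²/n, with σ² the
finite-population variance (divisor N).  PRE = 100·(σ²/n)/MSE uses the MSE
universally; for symmetric populations the extreme-median estimators are
unbiased and MSE = variance, while for skewed populations the bias term is
the dominant effect (below).

## Ranking modes and the additive-error model

The synthetic frame is x ~ F i.i.d., y = x + e with e ~ N(0, error_sd²)
independent of x (default error_sd = 1).  Perfect ranking sorts sets by y;
imperfect ranking sorts by x while still measuring y, so its ranking
quality is governed by ρ = sd(X)/√(var(X)+1): ≈ 0.28 for Uniform(0,1),
0.71 for Normal(5,1), 0.95 for Weibull(1.5,5), 0.99 for Gamma(4,3).  A
near-uninformative concomitant (the uniform case) necessarily pulls every
ranked design's PRE to ~100; this is a property of the model, not of any
particular scheme.

The frame is generated **once per distribution and held fixed** across all
Monte-Carlo iterations (generation is step one of the protocol, iteration a
later step); `StudyConfig(regenerate_population=True)` provides the
per-iteration-regeneration variant for sensitivity analysis.  A fixed
N = 1000 frame carries real sampling noise of its own — empirical tail
order statistics at set size 20 depend strongly on the frame's extreme
values — so headline quantities such as the maximum PRE over m vary
substantially between population realizations.  The acceptance tests
therefore widen their comparison band to the observed spread of the
statistic across five independent regenerations when that spread exceeds
the base tolerance.

Draws are with replacement because the double designs handle up to
(2m)³ = 8000 units per cycle at m = 10 from a frame of 1000; a
without-replacement reading is arithmetically impossible there.

## Theoretical variances

Single-stage expected order statistics E[X₍ᵢ:ₖ₎] are computed by quadrature
in probability space, ∫₀¹ Q(u)·Beta(i, k−i+1) du (absolute tolerance 1e-8),
which treats bounded and unbounded supports uniformly.  Two-stage means —
the second-stage law of the double designs, the i-th order statistic of a
set whose members are independent X₍₁:ₘ₎,…,X₍ₘ:ₘ₎ — are non-i.i.d. order
statistics with no convenient closed form and are estimated by seeded Monte
Carlo with per-entry standard errors (default 2·10⁵ replicates; m = 1
returns the exact distribution mean since no ranking occurs).

The RSS and DRSS variance formulas are exact: the full set of ranks
satisfies Σᵢ E[(X₍ᵢ:ₘ₎−μ)²] = mσ², which converts the sum of order-statistic
variances into σ² minus the φ² terms.  The extreme-median closed form
(σ²/2rm minus weighted φ² terms at ranks 1, m, m+1, 2m of set size 2m)
applies that identity to a *partial* rank set, so it is exact only at
m = 2, where the four designated ranks exhaust 1..4; for larger m it
misstates the variance (for the standard normal at m = 3 it is ~48% high,
and by m = 10 the expression goes negative).  The double extreme-median
closed form reuses single-stage order-statistic means, so it describes the
single-stage design; the realized two-stage variance is strictly tighter
already at m = 2.  Every `VarianceReport` for these designs carries a
`notes` field saying so, the test suite pins both facts (exactness at
m = 2 for the single-stage form; simulation strictly below the printed
form for the double design), and all relative-efficiency results are taken
from simulation, never from these closed forms.

## Bias of extreme-median designs on skewed populations

For right-skewed populations the designated-rank means do not average back
to μ: E[X₍₂ₘ:₂ₘ₎] sits far above μ while E[X₍₁:₂ₘ₎] is compressed against
the short left tail, giving the estimator a positive bias of roughly 0.2σ
at m = 10 for Gamma(4,3) or Weibull(1.5,5) shapes.  Bias does not shrink
with the number of cycles, so as m grows the MSE becomes bias-dominated
and the MSE-based PRE falls — below 100 for the skewed study populations
at large m, with the maximum over m attained at m = 3.  This is a genuine
property of extreme-median selection under asymmetry, reproduced
independently by the closed-form order-statistic means and by simulation.
Consequences quantified by the test suite: the scheme ordering
DEMRSS ≥ EMRSS ≥ DRSS ≥ RSS holds on symmetric populations but breaks at
the DRSS→EMRSS step on skewed ones, and PREs are not monotone in m there.

## Monte-Carlo engine

Ranking drawn units by a key is invariant under any strictly monotone
transform of the key, so for a finite frame the engine pre-sorts the
population once by the ranking key and replaces each drawn unit by its
integer position in the sorted frame: ranking positions is exactly ranking
keys, with key ties occurring only between repeat draws of the same unit
(hence harmless).  When the frame is small enough (N ≤ 65535 positions),
positions are encoded as 16-bit keys with `block = 65535 // N` key values
per unit and keys drawn uniformly on [0, block·N) — exactly uniform over
units by construction — because the radix sort of uint16 arrays is several
times faster than a float sort at these set sizes.  Larger frames fall back
to sorting int64 positions.  Selected positions map back to measured values
only after selection, so the hot loop is RNG + small-stride integer sorts.
A loop-based reference implementation of every selector (with per-unit
provenance: cycle, set, designated rank, first-stage origin) lives in
`demrss.designs`, and the test suite checks the two paths agree in mean and
variance.

For a distribution source (used by the theory-oracle and unbiasedness
tests), draws are i.i.d. floats ranked directly.  Under imperfect ranking
with additive error, no selection step ever depends on e (both ranking
stages use x), so e is added to the selected x values afterwards — an exact
distributional shortcut.

Tie-breaks everywhere are by stable order of draw; ties have measure zero
for continuous populations, and stability keeps every sampler
deterministic given its seed.  Study grids derive one child seed stream per
(distribution, scheme, m) cell from the master seed, so cells can be
subset or reordered without changing results; both ranking modes of a cell
share one stream (common random numbers), which makes the
perfect-vs-imperfect contrast exact when y ≡ x and tighter in general.

## Problem sizes

Defaults follow the full protocol: N = 1000, m = 3..10, r = 5, 100,000
iterations, both rankings, all five schemes.  The shipped studies use
reduced, documented sizes chosen to keep Monte-Carlo standard errors well
below the effects being tested: the acceptance script runs 20,000
iterations per cell (relative SE of an MSE ≈ √(2/20000) ≈ 1%); the test
suite uses 3,000 iterations for the max-PRE reproduction (SE ≈ 2.6%,
small against its ±20% band), a m ∈ {3, 6, 10} grid at 10,000 iterations
for the ordering properties, and 10⁵ replicates for unbiasedness checks.
All comparisons carry explicit Monte-Carlo standard errors and use 3–4 SE
bands.

## Known limitations

* Order-statistic variances and covariances are not computed; the
  covariance re-expression of the two-stage variance is used only as the
  inequality var(DRSS) ≤ var(RSS).
* No exact (combinatorial) evaluation of the two-stage non-i.i.d. order
  statistic law; Monte Carlo with standard errors stands in.
* The empirical-data mode treats the supplied table as the complete finite
  population and reports with-replacement PREs; finite-population
  corrections for without-replacement designs are out of scope.
* Weibull ML fitting of empirical columns is a descriptive convenience
  only.
* The synthetic generator covers continuous i.i.d. frames with additive
  Gaussian concomitant error; it does not emulate clustered, discrete or
  heteroscedastic data, so passing tests say nothing about ranking models
  whose error structure depends on x.
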