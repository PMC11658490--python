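# demrss

Ranked set sampling (RSS) raises the efficiency of mean estimation when
ranking a handful of units is cheap (visual inspection, an auxiliary
measurement) but measuring them is expensive — pasture yields, children's
weight, pollutant loads.  This package implements a family of such designs
as a tested simulation library:

* **SRS** — simple random sampling, the comparator;
* **RSS** — rank m sets of m units, measure the i-th ranked unit of set i;
* **DRSS** — double RSS: RSS-screened sets are re-ranked and RSS-sampled;
* **EMRSS** — extreme-cum-median RSS: 2m sets of 2m units contribute only
  extremes (ranks 1 and 2m) and medians (ranks m and m+1);
* **DEMRSS** — double extreme-cum-median RSS: the EMRSS pattern applied to
  RSS-pre-screened sets, aimed at heterogeneous and outlier-prone
  populations.

It provides the samplers (perfect ranking on the study variable y, or
imperfect ranking on a concomitant x), the mean estimators, closed-form
variances built from expected order statistics

```
var(μ̂_RSS) = (1/rm) [ σ² − (1/m) Σᵢ (μ_(i:m) − μ)² ],
```

and Monte-Carlo **percent relative efficiency** studies,

```
PRE = 100 · var(μ̂_SRS) / MSE(μ̂_k),    var(μ̂_SRS) = σ²/n,
```

at matched measured sample size n (n = rm for SRS/RSS/DRSS, n = 2rm for
EMRSS/DEMRSS; m is the set size, r the number of cycles).  The MSE form is
used throughout because the extreme-median estimators are biased for
asymmetric populations — a property the studies here quantify rather than
assume away.

## Worked example

```python
import demrss as drs

pop = drs.generate_population(drs.normal(5, 1), N=1000, error_sd=1.0, seed=42)
print(f"population: N={pop.N}, mu_y={pop.mu_y:.4f}, sigma2_y={pop.sigma2_y:.4f}, "
      f"rho_xy={drs.population_correlation(pop):.4f}")
for scheme in ("srs", "rss", "drss", "emrss", "demrss"):
    m = 1 if scheme == "srs" else 3
    r = 15 if scheme == "srs" else 5
    cfg = drs.DesignConfig(scheme, m=m, r=r, ranking="perfect")
    s = drs.empirical_performance(pop, cfg, iterations=20_000, seed=7)
    print(f"{scheme:6s} n={s.n:3d}  bias={s.bias:+.4f}  mse={s.mse:.5f}  "
          f"PRE={s.pre:6.1f} +- {s.se_pre:.1f}")
```

prints

```
population: N=1000, mu_y=4.8897, sigma2_y=1.9900, rho_xy=0.6952
srs    n= 15  bias=+0.0027  mse=0.13261  PRE= 100.0 +- 1.0
rss    n= 15  bias=-0.0019  mse=0.06887  PRE= 192.6 +- 1.9
drss   n= 15  bias=-0.0005  mse=0.05155  PRE= 257.4 +- 2.6
emrss  n= 30  bias=+0.0051  mse=0.02009  PRE= 330.2 +- 3.4
demrss n= 30  bias=+0.0085  mse=0.01217  PRE= 545.1 +- 5.5
```

The frame is a finite population of N = 1000 pairs with x ~ Normal(5, 1)
and y = x + e, e ~ N(0, 1), so ranking on x is imperfect with correlation
ρ ≈ 0.70.  Each line replicates one design 20,000 times against that fixed
frame: bias is measured against the population mean μ_y, and PRE compares
the design's MSE with the analytic SRS variance σ²/n at the same number of
measured units (note EMRSS/DEMRSS measure n = 2rm = 30 units at m = 3).
On this near-symmetric population every refinement helps: double-stage
screening plus the extreme-median pattern (DEMRSS) is ~5.5× as efficient as
SRS.  Rerunning with `ranking="imperfect"` shows every PRE shrink toward
100 as ranking errors creep in.

The same machinery is exposed on the command line:

```sh
demrss simulate --dist weibull:1.5,5 --m 3-10 --r 5 --iters 20000 --seed 1 --outdir run1
demrss empirical --data children.csv --y-col weight --x-col height --m 3-10 --r 1,2,3,4
demrss theory --dist uniform:0,1 --scheme rss --m 2 --r 1
```

`simulate` writes a long-format `results.csv` (one row per
distribution × scheme × m × ranking cell) plus a run manifest;
`empirical` treats any two-column numeric table as the finite population
and adds a population summary (means, coefficients of variation, ρ_xy).

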