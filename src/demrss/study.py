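"""Monte-Carlo relative-efficiency studies and the empirical-data workflow.

``run_simulation_study`` reproduces the synthetic-population protocol: for
each distribution a single finite population of size N is generated under
the additive-error model y = x + e (e ~ N(0,1)) and held fixed; every
(scheme, m, ranking) grid cell then replicates its design draw and reports
bias, variance, MSE and the percent relative efficiency against the
analytic with-replacement SRS variance sigma^2/n at matched n.

``run_empirical_study`` applies the same machinery to a user-supplied
two-column table (study variable y, concomitant x) treated as the finite
population, over an (r, m) grid.

Seeding: the master seed spawns one independent, cell-coordinate-keyed
stream per grid cell, so subsetting or reordering the grid never changes
any cell's result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import DesignConfig, SCHEMES
from .estimation import empirical_performance, mean_estimate, pre
from .populations import (
    DegeneratePopulationError,
    DistributionSpec,
    Population,
    gamma,
    generate_population,
    normal,
    population_correlation,
    uniform,
    weibull,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "default_distributions",
    "run_simulation_study",
    "run_empirical_study",
    "summarize_population_parameters",
    "fit_weibull",
    "plot_pre",
]

logger = logging.getLogger("demrss")

RESULT_COLUMNS = [
    "distribution", "scheme", "m", "r", "ranking", "n",
    "bias", "variance", "mse", "pre", "se_pre", "seed", "iterations",
]


def default_distributions() -> list[DistributionSpec]:
    """The four study populations: two symmetric, two right-skewed."""
    return [uniform(0, 1), normal(5, 1), gamma(4, 3), weibull(1.5, 5)]


@dataclass
class StudyConfig:
    """Grid specification for the simulation study (defaults: the full design)."""

    distributions: list[DistributionSpec] = field(default_factory=default_distributions)
    N: int = 1000
    m_range: tuple[int, ...] = tuple(range(3, 11))
    r: int = 5
    iterations: int = 100_000
    rankings: tuple[str, ...] = ("perfect", "imperfect")
    schemes: tuple[str, ...] = SCHEMES
    master_seed: int = 0
    error_sd: float = 1.0
    regenerate_population: bool = False

    def __post_init__(self) -> None:
        if not self.distributions or not self.m_range or not self.rankings or not self.schemes:
            raise ValueError("distributions, m_range, rankings and schemes must be nonempty")
        if self.iterations < 2:
            raise ValueError("iterations must be >= 2")
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}")


@dataclass
class StudyResult:
    """Long-format grid of performance summaries with provenance."""

    table: pd.DataFrame
    config: object
    populations: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(Path(path), index=False)

    def max_pre(self, scheme: str, distribution: str, ranking: str) -> tuple[int, float]:
        """(m, PRE) at the maximum PRE over m for one (scheme, dist, ranking)."""
        sub = self.table[
            (self.table.scheme == scheme)
            & (self.table.distribution == distribution)
            & (self.table.ranking == ranking)
        ]
        if sub.empty:
            raise KeyError(f"no cells for ({scheme}, {distribution}, {ranking})")
        row = sub.loc[sub.pre.idxmax()]
        return int(row.m), float(row.pre)


def _cell_seed(*entropy) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(e) & 0x7FFFFFFF for e in entropy])


def _feasible(scheme: str, m: int, N: int) -> bool:
    set_size = 2 * m if scheme in ("emrss", "demrss") else m
    min_m = 2 if scheme in ("emrss", "demrss") else 1
    return m >= min_m and set_size <= N


def run_simulation_study(config: StudyConfig, progress: bool = False) -> StudyResult:
    """Run the full (distribution x scheme x m x ranking) PRE grid."""
    rows: list[dict] = []
    populations: dict[str, dict] = {}
    dist_iter = enumerate(config.distributions)
    if progress:
        try:
            from tqdm import tqdm  # optional nicety

            dist_iter = tqdm(list(dist_iter), desc="distributions")
        except ImportError:  # pragma: no cover
            pass
    for di, dist in dist_iter:
        pop_seed = _cell_seed(config.master_seed, di, 999_983)
        pop = generate_population(dist, config.N, config.error_sd, seed=pop_seed)
        populations[dist.label()] = {
            "mu_y": pop.mu_y, "sigma2_y": pop.sigma2_y,
            "rho_xy": population_correlation(pop) if pop.sigma2_x > 0 else float("nan"),
        }
        for si, scheme in enumerate(config.schemes):
            for m in config.m_range:
                if not _feasible(scheme, m, config.N):
                    logger.warning(
                        "skipping infeasible cell scheme=%s dist=%s m=%d "
                        "(set size exceeds N=%d or m below scheme minimum)",
                        scheme, dist.label(), m, config.N,
                    )
                    continue
                for ranking in config.rankings:
                    # one stream per (dist, scheme, m): both rankings see the
                    # same unit draws (common random numbers), so the
                    # perfect-vs-imperfect contrast is not inflated by
                    # independent Monte-Carlo noise
                    cell_ss = _cell_seed(config.master_seed, di, si, m)
                    cell_seed_int = int(cell_ss.generate_state(1)[0] & 0x7FFFFFFF)
                    dc = DesignConfig(scheme=scheme, m=m, r=config.r, ranking=ranking)
                    if config.regenerate_population:
                        summary = _performance_regenerating(
                            dist, dc, config.iterations, config.N,
                            config.error_sd, np.random.default_rng(cell_ss),
                        )
                    else:
                        summary = empirical_performance(
                            pop, dc, config.iterations, seed=np.random.default_rng(cell_ss)
                        )
                    rows.append({
                        "distribution": dist.label(), "scheme": scheme, "m": m,
                        "r": config.r, "ranking": ranking, "n": dc.n,
                        "bias": summary.bias, "variance": summary.variance,
                        "mse": summary.mse, "pre": summary.pre,
                        "se_pre": summary.se_pre, "seed": cell_seed_int,
                        "iterations": config.iterations,
                    })
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return StudyResult(table=table, config=config, populations=populations)


def _performance_regenerating(dist, dconfig, iterations, N, error_sd, rng):
    """Sensitivity variant: a fresh finite population for every iteration.

    Loop-based (one draw per population), so intended for modest iteration
    counts; bias is measured against the distribution-level mean of y.
    """
    from .designs import select

    ests = np.empty(iterations)
    for it in range(iterations):
        pop = generate_population(dist, N, error_sd, seed=rng)
        ests[it] = mean_estimate(select(pop, dconfig, rng=rng))
    mu = dist.mean()
    sigma2 = dist.var() + error_sd**2
    dev = ests - mu
    mse = float((dev**2).mean())
    from .estimation import PerformanceSummary

    return PerformanceSummary(
        scheme=dconfig.scheme, m=dconfig.m, r=dconfig.r, ranking=dconfig.ranking,
        n=dconfig.n, n_iterations=iterations, mean_of_estimates=float(ests.mean()),
        bias=float(ests.mean() - mu), variance=float(ests.var()), mse=mse,
        pre=pre(sigma2 / dconfig.n, mse),
        se_mean=float(ests.std() / np.sqrt(iterations)),
        se_mse=float((dev**2).std() / np.sqrt(iterations)),
        se_pre=float(100.0 * (sigma2 / dconfig.n) / mse**2 * (dev**2).std() / np.sqrt(iterations)),
    )


# ---------------------------------------------------------------------------
# empirical-data workflow

def _validate_table(table: pd.DataFrame, y_col: str, x_col: str) -> pd.DataFrame:
    for col in (y_col, x_col):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not found in table (have {list(table.columns)})")
    sub = table[[y_col, x_col]].apply(pd.to_numeric, errors="coerce")
    bad = sub.index[sub.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(
            f"non-numeric or missing values in rows {bad[:20]}"
            + (" ..." if len(bad) > 20 else "")
        )
    return sub


def summarize_population_parameters(
    table: pd.DataFrame, y_col: str = "y", x_col: str = "x"
) -> dict:
    """N, means, coefficients of variation, Pearson correlation and Cxy.

    Cx = sd(x)/mean(x), Cy = sd(y)/mean(y) (population sd, divisor N);
    Cxy = rho_xy * Cx * Cy.
    """
    sub = _validate_table(table, y_col, x_col)
    y = sub[y_col].to_numpy(dtype=float)
    x = sub[x_col].to_numpy(dtype=float)
    pop = Population.from_xy(x, y)
    if pop.sigma2_x <= 0 or pop.sigma2_y <= 0:
        raise DegeneratePopulationError("zero variance: correlation undefined")
    if pop.mu_x == 0 or pop.mu_y == 0:
        raise ValueError("zero mean: coefficient of variation undefined")
    rho = population_correlation(pop)
    cx = np.sqrt(pop.sigma2_x) / pop.mu_x
    cy = np.sqrt(pop.sigma2_y) / pop.mu_y
    return {
        "N": pop.N, "mu_x": pop.mu_x, "mu_y": pop.mu_y,
        "Cx": float(cx), "Cy": float(cy),
        "rho_xy": float(rho), "Cxy": float(rho * cx * cy),
    }


def run_empirical_study(
    table: pd.DataFrame,
    y_col: str = "y",
    x_col: str = "x",
    m_values: tuple[int, ...] = tuple(range(3, 11)),
    r_values: tuple[int, ...] = (1, 2, 3, 4),
    schemes: tuple[str, ...] = ("rss", "drss", "emrss", "demrss"),
    rankings: tuple[str, ...] = ("perfect", "imperfect"),
    iterations: int = 20_000,
    master_seed: int = 0,
) -> StudyResult:
    """PRE grid over (r, m) treating a user table as the finite population."""
    if iterations < 2:
        raise ValueError("iterations must be >= 2")
    sub = _validate_table(table, y_col, x_col)
    pop = Population.from_xy(sub[x_col].to_numpy(float), sub[y_col].to_numpy(float))
    rows = []
    for rj, r in enumerate(r_values):
        for m in m_values:
            for si, scheme in enumerate(schemes):
                if not _feasible(scheme, m, pop.N):
                    logger.warning(
                        "skipping infeasible cell scheme=%s m=%d r=%d "
                        "(set size exceeds N=%d)", scheme, m, r, pop.N,
                    )
                    continue
                for ranking in rankings:
                    cell_ss = _cell_seed(master_seed, rj, m, si)  # shared across rankings
                    dc = DesignConfig(scheme=scheme, m=m, r=r, ranking=ranking)
                    summary = empirical_performance(
                        pop, dc, iterations, seed=np.random.default_rng(cell_ss)
                    )
                    rows.append({
                        "distribution": "empirical", "scheme": scheme, "m": m,
                        "r": r, "ranking": ranking, "n": dc.n,
                        "bias": summary.bias, "variance": summary.variance,
                        "mse": summary.mse, "pre": summary.pre,
                        "se_pre": summary.se_pre,
                        "seed": int(cell_ss.generate_state(1)[0] & 0x7FFFFFFF),
                        "iterations": iterations,
                    })
    result = StudyResult(
        table=pd.DataFrame(rows, columns=RESULT_COLUMNS), config={
            "m_values": list(m_values), "r_values": list(r_values),
            "schemes": list(schemes), "rankings": list(rankings),
            "iterations": iterations, "master_seed": master_seed,
        },
    )
    result.populations["empirical"] = summarize_population_parameters(
        table, y_col=y_col, x_col=x_col
    )
    return result


def fit_weibull(values) -> tuple[float, float]:
    """Descriptive maximum-likelihood Weibull (shape, scale) fit, location 0."""
    from scipy import stats

    shape, _, scale = stats.weibull_min.fit(np.asarray(values, float), floc=0)
    return float(shape), float(scale)


def plot_pre(result: StudyResult, path, ranking: str = "perfect") -> Path:
    """PRE-vs-m panels, one per distribution, lines per scheme (convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.table[result.table.ranking == ranking]
    dists = list(dict.fromkeys(df.distribution))
    fig, axes = plt.subplots(
        1, max(len(dists), 1), figsize=(4 * max(len(dists), 1), 3.5), squeeze=False
    )
    for ax, dist in zip(axes[0], dists):
        sub = df[df.distribution == dist]
        for scheme in dict.fromkeys(sub.scheme):
            cell = sub[sub.scheme == scheme].sort_values("m")
            ax.plot(cell.m, cell.pre, marker="o", label=scheme.upper())
        ax.set_title(dist)
        ax.set_xlabel("set size m")
        ax.set_ylabel("PRE (%)")
    axes[0, 0].legend(fontsize=8)
    fig.suptitle(f"PRE of mean estimators vs SRS ({ranking} ranking)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
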