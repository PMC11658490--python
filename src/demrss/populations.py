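"""Synthetic populations and distribution specifications.

The simulation frame is a finite population of ``N`` paired values
``(x, y)``: a cheaply observable concomitant variable ``x`` drawn i.i.d.
from a named continuous distribution, and the study variable
``y = x + e`` with additive Gaussian measurement structure
``e ~ N(0, error_sd**2)``.  Ranked-set designs rank on ``y`` (perfect
ranking) or on ``x`` (imperfect ranking) but always measure ``y``.

Population-level moments (``mu_y``, ``sigma2_y``, ...) are finite-population
parameters and therefore use divisor ``N``, not ``N - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "DistributionSpec",
    "Population",
    "DegeneratePopulationError",
    "generate_population",
    "population_correlation",
    "register_family",
    "uniform",
    "normal",
    "gamma",
    "weibull",
]


class DegeneratePopulationError(ValueError):
    """Raised when a population has zero variance where variation is required."""


def _make_uniform(params: tuple[float, ...]):
    a, b = params
    if not b > a:
        raise ValueError(f"uniform requires upper > lower, got ({a}, {b})")
    return stats.uniform(loc=a, scale=b - a)


def _make_normal(params: tuple[float, ...]):
    mu, sd = params
    if not sd > 0:
        raise ValueError(f"normal requires sd > 0, got {sd}")
    return stats.norm(loc=mu, scale=sd)


def _make_gamma(params: tuple[float, ...]):
    shape, scale = params
    if not (shape > 0 and scale > 0):
        raise ValueError(f"gamma requires positive shape and scale, got ({shape}, {scale})")
    return stats.gamma(a=shape, scale=scale)


def _make_weibull(params: tuple[float, ...]):
    shape, scale = params
    if not (shape > 0 and scale > 0):
        raise ValueError(f"weibull requires positive shape and scale, got ({shape}, {scale})")
    return stats.weibull_min(c=shape, scale=scale)


# family -> (builder, number of params, conventional parameterization note)
_FAMILIES: dict[str, tuple[Callable, int, str]] = {
    "uniform": (_make_uniform, 2, "(lower, upper) bounds"),
    "normal": (_make_normal, 2, "(mean, standard deviation)"),
    "gamma": (_make_gamma, 2, "(shape, scale)"),
    "weibull": (_make_weibull, 2, "(shape, scale)"),
}


def register_family(name: str, builder: Callable, n_params: int, note: str) -> None:
    """Register an additional continuous family.

    ``builder`` maps a parameter tuple to a frozen scipy.stats distribution
    and must raise ``ValueError`` on invalid parameters.
    """
    _FAMILIES[name] = (builder, n_params, note)


@dataclass(frozen=True)
class DistributionSpec:
    """A named continuous distribution with parameters.

    Thin, validated wrapper over a frozen ``scipy.stats`` distribution.
    ``params`` follow the family's conventional order, recorded in
    ``parameterization``; gamma and weibull use (shape, scale).
    """

    family: str
    params: tuple[float, ...]
    parameterization: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; known: {sorted(_FAMILIES)}"
            )
        builder, n_params, note = _FAMILIES[self.family]
        params = tuple(float(p) for p in self.params)
        if len(params) != n_params:
            raise ValueError(
                f"{self.family} takes {n_params} parameters, got {len(params)}"
            )
        object.__setattr__(self, "params", params)
        if not self.parameterization:
            object.__setattr__(self, "parameterization", note)
        builder(params)  # validate eagerly

    @property
    def frozen(self):
        """The underlying frozen scipy distribution (rebuilt on demand)."""
        return _FAMILIES[self.family][0](self.params)

    # -- total functions on the support ------------------------------------
    def pdf(self, x):
        return self.frozen.pdf(x)

    def cdf(self, x):
        return self.frozen.cdf(x)

    def ppf(self, q):
        return self.frozen.ppf(q)

    def mean(self) -> float:
        return float(self.frozen.mean())

    def var(self) -> float:
        return float(self.frozen.var())

    def std(self) -> float:
        return float(self.frozen.std())

    def rvs(self, size, rng: np.random.Generator):
        return self.frozen.rvs(size=size, random_state=rng)

    def is_symmetric(self) -> bool:
        """True for families symmetric about their mean (uniform, normal)."""
        return self.family in ("uniform", "normal")

    def label(self) -> str:
        inner = ", ".join(f"{p:g}" for p in self.params)
        return f"{self.family}({inner})"

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": list(self.params),
            "parameterization": self.parameterization,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(d["family"], tuple(d["params"]), d.get("parameterization", ""))


# Convenience constructors ------------------------------------------------

def uniform(lower: float = 0.0, upper: float = 1.0) -> DistributionSpec:
    return DistributionSpec("uniform", (lower, upper))


def normal(mean: float = 0.0, sd: float = 1.0) -> DistributionSpec:
    return DistributionSpec("normal", (mean, sd))


def gamma(shape: float, scale: float) -> DistributionSpec:
    return DistributionSpec("gamma", (shape, scale))


def weibull(shape: float, scale: float) -> DistributionSpec:
    return DistributionSpec("weibull", (shape, scale))


@dataclass
class Population:
    """A finite sampling frame of paired (concomitant, study) values.

    Moments are exact finite-population parameters (divisor ``N``).
    """

    x: np.ndarray
    y: np.ndarray
    N: int
    mu_x: float
    sigma2_x: float
    mu_y: float
    sigma2_y: float
    seed: int | None = None
    dist: DistributionSpec | None = None
    error_sd: float | None = None

    @classmethod
    def from_xy(
        cls,
        x,
        y,
        seed: int | None = None,
        dist: DistributionSpec | None = None,
        error_sd: float | None = None,
    ) -> "Population":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValueError("x and y must be 1-d arrays of equal length")
        if len(x) < 1:
            raise ValueError("population must contain at least one unit")
        return cls(
            x=x,
            y=y,
            N=len(x),
            mu_x=float(x.mean()),
            sigma2_x=float(x.var()),  # ddof=0: finite-population parameter
            mu_y=float(y.mean()),
            sigma2_y=float(y.var()),
            seed=seed,
            dist=dist,
            error_sd=error_sd,
        )

    # -- CSV + YAML sidecar round trip ------------------------------------
    def to_csv(self, path) -> None:
        """Write the frame as a 2-column CSV ``x,y`` with a YAML sidecar."""
        import pandas as pd

        path = Path(path)
        pd.DataFrame({"x": self.x, "y": self.y}).to_csv(path, index=False)
        sidecar = {
            "seed": self.seed,
            "error_sd": self.error_sd,
            "dist": self.dist.to_dict() if self.dist is not None else None,
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def from_csv(cls, path) -> "Population":
        import pandas as pd

        path = Path(path)
        df = pd.read_csv(path)
        seed = error_sd = dist = None
        sidecar = path.with_suffix(".yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
            seed = meta.get("seed")
            error_sd = meta.get("error_sd")
            if meta.get("dist"):
                dist = DistributionSpec.from_dict(meta["dist"])
        return cls.from_xy(df["x"].to_numpy(), df["y"].to_numpy(),
                           seed=seed, dist=dist, error_sd=error_sd)


def generate_population(
    dist: DistributionSpec,
    N: int,
    error_sd: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
) -> Population:
    """Generate a finite population under the additive-error regression model.

    ``x`` is drawn i.i.d. from ``dist``; ``y = x + e`` with
    ``e ~ N(0, error_sd**2)`` independent of ``x``.  Deterministic given
    ``seed``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if error_sd < 0:
        raise ValueError("error_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    x = np.asarray(dist.rvs(N, rng), dtype=float)
    e = rng.normal(0.0, error_sd, size=N) if error_sd > 0 else np.zeros(N)
    y = x + e
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return Population.from_xy(x, y, seed=seed_int, dist=dist, error_sd=error_sd)


def population_correlation(pop: Population) -> float:
    """Pearson correlation of (x, y) over the finite population."""
    if pop.N < 2:
        raise DegeneratePopulationError("correlation needs at least 2 units")
    if pop.sigma2_x <= 0 or pop.sigma2_y <= 0:
        raise DegeneratePopulationError("correlation undefined for zero variance")
    cov = float(np.mean((pop.x - pop.mu_x) * (pop.y - pop.mu_y)))
    return float(cov / np.sqrt(pop.sigma2_x * pop.sigma2_y))
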