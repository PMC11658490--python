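"""Unit-selection layouts for SRS, RSS, DRSS, EMRSS and DEMRSS.

Every design draws small sets of units with replacement from a finite
population, ranks each set cheaply — by the study variable ``y`` under
perfect ranking, or by the concomitant ``x`` under imperfect ranking — and
measures only designated ranks:

* RSS: m sets of m; set i contributes its i-th ranked unit (n = r*m).
* DRSS: two-stage RSS — m groups of m**2 units are first reduced by RSS to
  m sets of m pre-screened units, which are re-ranked and sampled by the
  same diagonal rule (n = r*m).
* EMRSS: 2m sets of 2m; the first m sets contribute extremes (minima, then
  maxima) and the last m sets contribute the two middle ranks m and m+1,
  following the even/odd-m layouts (n = 2*r*m).
* DEMRSS: two-stage EMRSS — 2m groups of (2m)**2 units are reduced by RSS to
  2m pre-screened sets of 2m, then the EMRSS pattern is applied (n = 2*r*m).

The selectors here are direct, loop-based reference implementations that
record per-unit provenance; the vectorized Monte-Carlo engine used for
performance studies lives in :mod:`demrss.estimation` and is tested for
distributional agreement against these.

Ties in ranking are broken by the stable order of draw (ties have measure
zero for continuous populations; stability keeps the samplers deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .populations import Population

__all__ = [
    "SCHEMES",
    "DesignConfig",
    "RankPattern",
    "RankedSample",
    "emrss_rank_pattern",
    "srs_select",
    "rss_select",
    "drss_select",
    "emrss_select",
    "demrss_select",
    "select",
]

SCHEMES = ("srs", "rss", "drss", "emrss", "demrss")
RANKINGS = ("perfect", "imperfect")


@dataclass(frozen=True)
class DesignConfig:
    """Scheme + set size m + cycles r + ranking mode; fully determines a design."""

    scheme: str
    m: int
    r: int = 1
    ranking: str = "perfect"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.ranking not in RANKINGS:
            raise ValueError(f"ranking must be one of {RANKINGS}, got {self.ranking!r}")
        min_m = 2 if self.scheme in ("emrss", "demrss") else 1
        if self.m < min_m:
            raise ValueError(f"{self.scheme} requires m >= {min_m}, got {self.m}")
        if self.r < 1:
            raise ValueError(f"r must be >= 1, got {self.r}")

    @property
    def n(self) -> int:
        """Measured sample size: r*m for srs/rss/drss, 2*r*m for emrss/demrss."""
        per_cycle = 2 * self.m if self.scheme in ("emrss", "demrss") else self.m
        return self.r * per_cycle

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "m": self.m, "r": self.r,
                "ranking": self.ranking, "seed": self.seed}

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class RankPattern:
    """Designated order-statistic rank per set for the extreme-median layouts."""

    m: int
    ranks: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != 2 * self.m:
            raise ValueError("pattern must designate one rank per set (2m sets)")
        if any(not 1 <= s <= 2 * self.m for s in self.ranks):
            raise ValueError("every designated rank must lie in 1..2m")


def emrss_rank_pattern(m: int) -> RankPattern:
    """Designated ranks of the extreme-cum-median layout for 2m sets of size 2m.

    Even m: sets 1..m/2 take the minimum (rank 1), the next m/2 sets the
    maximum (rank 2m), the next m/2 sets rank m and the last m/2 sets rank
    m+1.  Odd m: (m-1)/2 minima, (m-1)/2 maxima, then the middle block — set
    m takes rank m, set m+1 takes rank m+1, sets m+2..(3m+1)/2 take rank m
    and the final (m-1)/2 sets take rank m+1.
    """
    m = int(m)
    if m < 2:
        raise ValueError("extreme-median layouts require m >= 2")
    if m % 2 == 0:
        half = m // 2
        ranks = [1] * half + [2 * m] * half + [m] * half + [m + 1] * half
    else:
        half = (m - 1) // 2
        ranks = (
            [1] * half
            + [2 * m] * half
            + [m, m + 1]
            + [m] * ((3 * m + 1) // 2 - (m + 1))
            + [m + 1] * half
        )
    return RankPattern(m=m, ranks=tuple(ranks))


@dataclass
class RankedSample:
    """Measured study-variable values from one design draw, with provenance.

    ``provenance`` has one row per measured unit: cycle (1-based), set
    (1-based index among the cycle's sets), designated_rank (the order
    statistic measured), and for two-stage schemes stage1_set (the
    first-stage subset the selected unit originated from, 1-based).
    """

    values: np.ndarray
    provenance: pd.DataFrame
    config: DesignConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.config.n:
            raise ValueError(
                f"expected n={self.config.n} measured values, got {len(self.values)}"
            )

    def to_csv(self, path) -> None:
        df = self.provenance.copy()
        df["value"] = self.values
        df.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# selection helpers

def _ranking_key(pop: Population, ranking: str) -> np.ndarray:
    return pop.y if ranking == "perfect" else pop.x


def _rng_or_seed(config: DesignConfig, rng) -> np.random.Generator:
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return rng


def _check_indices(indices, shape, N) -> np.ndarray:
    indices = np.asarray(indices)
    if indices.shape != shape:
        raise ValueError(f"injected indices must have shape {shape}, got {indices.shape}")
    if indices.min() < 0 or indices.max() >= N:
        raise ValueError("injected indices out of population range")
    return indices


def srs_select(pop: Population, n: int, rng=None, indices=None) -> RankedSample:
    """Simple random sample of n units, with replacement; the comparator design."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if indices is None:
        indices = rng.integers(0, pop.N, size=n)
    else:
        indices = _check_indices(indices, (n,), pop.N)
    config = DesignConfig(scheme="srs", m=1, r=n)
    prov = pd.DataFrame(
        {"cycle": np.arange(1, n + 1), "set": 1,
         "designated_rank": pd.NA, "stage1_set": pd.NA}
    )
    return RankedSample(values=pop.y[indices], provenance=prov, config=config)


def rss_select(pop: Population, config: DesignConfig, rng=None, indices=None) -> RankedSample:
    """Single-stage ranked set sample: i-th ranked unit of set i, r cycles."""
    if config.scheme != "rss":
        raise ValueError("config.scheme must be 'rss'")
    rng = _rng_or_seed(config, rng)
    m, r = config.m, config.r
    key = _ranking_key(pop, config.ranking)
    if indices is None:
        indices = rng.integers(0, pop.N, size=(r, m, m))
    else:
        indices = _check_indices(indices, (r, m, m), pop.N)
    values, rows = [], []
    for j in range(r):
        for i in range(m):
            set_idx = indices[j, i]
            order = np.argsort(key[set_idx], kind="stable")
            chosen = set_idx[order[i]]
            values.append(pop.y[chosen])
            rows.append((j + 1, i + 1, i + 1, pd.NA))
    prov = pd.DataFrame(rows, columns=["cycle", "set", "designated_rank", "stage1_set"])
    return RankedSample(values=np.array(values), provenance=prov, config=config)


def _two_stage_cycle(key, group_indices, K):
    """First-stage RSS within one group of K*K units.

    Returns (member_unit_indices, member_origins): the K pre-screened units
    (origin row i contributed its i-th ranked unit), in draw order.
    """
    members, origins = [], []
    for i in range(K):
        row = group_indices[i]
        order = np.argsort(key[row], kind="stable")
        members.append(row[order[i]])
        origins.append(i + 1)
    return np.array(members), np.array(origins)


def drss_select(pop: Population, config: DesignConfig, rng=None, indices=None) -> RankedSample:
    """Double ranked set sample: RSS-screened sets re-ranked and RSS-sampled."""
    if config.scheme != "drss":
        raise ValueError("config.scheme must be 'drss'")
    rng = _rng_or_seed(config, rng)
    m, r = config.m, config.r
    key = _ranking_key(pop, config.ranking)
    if indices is None:
        indices = rng.integers(0, pop.N, size=(r, m, m, m))
    else:
        indices = _check_indices(indices, (r, m, m, m), pop.N)
    values, rows = [], []
    for j in range(r):
        for g in range(m):
            members, origins = _two_stage_cycle(key, indices[j, g], m)
            order = np.argsort(key[members], kind="stable")
            chosen = members[order[g]]
            values.append(pop.y[chosen])
            rows.append((j + 1, g + 1, g + 1, origins[order[g]]))
    prov = pd.DataFrame(rows, columns=["cycle", "set", "designated_rank", "stage1_set"])
    return RankedSample(values=np.array(values), provenance=prov, config=config)


def emrss_select(pop: Population, config: DesignConfig, rng=None, indices=None) -> RankedSample:
    """Extreme-cum-median ranked set sample over 2m sets of 2m units."""
    if config.scheme != "emrss":
        raise ValueError("config.scheme must be 'emrss'")
    rng = _rng_or_seed(config, rng)
    m, r = config.m, config.r
    K = 2 * m
    pattern = emrss_rank_pattern(m).ranks
    key = _ranking_key(pop, config.ranking)
    if indices is None:
        indices = rng.integers(0, pop.N, size=(r, K, K))
    else:
        indices = _check_indices(indices, (r, K, K), pop.N)
    values, rows = [], []
    for j in range(r):
        for s in range(K):
            set_idx = indices[j, s]
            order = np.argsort(key[set_idx], kind="stable")
            chosen = set_idx[order[pattern[s] - 1]]
            values.append(pop.y[chosen])
            rows.append((j + 1, s + 1, pattern[s], pd.NA))
    prov = pd.DataFrame(rows, columns=["cycle", "set", "designated_rank", "stage1_set"])
    return RankedSample(values=np.array(values), provenance=prov, config=config)


def demrss_select(pop: Population, config: DesignConfig, rng=None, indices=None) -> RankedSample:
    """Double extreme-cum-median ranked set sample.

    Per cycle: 2m groups of (2m)**2 units are each RSS-screened into one
    pre-screened set of 2m units; each pre-screened set is re-ranked (the
    explicit re-sort matters under imperfect ranking) and group s contributes
    the unit at the extreme-median pattern rank for set s.
    """
    if config.scheme != "demrss":
        raise ValueError("config.scheme must be 'demrss'")
    rng = _rng_or_seed(config, rng)
    m, r = config.m, config.r
    K = 2 * m
    pattern = emrss_rank_pattern(m).ranks
    key = _ranking_key(pop, config.ranking)
    if indices is None:
        indices = rng.integers(0, pop.N, size=(r, K, K, K))
    else:
        indices = _check_indices(indices, (r, K, K, K), pop.N)
    values, rows = [], []
    for j in range(r):
        for s in range(K):
            members, origins = _two_stage_cycle(key, indices[j, s], K)
            order = np.argsort(key[members], kind="stable")
            pos = order[pattern[s] - 1]
            values.append(pop.y[members[pos]])
            rows.append((j + 1, s + 1, pattern[s], origins[pos]))
    prov = pd.DataFrame(rows, columns=["cycle", "set", "designated_rank", "stage1_set"])
    return RankedSample(values=np.array(values), provenance=prov, config=config)


_SELECTORS = {
    "rss": rss_select,
    "drss": drss_select,
    "emrss": emrss_select,
    "demrss": demrss_select,
}


def select(pop: Population, config: DesignConfig, rng=None) -> RankedSample:
    """Dispatch one design draw by scheme."""
    if config.scheme == "srs":
        rng = _rng_or_seed(config, rng)
        return srs_select(pop, config.n, rng=rng)
    return _SELECTORS[config.scheme](pop, config, rng=rng)
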