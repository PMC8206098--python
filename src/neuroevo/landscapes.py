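"""Combinatorial fitness landscapes and the information-gain transform.

Two landscape families are provided.  NK landscapes assign fitness to binary
strings of length N as a sum of N random component tables, each depending on
K coordinates (the component's own coordinate plus K-1 random others); K
tunes ruggedness, from additive (K=1) to fully random (K=N).  Travelling
salesman instances assign fitness to permutations as the negated closed-tour
length.

To compare progress across landscape realisations, fitness f is transformed
to information gain ``I_f = -log2 q_f`` where ``q_f`` is the fraction of all
genotypes with fitness at least f (including f's own type, so q_f > 0).  A
median genotype thus carries 1 bit, a 75th-percentile genotype 2 bits, and
the global optimum of an N-bit landscape without fitness ties N bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "NKLandscape", "TSPInstance", "make_nk", "nk_fitness",
    "enumerate_fitness", "information_gain", "random_tsp", "tour_length",
    "tsp_fitness", "brute_force_best_tour",
]

#: Exhaustive enumeration is refused above this genotype length (memory guard).
MAX_ENUMERATION_N = 24


@dataclass
class NKLandscape:
    """An NK fitness landscape with one component per coordinate (m = N).

    ``deps[i]`` lists the K coordinates component i depends on (its own
    coordinate first); ``tables[i]`` holds the 2**K component values, indexed
    by the bits of the restriction read in ``deps[i]`` order.
    """

    N: int
    K: int
    deps: np.ndarray     # (N, K) int
    tables: np.ndarray   # (N, 2**K) float in [0, 1]
    seed: int | None = None
    _all_fitness: np.ndarray | None = field(default=None, repr=False, compare=False)
    _sorted_fitness: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.deps = np.asarray(self.deps, dtype=int)
        self.tables = np.asarray(self.tables, dtype=float)
        if not 1 <= self.K <= self.N:
            raise ValueError("require 1 <= K <= N")
        if self.deps.shape != (self.N, self.K):
            raise ValueError("dependence sets must have shape (N, K)")
        if self.tables.shape != (self.N, 2 ** self.K):
            raise ValueError("each component table needs exactly 2**K entries")
        if np.any(self.tables < 0) or np.any(self.tables > 1):
            raise ValueError("component table values must lie in [0, 1]")
        for i in range(self.N):
            row = self.deps[i]
            if len(set(row.tolist())) != self.K or i not in row:
                raise ValueError("each dependence set needs K distinct indices "
                                 "including its own coordinate")

    @property
    def m(self) -> int:
        return self.N

    def fitness(self, genotype: np.ndarray) -> float:
        genotype = np.asarray(genotype).astype(int)
        if genotype.shape != (self.N,):
            raise ValueError(f"genotype must have length N = {self.N}")
        weights = 1 << np.arange(self.K - 1, -1, -1)
        idx = genotype[self.deps] @ weights
        return float(self.tables[np.arange(self.N), idx].sum())

    def all_fitness(self) -> np.ndarray:
        """Fitness of all 2**N genotypes in lexicographic order (cached).

        Genotype g corresponds to the bit vector of the integer g with the
        first coordinate as the most significant bit.
        """
        if self._all_fitness is None:
            if self.N > MAX_ENUMERATION_N:
                raise ValueError(
                    f"exhaustive enumeration refused for N > {MAX_ENUMERATION_N}; "
                    "use sampled information gain instead")
            g = np.arange(1 << self.N, dtype=np.int64)
            total = np.zeros(g.size)
            for i in range(self.N):
                idx = np.zeros(g.size, dtype=np.int64)
                for d in self.deps[i]:
                    idx = (idx << 1) | ((g >> (self.N - 1 - d)) & 1)
                total += self.tables[i][idx]
            self._all_fitness = total
        return self._all_fitness

    def sorted_fitness(self) -> np.ndarray:
        if self._sorted_fitness is None:
            self._sorted_fitness = np.sort(self.all_fitness())
        return self._sorted_fitness

    def information_gain(self, f: float | np.ndarray) -> float | np.ndarray:
        """Exact ``I_f`` by enumeration; vectorised over f."""
        vals = self.sorted_fitness()
        count_ge = vals.size - np.searchsorted(vals, f, side="left")
        q = count_ge / vals.size
        with np.errstate(divide="ignore"):
            out = -np.log2(q)
        return float(out) if np.isscalar(f) else out

    def sample_fitness(self, n_samples: int, seed) -> np.ndarray:
        """Fitness of genotypes drawn uniformly at random."""
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 1 << self.N, size=n_samples, dtype=np.int64)
        total = np.zeros(n_samples)
        for i in range(self.N):
            idx = np.zeros(n_samples, dtype=np.int64)
            for d in self.deps[i]:
                idx = (idx << 1) | ((g >> (self.N - 1 - d)) & 1)
            total += self.tables[i][idx]
        return total

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "N": self.N, "K": self.K, "seed": self.seed,
            "deps": self.deps.tolist(), "tables": self.tables.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "NKLandscape":
        d = json.loads(Path(path).read_text())
        return cls(N=d["N"], K=d["K"], deps=np.array(d["deps"]),
                   tables=np.array(d["tables"]), seed=d.get("seed"))


def make_nk(N: int, K: int, seed: int) -> NKLandscape:
    """Draw an NK landscape: random dependence sets, iid U[0,1] tables.

    Component i depends on coordinate i plus K-1 further coordinates drawn
    uniformly without replacement.  Identical seeds give identical
    landscapes; different seeds give different realisations of the same
    (N, K) task class.
    """
    if not 1 <= K <= N:
        raise ValueError("require 1 <= K <= N")
    rng = np.random.default_rng(seed)
    deps = np.empty((N, K), dtype=int)
    for i in range(N):
        others = np.delete(np.arange(N), i)
        extra = rng.choice(others, size=K - 1, replace=False) if K > 1 else []
        deps[i] = [i, *extra]
    tables = rng.random((N, 2 ** K))
    return NKLandscape(N=N, K=K, deps=deps, tables=tables, seed=int(seed))


def nk_fitness(landscape: NKLandscape, genotype: np.ndarray) -> float:
    return landscape.fitness(genotype)


def enumerate_fitness(landscape: NKLandscape) -> np.ndarray:
    return landscape.all_fitness()


def information_gain(f: float, landscape: NKLandscape, mode: str = "exact",
                     n_samples: int | None = None, seed=None) -> float:
    """Information gain of fitness value f on a landscape.

    ``exact`` mode enumerates all genotypes (N <= 24).  ``sampled`` mode
    draws ``n_samples`` uniform genotypes and uses the add-one estimator
    ``q_hat = (1 + #{>= f}) / (1 + n_samples)``, which keeps the estimate
    finite even for fitness above the sampled maximum.
    """
    if mode == "exact":
        return landscape.information_gain(f)
    if mode == "sampled":
        if not n_samples or n_samples < 1:
            raise ValueError("sampled mode needs n_samples >= 1")
        vals = landscape.sample_fitness(n_samples, seed)
        q_hat = (1 + int(np.sum(vals >= f))) / (1 + n_samples)
        return float(-np.log2(q_hat))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# travelling salesman


@dataclass
class TSPInstance:
    """Cities in the plane with the symmetric Euclidean distance matrix."""

    coords: np.ndarray          # (n_cities, 2)
    dist: np.ndarray = field(default=None)  # filled in __post_init__

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2 or len(self.coords) < 3:
            raise ValueError("need at least 3 cities with 2-D coordinates")
        if self.dist is None:
            self.dist = squareform(pdist(self.coords))

    @property
    def n_cities(self) -> int:
        return len(self.coords)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.coords, delimiter=",", header="x,y", comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TSPInstance":
        return cls(np.loadtxt(path, delimiter=",", skiprows=1))


def random_tsp(n_cities: int, seed, box: float = 1.0) -> TSPInstance:
    rng = np.random.default_rng(seed)
    return TSPInstance(rng.uniform(0.0, box, (n_cities, 2)))


def tour_length(instance: TSPInstance, tour: np.ndarray) -> float:
    """Closed-tour length: consecutive legs plus the return to the origin."""
    tour = np.asarray(tour).astype(int)
    if tour.size != instance.n_cities or len(set(tour.tolist())) != tour.size:
        raise ValueError("tour must be a permutation of all cities")
    return float(instance.dist[tour, np.roll(tour, -1)].sum())


def tsp_fitness(length: float) -> float:
    """Fitness of a tour: any monotone decreasing function of length; -l here."""
    if length <= 0:
        raise ValueError("tour length must be positive")
    return -float(length)


def brute_force_best_tour(instance: TSPInstance) -> tuple[np.ndarray, float]:
    """Exhaustive search for the shortest closed tour.

    The first city is pinned at the start, which enumerates every closed
    tour once per direction; reported lengths are unaffected.  Guarded to
    small instances.
    """
    n = instance.n_cities
    if n > 10:
        raise ValueError("exhaustive search is limited to 10 cities")
    best_len = np.inf
    best = None
    for rest in permutations(range(1, n)):
        tour = np.array((0, *rest))
        length = tour_length(instance, tour)
        if length < best_len:
            best_len = length
            best = tour
    return best, float(best_len)
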