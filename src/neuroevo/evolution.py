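"""The Darwinian generation loop over a lattice of reservoir computers.

A population of readout traces lives on a ring or torus of reservoir units,
one trace per site.  Each generation proceeds synchronously:

1. every stored trace is evaluated: amplitudes are sampled over the final
   evaluation window, decoded by the genotype-phenotype map, and scored on
   the fitness landscape;
2. every site ranks its closed neighbourhood (itself plus its lattice
   neighbours) by fitness and selects a teacher, deterministically (the top
   rank, at selection temperature 0) or stochastically with probability
   proportional to ``exp(-rank / tau)``;
3. every site whose teacher is not itself replicates the teacher's stored
   trace — either by training its reservoir on it with FORCE (the ``force``
   copy backend; the new stored trace is the readout emitted while tracking
   the teacher, so lineages stay aligned on a common time grid) or by
   copying the trace verbatim (the ``direct`` backend, an exact-copy
   reference that separates the evolutionary loop from learning fidelity) —
   and then receives calibrated white noise, the heritable mutation.
   Sites that selected themselves keep their stored trace untouched.

All teacher assignments are frozen against the generation-start traces
before any training happens, so the update is order-independent.  A site
whose training diverges keeps its previous trace and is flagged: such sites
act as temporary defects ("walls") in the lattice.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import Signal, random_fourier_signal, inject_noise, sample_at_intervals
from .reservoir import ReservoirParams, Reservoir, init_reservoir, force_train_many
from .gp_maps import signal_to_binary, signal_to_permutation
from .landscapes import NKLandscape, TSPInstance, make_nk, tour_length, tsp_fitness

__all__ = [
    "Topology", "EvolutionConfig", "Population", "GenerationRecord",
    "Phylogeny", "neighborhood", "rank_neighborhood", "select_teacher",
    "run_generation", "run_evolution",
]


@dataclass(frozen=True)
class Topology:
    """A periodic lattice of sites: 1-D ring or 2-D torus.

    Both wrap around, so every site has the same closed neighbourhood size:
    3 on the ring, 5 on the torus (von Neumann neighbours).
    """

    kind: str                       # "ring" | "torus"
    shape: int | tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind == "ring":
            if not isinstance(self.shape, int) or self.shape < 3:
                raise ValueError("ring length must be an integer >= 3")
        elif self.kind == "torus":
            shape = tuple(self.shape)
            object.__setattr__(self, "shape", shape)
            if len(shape) != 2 or min(shape) < 3:
                raise ValueError("torus dimensions must both be >= 3")
        else:
            raise ValueError(f"unknown topology kind {self.kind!r}")

    @property
    def n_sites(self) -> int:
        if self.kind == "ring":
            return self.shape
        return self.shape[0] * self.shape[1]

    def neighborhood(self, site: int) -> np.ndarray:
        """Closed neighbourhood of a site, sorted by site index."""
        n = self.n_sites
        if not 0 <= site < n:
            raise IndexError(f"site {site} outside lattice of {n} sites")
        if self.kind == "ring":
            nb = {site, (site - 1) % n, (site + 1) % n}
        else:
            rows, cols = self.shape
            r, c = divmod(site, cols)
            nb = {site,
                  ((r - 1) % rows) * cols + c,
                  ((r + 1) % rows) * cols + c,
                  r * cols + (c - 1) % cols,
                  r * cols + (c + 1) % cols}
        return np.array(sorted(nb), dtype=int)


def neighborhood(topology: Topology, site: int) -> np.ndarray:
    return topology.neighborhood(site)


def rank_neighborhood(fitnesses: np.ndarray, neighborhood: np.ndarray) -> np.ndarray:
    """Fitness ranks within a closed neighbourhood; 0 is fittest.

    Ties are broken in favour of the lower site index, which makes the
    ranking (and hence deterministic selection) reproducible.
    """
    neighborhood = np.asarray(neighborhood, dtype=int)
    if neighborhood.size == 0:
        raise ValueError("neighbourhood must be non-empty")
    order = sorted(range(neighborhood.size),
                   key=lambda j: (-fitnesses[neighborhood[j]], neighborhood[j]))
    ranks = np.empty(neighborhood.size, dtype=int)
    for rank, j in enumerate(order):
        ranks[j] = rank
    return ranks


def select_teacher(ranks: np.ndarray, tau: float,
                   seed: int | np.random.Generator) -> int:
    """Position (within the neighbourhood) of the selected teacher.

    At temperature 0 selection is deterministic: the rank-0 member.  For
    tau > 0 the member at rank r is chosen with probability proportional to
    ``exp(-r / tau)``; tau -> infinity approaches uniform random choice.
    """
    if tau < 0:
        raise ValueError("selection temperature must be non-negative")
    ranks = np.asarray(ranks)
    if tau == 0:
        return int(np.argmin(ranks))
    rng = np.random.default_rng(seed)
    w = np.exp(-(ranks - ranks.min()) / tau)
    return int(rng.choice(ranks.size, p=w / w.sum()))


def _default_torus_shape(n_sites: int) -> tuple[int, int]:
    r = int(np.sqrt(n_sites))
    while n_sites % r:
        r -= 1
    if r < 3 or n_sites // r < 3:
        raise ValueError(f"cannot arrange {n_sites} sites on a torus with sides >= 3")
    return (r, n_sites // r)


@dataclass
class EvolutionConfig:
    """Configuration of one evolutionary run.

    ``landscape`` is either an already-built :class:`NKLandscape` /
    :class:`TSPInstance` (shared across runs in a sweep) or a mapping such
    as ``{"kind": "nk", "N": 20, "K": 5}`` built from the run's own seed
    stream.  ``gp_map`` defaults to binary decoding for NK landscapes and
    permutation decoding for TSP instances.  A single master ``seed``
    deterministically spawns the independent streams for reservoir weights,
    initial signals, landscape, mutation noise and stochastic selection.

    ``signal_period`` sets the fundamental period of the random seed
    signals.  It defaults to the evaluation window (one full period is
    evaluated, so the decoded bin edges tile exactly one period), which
    also keeps every harmonic within the bandwidth the unit-time-constant
    neurons can track.
    """

    reservoir: ReservoirParams = field(default_factory=ReservoirParams)
    n_reservoir: int = 100
    topology: str = "ring"
    torus_shape: tuple[int, int] | None = None
    generations: int = 200
    landscape: "dict | NKLandscape | TSPInstance" = field(
        default_factory=lambda: {"kind": "nk", "N": 20, "K": 5})
    gp_map: str | None = None
    n_fourier: int = 5
    range_value: float = 2.0
    signal_period: float | None = None   # default: one period per evaluation window
    noise_amplitude: float = 0.0
    temperature: float = 0.0
    copy_backend: str = "force"
    train_on_clean: bool = False
    precision: str = "float32"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("need at least one generation")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")
        if self.temperature < 0:
            raise ValueError("selection temperature must be non-negative")
        if self.copy_backend not in ("force", "direct"):
            raise ValueError("copy backend must be 'force' or 'direct'")
        if self.precision not in ("float32", "float64"):
            raise ValueError("precision must be 'float32' or 'float64'")
        if self.copy_backend == "force" and \
                self.reservoir.n_train_steps < self.reservoir.n_signal_steps:
            raise ValueError("force backend requires t_train >= t_signal so a "
                             "full stored trace is produced while training")

    def build_topology(self) -> Topology:
        if self.topology == "ring":
            return Topology("ring", self.n_reservoir)
        shape = self.torus_shape or _default_torus_shape(self.n_reservoir)
        if shape[0] * shape[1] != self.n_reservoir:
            raise ValueError("torus shape inconsistent with n_reservoir")
        return Topology("torus", shape)

    def resolve_landscape(self, seed_stream: np.random.SeedSequence | None = None):
        if isinstance(self.landscape, (NKLandscape, TSPInstance)):
            return self.landscape
        spec = dict(self.landscape)
        kind = spec.pop("kind", "nk")
        if "seed" in spec and spec["seed"] is not None:
            seed = spec.pop("seed")
        else:
            spec.pop("seed", None)
            if seed_stream is None:
                seed_stream = np.random.SeedSequence(self.seed).spawn(6)[2]
            seed = int(seed_stream.generate_state(1)[0])
        if kind == "nk":
            return make_nk(spec["N"], spec["K"], seed)
        if kind == "tsp":
            from .landscapes import random_tsp
            return random_tsp(spec.get("n_cities", 10), seed)
        raise ValueError(f"unknown landscape kind {kind!r}")

    def resolve_gp_map(self, landscape) -> str:
        if self.gp_map is not None:
            return self.gp_map
        return "permutation" if isinstance(landscape, TSPInstance) else "binary"


@dataclass
class GenerationRecord:
    """What one generation saw: fitness, teacher and solution per site.

    ``fitness`` and ``solutions`` describe the stored traces at the start of
    the generation (the state on which teachers were chosen); ``teacher``
    holds the site index each site copied from (itself when it kept its
    trace); ``walls`` flags sites whose training diverged.
    """

    fitness: np.ndarray
    teacher: np.ndarray
    solutions: list
    walls: np.ndarray


@dataclass
class Population:
    """Lattice of reservoirs with their current stored traces."""

    topology: Topology
    traces: np.ndarray                 # (n_sites, trace_len) post-noise traces
    clean_traces: np.ndarray           # same, before this generation's noise
    dt: float
    reservoirs: list[Reservoir] | None = None

    @property
    def n_sites(self) -> int:
        return self.topology.n_sites

    def trace_signal(self, site: int) -> Signal:
        return Signal(self.traces[site], self.dt)


@dataclass
class _RngStreams:
    selection: np.random.Generator
    noise: np.random.Generator
    recovery: np.random.Generator


def _solution_size(landscape, config: EvolutionConfig) -> int:
    if isinstance(landscape, TSPInstance):
        return landscape.n_cities
    return landscape.N


def _evaluate(pop: Population, landscape, gp_map: str, n_points: int,
              t_evaluation: float) -> tuple[np.ndarray, list]:
    duration = pop.traces.shape[1] * pop.dt
    window = (duration - t_evaluation, duration)
    fitness = np.empty(pop.n_sites)
    solutions = []
    for s in range(pop.n_sites):
        amps = sample_at_intervals(pop.trace_signal(s), n_points, window)
        if gp_map == "binary":
            sol = signal_to_binary(amps)
            fitness[s] = landscape.fitness(sol)
        elif gp_map == "permutation":
            sol = signal_to_permutation(amps)
            fitness[s] = tsp_fitness(tour_length(landscape, sol))
        else:
            raise ValueError(f"unknown gp map {gp_map!r}")
        solutions.append(tuple(int(v) for v in sol))
    return fitness, solutions


def run_generation(population: Population, landscape, config: EvolutionConfig,
                   rngs: _RngStreams) -> GenerationRecord:
    """Advance the population by one generation, in place."""
    topo = population.topology
    n_sites = population.n_sites
    params = config.reservoir
    gp_map = config.resolve_gp_map(landscape)
    n_points = _solution_size(landscape, config)

    fitness, solutions = _evaluate(population, landscape, gp_map, n_points,
                                   params.t_evaluation)

    # teacher assignment from the frozen generation-start fitnesses
    teacher = np.empty(n_sites, dtype=int)
    for s in range(n_sites):
        nb = topo.neighborhood(s)
        ranks = rank_neighborhood(fitness, nb)
        chosen = nb[select_teacher(ranks, config.temperature, rngs.selection)]
        if config.temperature == 0 and fitness[chosen] <= fitness[s]:
            # deterministic selection only replaces a trace when a neighbour
            # is strictly fitter; an equally-fit population is a fixed point
            chosen = s
        teacher[s] = chosen

    walls = np.zeros(n_sites, dtype=bool)
    learners = np.flatnonzero(teacher != np.arange(n_sites))
    if learners.size:
        source = population.clean_traces if config.train_on_clean else population.traces
        targets = source[teacher[learners]].copy()  # snapshot before overwriting
        if config.copy_backend == "direct":
            new_traces = targets
        else:
            batch = force_train_many([population.reservoirs[s] for s in learners],
                                     targets, dtype=np.dtype(config.precision))
            new_traces = batch.outputs[:, -params.n_signal_steps:]
            for j, s in enumerate(learners):
                if batch.diverged[j]:
                    walls[s] = True
                    # a fresh state lets a defect recover in later generations
                    population.reservoirs[s].x = rngs.recovery.standard_normal(
                        params.n_neuron)
        for j, s in enumerate(learners):
            if walls[s]:
                continue
            population.clean_traces[s] = new_traces[j]
            if config.noise_amplitude > 0:
                noisy = inject_noise(Signal(new_traces[j], population.dt),
                                     config.noise_amplitude, params.t_evaluation,
                                     rngs.noise)
                population.traces[s] = noisy.samples
            else:
                population.traces[s] = new_traces[j]

    return GenerationRecord(fitness=fitness, teacher=teacher,
                            solutions=solutions, walls=walls)


@dataclass
class Phylogeny:
    """Complete record of a run: generations x sites, plus ancestry pointers.

    ``fitness[t, s]`` scores the trace site s carried at the start of
    generation t; ``teacher[t, s]`` is the site it copied from during
    generation t.  The trace a site holds at generation t therefore descends
    from site ``teacher[t-1, s]`` at generation t-1.
    """

    fitness: np.ndarray            # (T, n_sites)
    teacher: np.ndarray            # (T, n_sites)
    solutions: list                # T lists of per-site solution tuples
    walls: np.ndarray              # (T, n_sites) bool
    config: EvolutionConfig
    landscape: object = None

    @property
    def n_generations(self) -> int:
        return self.fitness.shape[0]

    @property
    def n_sites(self) -> int:
        return self.fitness.shape[1]

    def best_fitness_trajectory(self) -> np.ndarray:
        return self.fitness.max(axis=1)

    def information_gain(self) -> np.ndarray:
        """Per-site information gain matrix (exact; NK landscapes only)."""
        if not isinstance(self.landscape, NKLandscape):
            raise TypeError("information gain requires an NK landscape")
        return self.landscape.information_gain(self.fitness)

    def to_run_log(self, path: str | Path) -> None:
        """Tidy TSV: generation, site, fitness, I_f, teacher_site, solution."""
        has_if = isinstance(self.landscape, NKLandscape) and \
            self.landscape.N <= 24
        i_f = self.information_gain() if has_if else np.full_like(self.fitness, np.nan)
        rows = []
        for t in range(self.n_generations):
            for s in range(self.n_sites):
                sol = self.solutions[t][s]
                sol_txt = "".join(map(str, sol)) if self.config.resolve_gp_map(
                    self.landscape) == "binary" else ",".join(map(str, sol))
                rows.append((t, s, self.fitness[t, s], i_f[t, s],
                             self.teacher[t, s], sol_txt))
        pd.DataFrame(rows, columns=["generation", "site", "fitness", "I_f",
                                    "teacher_site", "solution"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_run_log(cls, path: str | Path) -> "Phylogeny":
        df = pd.read_csv(path, sep="\t", dtype={"solution": str})
        T = int(df["generation"].max()) + 1
        S = int(df["site"].max()) + 1
        fitness = np.full((T, S), np.nan)
        teacher = np.zeros((T, S), dtype=int)
        solutions = [[None] * S for _ in range(T)]
        for row in df.itertuples(index=False):
            t, s = int(row.generation), int(row.site)
            fitness[t, s] = row.fitness
            teacher[t, s] = int(row.teacher_site)
            sol = str(row.solution)
            solutions[t][s] = tuple(int(v) for v in
                                    (sol.split(",") if "," in sol else sol))
        return cls(fitness=fitness, teacher=teacher, solutions=solutions,
                   walls=np.zeros((T, S), dtype=bool),
                   config=EvolutionConfig(), landscape=None)

    def summary(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["reservoir"] = dataclasses.asdict(self.config.reservoir)
        if not isinstance(cfg["landscape"], dict):
            ls = self.config.landscape
            cfg["landscape"] = {"kind": "tsp" if isinstance(ls, TSPInstance) else "nk"}
        return {
            "config": cfg,
            "n_generations": self.n_generations,
            "n_sites": self.n_sites,
            "best_fitness": self.best_fitness_trajectory().tolist(),
            "final_max_fitness": float(self.fitness[-1].max()),
        }

    def save_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def run_evolution(config: EvolutionConfig) -> Phylogeny:
    """Initialise a population and run the full Darwinian dynamics.

    Each site starts from its own random Fourier trace; with the force
    backend every reservoir is first trained once on that trace so the
    stored traces are genuinely reservoir-generated.  The run is fully
    determined by ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    s_weights, s_signals, s_landscape, s_noise, s_selection, s_recovery = ss.spawn(6)
    landscape = config.resolve_landscape(s_landscape)
    topo = config.build_topology()
    n_sites = topo.n_sites
    params = config.reservoir
    dt = params.dt

    period = config.signal_period or params.t_evaluation
    signal_seeds = s_signals.spawn(n_sites)
    seeds_w = s_weights.spawn(n_sites)
    init_signals = np.stack([
        random_fourier_signal(config.n_fourier, config.range_value,
                              params.t_signal, dt, np.random.default_rng(sd),
                              period=period).samples
        for sd in signal_seeds])

    reservoirs = None
    if config.copy_backend == "force":
        reservoirs = [init_reservoir(params, int(sd.generate_state(1)[0]))
                      for sd in seeds_w]
        batch = force_train_many(reservoirs, init_signals,
                                 dtype=np.dtype(config.precision))
        traces = batch.outputs[:, -params.n_signal_steps:].copy()
        for s in range(n_sites):
            if batch.diverged[s]:   # keep the analytic seed trace as fallback
                traces[s] = init_signals[s]
    else:
        traces = init_signals

    population = Population(topology=topo, traces=traces,
                            clean_traces=traces.copy(), dt=dt,
                            reservoirs=reservoirs)
    rngs = _RngStreams(selection=np.random.default_rng(s_selection),
                       noise=np.random.default_rng(s_noise),
                       recovery=np.random.default_rng(s_recovery))

    records = [run_generation(population, landscape, config, rngs)
               for _ in range(config.generations)]

    return Phylogeny(
        fitness=np.stack([r.fitness for r in records]),
        teacher=np.stack([r.teacher for r in records]),
        solutions=[r.solutions for r in records],
        walls=np.stack([r.walls for r in records]),
        config=config, landscape=landscape)
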