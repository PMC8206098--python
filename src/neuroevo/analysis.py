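"""Experiment instruments: sweeps, representation bias, phylogeny export.

The sweeps re-run the evolutionary dynamics over a grid of one control
parameter — mutation noise amplitude, or selection temperature — and
collect the final-generation information-gain distribution per grid point.
The contrast the instruments quantify: raising the noise amplitude breaks
the process abruptly at an error threshold, while weakening selection
degrades it gradually.  Representation-bias curves measure how unevenly the
signal-to-solution maps cover solution space.  Phylogenies can be rendered
as generations-by-sites fitness heatmaps or exported as Newick forests of
the surviving lineages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evolution import EvolutionConfig, Phylogeny, run_evolution
from .landscapes import NKLandscape

__all__ = [
    "SweepResult", "BiasCurves", "noise_sweep", "temperature_sweep",
    "representation_bias", "phylogeny_to_newick", "render_fitness_heatmap",
    "gini_coefficient", "max_successive_drop",
    "NOISE_GRID_DEFAULT", "TAU_GRID_DEFAULT",
]

#: Noise amplitudes for error-threshold sweeps: linear over the studied range.
NOISE_GRID_DEFAULT = np.linspace(0.0, 147.0, 6)

#: Selection temperatures for selection-strength sweeps.  Ranks within a
#: closed neighbourhood span 0..2 (ring) or 0..4 (torus), so the crossover
#: from near-deterministic to near-random selection happens at tau of order
#: one; a geometric grid (factors of 4 below the top value) resolves it,
#: where a linear grid would place every nonzero point in the random regime.
TAU_GRID_DEFAULT = np.array([0.0] + [42.75 / 4 ** k for k in range(4, -1, -1)])


@dataclass
class SweepResult:
    """Final-generation distributions over a one-parameter grid.

    ``i_f`` and ``fitness`` have shape (n_values, n_runs, n_sites).  On
    landscapes without an exact information-gain transform the ``i_f``
    entries are NaN.  Distributions are pooled over runs when summarised:
    the run-to-run variability of these dynamics is high and the
    distributions can be multimodal, so full populations are retained and
    medians are taken over the pool.
    """

    param: str
    values: np.ndarray
    i_f: np.ndarray
    fitness: np.ndarray

    def median_per_value(self) -> np.ndarray:
        return np.median(self.i_f.reshape(len(self.values), -1), axis=1)

    def max_successive_drop(self) -> float:
        return max_successive_drop(self.median_per_value())

    def is_sharp(self) -> bool:
        """Sharp transition: one grid step carries over half the total span."""
        med = self.median_per_value()
        span = float(med.max() - med.min())
        return span > 0 and self.max_successive_drop() > 0.5 * span

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        n_vals, n_runs, n_sites = self.i_f.shape
        for i in range(n_vals):
            for r in range(n_runs):
                for s in range(n_sites):
                    rows.append((self.values[i], r, s,
                                 self.i_f[i, r, s], self.fitness[i, r, s]))
        pd.DataFrame(rows, columns=[self.param, "run", "site", "I_f",
                                    "fitness"]).to_csv(path, sep="\t", index=False)


def max_successive_drop(values: np.ndarray) -> float:
    """Largest decrease between consecutive entries (0 if none decreases)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(max(0.0, np.max(values[:-1] - values[1:])))


def _cell_seed(seed: int, run: int, value: float) -> int:
    # keyed by the parameter value itself, so executing grid points in any
    # order (or extending the grid) never changes a cell's stream
    bits = int(np.float64(value).view(np.uint64))
    return int(np.random.SeedSequence([seed, run, bits]).generate_state(1)[0])


def _sweep(base_config: EvolutionConfig, param: str, values, n_runs: int,
           seed: int) -> SweepResult:
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{param} values must be non-negative")
    landscape = base_config.resolve_landscape(
        np.random.SeedSequence([seed, 0xC0FFEE]))
    exact_if = isinstance(landscape, NKLandscape) and landscape.N <= 24
    n_sites = base_config.n_reservoir
    i_f = np.full((values.size, n_runs, n_sites), np.nan)
    fitness = np.empty((values.size, n_runs, n_sites))
    for i, value in enumerate(values):
        for r in range(n_runs):
            cfg = dataclasses.replace(
                base_config, landscape=landscape,
                seed=_cell_seed(seed, r, float(value)),
                **{param: float(value)})
            ph = run_evolution(cfg)
            fitness[i, r] = ph.fitness[-1]
            if exact_if:
                i_f[i, r] = landscape.information_gain(ph.fitness[-1])
    name = "noise_amplitude" if param == "noise_amplitude" else "temperature"
    return SweepResult(param=name, values=values, i_f=i_f, fitness=fitness)


def noise_sweep(base_config: EvolutionConfig, A_values=NOISE_GRID_DEFAULT,
                n_runs: int = 1, seed: int = 0) -> SweepResult:
    """Error-threshold experiment: sweep the mutation noise amplitude.

    The landscape realisation is fixed across all grid cells (so columns are
    comparable); each (value, run) cell gets an independent seeded stream.
    """
    return _sweep(base_config, "noise_amplitude", A_values, n_runs, seed)


def temperature_sweep(base_config: EvolutionConfig, tau_values=TAU_GRID_DEFAULT,
                      n_runs: int = 1, seed: int = 0) -> SweepResult:
    """Selection-strength experiment: sweep the selection temperature."""
    return _sweep(base_config, "temperature", tau_values, n_runs, seed)


# ---------------------------------------------------------------------------
# representation bias


@dataclass
class BiasCurves:
    """Rarefaction curves and token-frequency spectra of a GP map.

    ``distinct_signal[k]`` counts the distinct solutions among the first
    k+1 samples drawn uniformly in signal space (random Fourier traces
    pushed through the map); ``distinct_solution`` is the same for uniform
    sampling in solution space.  The spectra map sampled frequency (token
    count) to the number of solution types observed that often.
    """

    n_samples: int
    distinct_signal: np.ndarray
    distinct_solution: np.ndarray
    signal_counts: np.ndarray      # token count per sampled type
    solution_counts: np.ndarray
    n_types: int

    def signal_spectrum(self) -> dict[int, int]:
        freq, n = np.unique(self.signal_counts, return_counts=True)
        return dict(zip(freq.tolist(), n.tolist()))

    def solution_spectrum(self) -> dict[int, int]:
        freq, n = np.unique(self.solution_counts, return_counts=True)
        return dict(zip(freq.tolist(), n.tolist()))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "n_sampled": np.arange(1, self.n_samples + 1),
            "distinct_signal_space": self.distinct_signal,
            "distinct_solution_space": self.distinct_solution,
        }).to_csv(path, sep="\t", index=False)


def gini_coefficient(counts: np.ndarray) -> float:
    """Gini coefficient of a count vector (0 = even, -> 1 = concentrated)."""
    counts = np.sort(np.asarray(counts, dtype=float))
    if counts.sum() == 0:
        return 0.0
    n = counts.size
    cum = np.cumsum(counts)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def _distinct_curve(keys: np.ndarray) -> np.ndarray:
    _, first = np.unique(keys, return_index=True)
    new_type = np.zeros(keys.size, dtype=int)
    new_type[first] = 1
    return np.cumsum(new_type)


def representation_bias(gp_map: str, N: int, n_samples: int, seed: int = 0,
                        n_fourier: int = 5, t_window: float = 30.0) -> BiasCurves:
    """Compare uniform sampling in signal space against solution space.

    Signal-space samples are random truncated Fourier series (the same prior
    that seeds evolutionary runs) read out at N regular bin edges over a
    window of ``t_window`` time units and decoded by the chosen map.
    Solution-space samples are uniform over all types.  Because many signals
    decode to the same few solutions, the signal-space rarefaction curve
    saturates lower and its token-frequency spectrum is more skewed.
    """
    if gp_map == "binary":
        if N > 20:
            raise ValueError("distinct-type counting limited to N <= 20 bits")
    elif gp_map == "permutation":
        if N > 8:
            raise ValueError("distinct-type counting limited to N <= 8 elements")
    else:
        raise ValueError(f"unknown gp map {gp_map!r}")

    rng = np.random.default_rng(seed)
    # uniform in signal space: vectorised Fourier draws at the bin-edge times
    t = np.arange(N) * (t_window / N)
    m = np.arange(1, n_fourier + 1)
    a = rng.uniform(-0.5, 0.5, (n_samples, n_fourier))
    b = rng.uniform(-0.5, 0.5, (n_samples, n_fourier))
    sin_t = np.sin(np.outer(t, m))   # (N, n_fourier)
    cos_t = np.cos(np.outer(t, m))
    amps = a @ sin_t.T + b @ cos_t.T   # rescaling is monotone: maps unchanged

    if gp_map == "binary":
        n_types = 2 ** N
        weights = (1 << np.arange(N - 1, -1, -1)).astype(np.int64)
        signal_keys = (amps > 0).astype(np.int64) @ weights
        solution_keys = rng.integers(0, n_types, size=n_samples, dtype=np.int64)
    else:
        import math
        n_types = math.factorial(N)
        radix = np.int64(N) ** np.arange(N - 1, -1, -1, dtype=np.int64)
        signal_keys = np.argsort(amps, axis=1, kind="stable").astype(np.int64) @ radix
        perms = rng.permuted(np.tile(np.arange(N, dtype=np.int64), (n_samples, 1)),
                             axis=1)
        solution_keys = perms @ radix

    _, signal_counts = np.unique(signal_keys, return_counts=True)
    _, solution_counts = np.unique(solution_keys, return_counts=True)
    return BiasCurves(
        n_samples=n_samples,
        distinct_signal=_distinct_curve(signal_keys),
        distinct_solution=_distinct_curve(solution_keys),
        signal_counts=signal_counts,
        solution_counts=solution_counts,
        n_types=n_types,
    )


# ---------------------------------------------------------------------------
# phylogeny export


def phylogeny_to_newick(phylogeny: Phylogeny, final_site: int | None = None) -> str:
    """Newick forest of the lineages surviving to the final generation.

    Teacher pointers are traced backwards from each final-generation site
    (or from ``final_site`` only) to generation 0.  Every copy event is one
    branch of length 1; nodes are labelled ``s<site>_g<generation>``.  Each
    root lineage yields one tree, one per line.
    """
    T, S = phylogeny.fitness.shape
    if final_site is None:
        leaves = list(range(S))
    else:
        if not 0 <= final_site < S:
            raise IndexError("final_site outside the lattice")
        leaves = [final_site]

    def parent(node):
        t, s = node
        return (t - 1, int(phylogeny.teacher[t - 1, s])) if t > 0 else None

    kept: set[tuple[int, int]] = set()
    for s in leaves:
        node = (T - 1, s)
        while node is not None and node not in kept:
            kept.add(node)
            node = parent(node)

    children: dict[tuple[int, int], list[tuple[int, int]]] = {}
    roots = []
    for node in kept:
        par = parent(node)
        if par is None:
            roots.append(node)
        else:
            children.setdefault(par, []).append(node)

    def label(node):
        t, s = node
        return f"s{s}_g{t}"

    def render(node) -> str:
        kids = sorted(children.get(node, []))
        if not kids:
            return label(node)
        inner = ",".join(render(k) + ":1" for k in kids)
        return f"({inner}){label(node)}"

    return "\n".join(render(root) + ";" for root in sorted(roots))


def render_fitness_heatmap(phylogeny: Phylogeny, out: str | Path,
                           cross_section: int | None = None,
                           cmap: str = "viridis") -> Path:
    """Raster image of the phylogeny: generations (rows) by sites (columns).

    On a ring the full lattice is drawn; on a torus one row of the lattice
    is drawn per call (``cross_section`` selects which).  Pixel dimensions
    equal the matrix dimensions; the colour scale is recorded in a JSON
    sidecar next to the image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    topo = phylogeny.config.build_topology() if phylogeny.config else None
    M = phylogeny.fitness
    if topo is not None and topo.kind == "torus":
        rows, cols = topo.shape
        row = cross_section or 0
        if not 0 <= row < rows:
            raise IndexError("cross section outside the torus")
        M = M.reshape(M.shape[0], rows, cols)[:, row, :]
    out = Path(out)
    vmin, vmax = float(np.nanmin(M)), float(np.nanmax(M))
    plt.imsave(out, M, cmap=cmap, vmin=vmin, vmax=vmax, origin="upper")
    sidecar = out.with_suffix(out.suffix + ".json")
    sidecar.write_text(json.dumps({
        "vmin": vmin, "vmax": vmax, "cmap": cmap,
        "shape": list(M.shape), "rows": "generations", "cols": "sites",
    }, indent=2))
    return out
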