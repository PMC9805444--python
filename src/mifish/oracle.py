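"""Exact small-instance solver for the clone-tree cost model.

``brute_force_tree`` computes the true minimum total cost of a rooted clone
tree (root = all-2, single-probe +/-1 steps, whole-genome doublings with a
per-path budget) by exhaustive search of the bounded genotype grid: the
problem is cast as a minimum Steiner arborescence in the directed graph
whose vertices are (genotype, doublings-used) pairs and whose edges are the
elementary events, and solved with the Dreyfus-Wagner subset dynamic
program (Dijkstra closures via scipy).  Every genotype on the grid is a
potential Steiner node, so the result is exact — but the state space grows
as (2*max_count)^n_probes, hence the deliberately small instance bounds.

This module is the independent verification oracle for
:func:`mifish.tree.build_tree`; it returns only the optimal cost, never a
tree, and refuses instances above its bounds.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .tree import EditModel, TreeError

#: hard instance bounds (oracle-only contract)
MAX_PATTERNS = 5
MAX_PROBES = 4
MAX_COUNT = 6
_GRID_CAP = 12  # per-coordinate cap: twice the largest admissible count


class OracleBoundsError(ValueError):
    """Raised when an instance exceeds the exact-solver bounds."""


def brute_force_tree(clonal_patterns, model: EditModel | None = None) -> float:
    """Exact minimum total tree cost for a small pattern set.

    Bounds: at most 5 distinct patterns, at most 4 probes, all counts in
    0..6.  The ploidy-reduction flag is not supported here.
    """
    model = model or EditModel()
    if model.allow_ploidy_reduction:
        raise OracleBoundsError("exact solver does not model ploidy reduction")
    patterns = [tuple(int(x) for x in v) for v in clonal_patterns]
    if not patterns:
        raise TreeError("at least one clonal pattern required")
    p = len(patterns[0])
    if any(len(v) != p for v in patterns):
        raise TreeError("all patterns must have the same length")
    terminals = sorted(set(patterns))
    if len(terminals) > MAX_PATTERNS:
        raise OracleBoundsError(f"more than {MAX_PATTERNS} distinct patterns")
    if p > MAX_PROBES:
        raise OracleBoundsError(f"more than {MAX_PROBES} probes")
    if any(x < 0 or x > MAX_COUNT for v in terminals for x in v):
        raise OracleBoundsError(f"counts outside 0..{MAX_COUNT}")
    B = int(model.max_wgd_per_path)
    if B > 4:
        raise OracleBoundsError("doubling budgets above 4 are not supported")

    root = (2,) * p
    # Per-coordinate grid caps: positions above twice the largest relevant
    # value are dominated (steps only ever move toward terminals, and
    # doubling from them overshoots even further).
    caps = [
        min(_GRID_CAP, 2 * max([2] + [t[i] for t in terminals]))
        for i in range(p)
    ]
    dims = np.array([c + 1 for c in caps], dtype=np.int64)
    strides = np.ones(p, dtype=np.int64)
    for i in range(p - 2, -1, -1):
        strides[i] = strides[i + 1] * dims[i + 1]
    n_grid = int(dims.prod())
    layers = B + 1
    n_core = n_grid * layers
    m = len(terminals)
    n_total = n_core + m  # + virtual terminal sinks
    super_src = n_total  # one extra slot for multi-source closures

    coords = np.stack(
        np.unravel_index(np.arange(n_grid), tuple(dims)), axis=1
    )  # (n_grid, p)

    rows, cols, weights = [], [], []

    def add_edges(r, c, w):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        weights.append(np.full(len(r), w, dtype=np.float64))

    # step edges (both directions, within each budget layer)
    for i in range(p):
        movable = np.nonzero(coords[:, i] < caps[i])[0]
        nbr = movable + strides[i]
        for b in range(layers):
            off = b * n_grid
            add_edges(movable + off, nbr + off, model.step_cost)
            add_edges(nbr + off, movable + off, model.step_cost)
    # doubling edges (layer b -> b+1)
    if layers > 1:
        feasible = np.nonzero((2 * coords <= np.array(caps)).all(axis=1))[0]
        dst = (2 * coords[feasible] * strides).sum(axis=1)
        for b in range(layers - 1):
            add_edges(feasible + b * n_grid, dst + (b + 1) * n_grid, model.wgd_cost)
    # terminal capture: (t_j, any layer) -> virtual sink j, zero cost
    for j, t in enumerate(terminals):
        flat = int(np.dot(np.array(t, dtype=np.int64), strides))
        r = np.array([flat + b * n_grid for b in range(layers)], dtype=np.int64)
        c = np.full(layers, n_core + j, dtype=np.int64)
        rows.append(r)
        cols.append(c)
        weights.append(np.zeros(layers, dtype=np.float64))

    # Reversed graph: Dijkstra from a sink yields, for every vertex v, the
    # shortest v -> sink distance in the forward graph.  A permanent
    # super-source row (weights mutated in place, inf = unused) provides
    # multi-source closures without rebuilding the matrix.
    rev_rows = np.concatenate(cols + [np.full(n_core, super_src, dtype=np.int64)])
    rev_cols = np.concatenate(rows + [np.arange(n_core, dtype=np.int64)])
    rev_w = np.concatenate(weights + [np.full(n_core, np.inf)])
    graph = csr_matrix(
        (rev_w, (rev_rows, rev_cols)), shape=(n_total + 1, n_total + 1)
    )
    graph.sort_indices()
    sup = slice(graph.indptr[super_src], graph.indptr[super_src + 1])
    # the super row holds exactly the n_core source slots, in column order
    assert np.array_equal(graph.indices[sup], np.arange(n_core))

    def closure(potentials: np.ndarray) -> np.ndarray:
        """min_u potentials[u] + d(v -> u) for every core vertex v."""
        graph.data[sup] = potentials
        return dijkstra(graph, directed=True, indices=super_src)[:n_core]

    def sink_distances(j: int) -> np.ndarray:
        graph.data[sup] = np.inf  # disable the super row
        return dijkstra(graph, directed=True, indices=n_core + j)[:n_core]

    # Dreyfus-Wagner over terminal subsets
    full = (1 << m) - 1
    f: dict[int, np.ndarray] = {}
    for j in range(m):
        f[1 << j] = sink_distances(j)
    for mask in sorted(range(1, full + 1), key=lambda x: bin(x).count("1")):
        if mask in f:
            continue
        base = np.full(n_core, np.inf)
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub < other:
                np.minimum(base, f[sub] + f[other], out=base)
            sub = (sub - 1) & mask
        f[mask] = closure(base)

    root_idx = int(np.dot(np.full(p, 2, dtype=np.int64), strides))  # layer 0
    value = float(f[full][root_idx])
    if math.isinf(value):  # pragma: no cover - grid always connects
        raise TreeError("no feasible tree within the doubling budget")
    return value


def random_instance(
    rng: np.random.Generator,
    n_probes: int | None = None,
    n_patterns: int | None = None,
    max_count: int = MAX_COUNT,
) -> list[tuple[int, ...]]:
    """A random small pattern set within the exact-solver bounds.

    Patterns are grown the way clones evolve: starting from the diploid
    root, each new pattern perturbs a previously generated genotype by up
    to two single-probe steps, optionally preceded by a doubling (kept
    within the count cap).  Used by the oracle-equivalence checks.
    """
    p = int(n_probes) if n_probes is not None else int(rng.integers(2, MAX_PROBES + 1))
    m = (
        int(n_patterns)
        if n_patterns is not None
        else int(rng.integers(1, MAX_PATTERNS + 1))
    )
    root = (2,) * p
    pool: list[tuple[int, ...]] = [root]
    out: list[tuple[int, ...]] = []
    guard = 0
    while len(out) < m and guard < 500:
        guard += 1
        base = np.array(pool[int(rng.integers(len(pool)))], dtype=np.int64)
        g = base.copy()
        if rng.random() < 0.3 and (2 * g <= max_count).all():
            g = 2 * g
        for _ in range(int(rng.integers(0, 3))):
            j = int(rng.integers(p))
            g[j] = min(max_count, max(0, g[j] + int(rng.choice([-1, 1]))))
        t = tuple(int(x) for x in g)
        if t not in out:
            out.append(t)
            pool.append(t)
    if len(out) < m:  # pragma: no cover - guard exhaustion is pathological
        raise RuntimeError("failed to generate a random instance")
    return out
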