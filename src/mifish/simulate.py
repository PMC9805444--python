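"""Synthetic single-cell FISH count tables with known clonal structure.

The generator emulates the statistical structure the analysis assumes: a
clone tree rooted at a fully diploid genotype, children differing from their
parent by single-probe +/-1 copy steps optionally preceded by a whole-genome
doubling (at most two doublings per lineage), supplied clone frequencies,
and independent per-probe miscount noise (signal dropout dominates over
split-signal artifacts in interphase FISH, hence the asymmetric defaults
``p_drop=0.05`` and ``p_split=0.02``).

Everything is reproducible from the config seed; the noise-free expected
summary (``true_summary``) serves as ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import ProbePanel, default_panel
from .ploidy import (
    ClonePattern,
    SampleSummary,
    SignalPattern,
    diversification_class,
    instability_index,
    CLONAL_FRACTION,
)

DEFAULT_P_DROP = 0.05
DEFAULT_P_SPLIT = 0.02


class SimulationError(ValueError):
    """Raised for infeasible or inconsistent simulation requests."""


@dataclass(frozen=True)
class SimClone:
    """One simulated clone: genotype vector, parent link and frequency."""

    clone_id: str
    genotype: tuple[int, ...]
    parent_id: str | None = None
    frequency: float = 0.0
    n_wgd: int = 0  # doublings on the edge from the parent

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.genotype):
            raise SimulationError(f"clone {self.clone_id}: negative copy number")
        if not 0.0 <= self.frequency <= 1.0:
            raise SimulationError(
                f"clone {self.clone_id}: frequency {self.frequency} outside [0, 1]"
            )


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated sample."""

    panel: ProbePanel
    clones: tuple[SimClone, ...]
    n_cells: int
    p_drop: float = DEFAULT_P_DROP
    p_split: float = DEFAULT_P_SPLIT
    max_wgd_per_lineage: int = 2
    seed: int = 0
    sample_id: str = "SIM"

    def __post_init__(self) -> None:
        object.__setattr__(self, "clones", tuple(self.clones))
        if self.n_cells <= 0:
            raise SimulationError("n_cells must be positive")
        for name, p in (("p_drop", self.p_drop), ("p_split", self.p_split)):
            if not 0.0 <= p <= 0.5:
                raise SimulationError(f"{name}={p} outside [0, 0.5]")
        if not self.clones:
            raise SimulationError("at least one clone required")
        total = sum(c.frequency for c in self.clones)
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"clone frequencies sum to {total}, not 1")
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise SimulationError("duplicate clone ids")
        by_id = {c.clone_id: c for c in self.clones}
        roots = [c for c in self.clones if c.parent_id is None]
        if len(roots) != 1:
            raise SimulationError("exactly one root clone required")
        if any(g != 2 for g in roots[0].genotype):
            raise SimulationError("root clone genotype must be fully diploid (all-2)")
        for c in self.clones:
            if len(c.genotype) != len(self.panel):
                raise SimulationError(
                    f"clone {c.clone_id}: genotype length {len(c.genotype)} "
                    f"!= panel length {len(self.panel)}"
                )
            if c.parent_id is not None and c.parent_id not in by_id:
                raise SimulationError(
                    f"clone {c.clone_id}: unknown parent {c.parent_id!r}"
                )
        # WGD budget along every root-to-leaf lineage
        for c in self.clones:
            used, cur = 0, c
            seen = set()
            while cur.parent_id is not None:
                if cur.clone_id in seen:
                    raise SimulationError("clone parent links contain a cycle")
                seen.add(cur.clone_id)
                used += cur.n_wgd
                cur = by_id[cur.parent_id]
            if used > self.max_wgd_per_lineage:
                raise SimulationError(
                    f"clone {c.clone_id}: {used} doublings on its lineage exceed "
                    f"the budget of {self.max_wgd_per_lineage}"
                )

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.clones], dtype=float)

    @property
    def genotypes(self) -> np.ndarray:
        return np.array([c.genotype for c in self.clones], dtype=np.int64)


def random_clone_tree(
    panel: ProbePanel,
    n_clones: int,
    n_wgd: int = 0,
    steps_per_edge: int = 1,
    seed: int = 0,
    max_wgd_per_lineage: int = 2,
) -> list[SimClone]:
    """Generate a random rooted clone tree over the panel.

    The root is fully diploid; each of the other ``n_clones - 1`` clones
    descends from a uniformly chosen earlier clone by ``steps_per_edge``
    single-gene-probe +/-1 steps, and exactly ``n_wgd`` of the edges carry a
    whole-genome doubling (placed so that no lineage exceeds
    ``max_wgd_per_lineage``).  Frequencies are Dirichlet(1)-distributed.
    Deterministic for a given seed.
    """
    if n_clones < 1:
        raise SimulationError("n_clones must be >= 1")
    if n_wgd < 0:
        raise SimulationError("n_wgd must be >= 0")
    if n_wgd > max(0, n_clones - 1):
        raise SimulationError("cannot place more doublings than edges")
    rng = np.random.default_rng(seed)
    p = len(panel)
    gene_idx = list(panel.gene_indices)

    for _attempt in range(200):
        genotypes = [np.full(p, 2, dtype=np.int64)]
        parents = [None]
        wgd_edges = [0]
        wgd_depth = [0]
        wgd_left = n_wgd
        ok = True
        for i in range(1, n_clones):
            parent = int(rng.integers(0, i))
            edges_left_after = n_clones - 1 - i
            can_wgd = wgd_depth[parent] < max_wgd_per_lineage
            must_wgd = wgd_left > edges_left_after
            if must_wgd and not can_wgd:
                ok = False
                break
            do_wgd = can_wgd and wgd_left > 0 and (
                must_wgd or rng.random() < wgd_left / (edges_left_after + 1)
            )
            g = genotypes[parent].copy()
            if do_wgd:
                g *= 2
                wgd_left -= 1
            for _ in range(steps_per_edge):
                j = int(rng.choice(gene_idx))
                step = int(rng.choice([-1, 1]))
                if g[j] + step < 0:
                    step = 1
                g[j] += step
            if any(np.array_equal(g, h) for h in genotypes):
                ok = False
                break
            genotypes.append(g)
            parents.append(parent)
            wgd_edges.append(int(do_wgd))
            wgd_depth.append(wgd_depth[parent] + int(do_wgd))
        if ok and wgd_left == 0:
            freqs = rng.dirichlet(np.ones(n_clones))
            clones = []
            for i, g in enumerate(genotypes):
                clones.append(
                    SimClone(
                        clone_id=f"clone{i}",
                        genotype=tuple(int(x) for x in g),
                        parent_id=None if parents[i] is None else f"clone{parents[i]}",
                        frequency=float(freqs[i]),
                        n_wgd=wgd_edges[i],
                    )
                )
            return clones
    raise SimulationError(
        "could not generate a feasible clone tree for the requested parameters"
    )


def with_frequencies(clones: list[SimClone], frequencies) -> list[SimClone]:
    """Return the same clone tree with the given frequencies (must sum to 1)."""
    if len(frequencies) != len(clones):
        raise SimulationError("one frequency per clone required")
    return [replace(c, frequency=float(f)) for c, f in zip(clones, frequencies)]


def sample_cells(config: SimConfig) -> pd.DataFrame:
    """Draw a per-cell count table from the configured clone mixture.

    Each cell's clone is drawn from the clone frequencies; every probe count
    is then perturbed independently: -1 with ``p_drop`` (floored at 0),
    +1 with ``p_split``.  Output is the canonical cell frame (one row per
    nucleus, counts in panel order, empty qc column).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    clone_idx = rng.choice(len(config.clones), size=n, p=config.frequencies)
    counts = config.genotypes[clone_idx].copy()
    u = rng.random(counts.shape)
    counts -= (u < config.p_drop).astype(np.int64)
    counts += ((u >= config.p_drop) & (u < config.p_drop + config.p_split)).astype(
        np.int64
    )
    np.maximum(counts, 0, out=counts)

    width = len(str(n - 1)) if n > 1 else 1
    frame = pd.DataFrame(
        {
            "sample_id": config.sample_id,
            "cell_id": [f"c{i:0{width}d}" for i in range(n)],
        }
    )
    for j, name in enumerate(config.panel.names):
        frame[name] = counts[:, j]
    frame["qc"] = ""
    frame.attrs["true_clone"] = [config.clones[i].clone_id for i in clone_idx]
    return frame


def true_summary(config: SimConfig) -> SampleSummary:
    """The noise-free expected per-sample summary of a simulation config.

    True pattern count = number of distinct clone genotypes; true average
    ploidy = frequency-weighted mean of the genotype centromere means; a
    clone is expected-clonal iff its frequency strictly exceeds 2%.
    """
    panel = config.panel
    geno_freq: dict[tuple[int, ...], float] = {}
    for c in config.clones:
        geno_freq[c.genotype] = geno_freq.get(c.genotype, 0.0) + c.frequency
    n_patterns = len(geno_freq)
    cen = list(panel.centromere_indices)
    avg_ploidy = sum(
        f * (sum(g[i] for i in cen) / 2.0) for g, f in geno_freq.items()
    )
    clones = []
    poly = 0.0
    n4 = n8 = 0.0
    for g, f in sorted(geno_freq.items(), key=lambda kv: (-kv[1], kv[0])):
        sp = SignalPattern.from_counts(g, panel)
        clones.append(
            ClonePattern(
                pattern=sp,
                n_cells=int(round(f * config.n_cells)),
                fraction=f,
                clonal=f > CLONAL_FRACTION,
            )
        )
        if sp.ploidy_class in (4, 8):
            poly += f
            if sp.ploidy_class == 4:
                n4 += f
            else:
                n8 += f
    n_clonal = sum(cp.clonal for cp in clones)
    if n8 > 0:
        ratio = n4 / n8
    elif n4 > 0:
        ratio = math.inf
    else:
        ratio = math.nan
    return SampleSummary(
        sample_id=config.sample_id,
        n_analyzed=config.n_cells,
        average_ploidy=avg_ploidy,
        instability_index=instability_index(n_patterns, config.n_cells),
        n_patterns=n_patterns,
        n_clonal_patterns=n_clonal,
        clonal_patterns=clones,
        polyploid_fraction=100.0 * poly,
        tetra_octo_ratio=ratio,
        diversification=diversification_class(n_clonal),
    )


# ---------------------------------------------------------------------------
# YAML config plumbing for the CLI
# ---------------------------------------------------------------------------

def config_from_yaml(path: str | Path, panel: ProbePanel | None = None) -> SimConfig:
    """Load a simulation config from YAML.

    Two clone sources are supported: an explicit ``clones`` list (id, parent,
    genotype, frequency, n_wgd) or a ``tree`` block (n_clones, n_wgd,
    steps_per_edge) expanded through :func:`random_clone_tree`.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if panel is None:
        panel = default_panel()
    seed = int(doc.get("seed", 0))
    if "clones" in doc:
        clones = [
            SimClone(
                clone_id=str(c["id"]),
                genotype=tuple(int(x) for x in c["genotype"]),
                parent_id=None if c.get("parent") in (None, "") else str(c["parent"]),
                frequency=float(c["frequency"]),
                n_wgd=int(c.get("n_wgd", 0)),
            )
            for c in doc["clones"]
        ]
    elif "tree" in doc:
        t = doc["tree"]
        clones = random_clone_tree(
            panel,
            n_clones=int(t["n_clones"]),
            n_wgd=int(t.get("n_wgd", 0)),
            steps_per_edge=int(t.get("steps_per_edge", 1)),
            seed=seed,
        )
        if "frequencies" in t:
            clones = with_frequencies(clones, [float(f) for f in t["frequencies"]])
    else:
        raise SimulationError(f"{path}: config needs a 'clones' list or a 'tree' block")
    return SimConfig(
        panel=panel,
        clones=tuple(clones),
        n_cells=int(doc["n_cells"]),
        p_drop=float(doc.get("p_drop", DEFAULT_P_DROP)),
        p_split=float(doc.get("p_split", DEFAULT_P_SPLIT)),
        seed=seed,
        sample_id=str(doc.get("sample_id", "SIM")),
    )
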