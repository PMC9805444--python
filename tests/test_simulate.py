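import math

import numpy as np
import pytest
from scipy import stats

from mifish import (
    SimClone,
    SimConfig,
    SimulationError,
    counts_matrix,
    random_clone_tree,
    sample_cells,
    true_summary,
    with_frequencies,
)


def _single_clone_config(panel, **kw):
    root = SimClone("clone0", (2,) * len(panel), None, 1.0)
    defaults = dict(panel=panel, clones=(root,), n_cells=100, p_drop=0, p_split=0)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_single_diploid_clone_noise_free(small_panel):
    cells = sample_cells(_single_clone_config(small_panel, n_cells=100, seed=5))
    mat = counts_matrix(cells, small_panel)
    assert mat.shape == (100, 5)
    assert (mat == 2).all()


def test_sampling_is_deterministic_per_seed(small_panel):
    clones = random_clone_tree(small_panel, n_clones=4, n_wgd=1, seed=9)
    cfg = SimConfig(panel=small_panel, clones=tuple(clones), n_cells=500, seed=42)
    a = sample_cells(cfg)
    b = sample_cells(cfg)
    assert a.equals(b)
    again = random_clone_tree(small_panel, n_clones=4, n_wgd=1, seed=9)
    assert [c.genotype for c in again] == [c.genotype for c in clones]


def test_wgd_child_is_doubled_root(small_panel):
    clones = random_clone_tree(
        small_panel, n_clones=2, n_wgd=1, steps_per_edge=0, seed=0
    )
    assert clones[0].genotype == (2,) * 5
    assert clones[1].genotype == (4,) * 5
    assert clones[1].n_wgd == 1


def test_clone_fractions_match_frequencies(small_panel):
    """Observed clone fractions concentrate within the exact binomial CI."""
    root = SimClone("c0", (2,) * 5, None, 0.6)
    child = SimClone("c1", (2, 2, 3, 2, 2), "c0", 0.4)
    cfg = SimConfig(
        panel=small_panel, clones=(root, child), n_cells=10_000,
        p_drop=0, p_split=0, seed=1,
    )
    mat = counts_matrix(sample_cells(cfg), small_panel)
    n_child = int((mat[:, 2] == 3).sum())
    assert abs(n_child / 10_000 - 0.4) < 0.02
    lo, hi = stats.binom.interval(0.999, 10_000, 0.4)
    assert lo <= n_child <= hi


def test_dropout_shifts_mean_count_by_p_drop(small_panel):
    cfg = _single_clone_config(
        small_panel, n_cells=10_000, p_drop=0.05, p_split=0.0, seed=3
    )
    mat = counts_matrix(sample_cells(cfg), small_panel)
    assert np.allclose(mat.mean(axis=0), 2 - 0.05, atol=0.02)


def test_noise_free_fidelity(small_panel):
    """Without noise the distinct observed vectors are the clone genotypes."""
    clones = random_clone_tree(small_panel, n_clones=5, n_wgd=1, seed=4)
    clones = with_frequencies(clones, [0.3, 0.25, 0.2, 0.15, 0.1])
    cfg = SimConfig(
        panel=small_panel, clones=tuple(clones), n_cells=2000,
        p_drop=0, p_split=0, seed=8,
    )
    observed = set(map(tuple, counts_matrix(sample_cells(cfg), small_panel).tolist()))
    assert observed == {c.genotype for c in clones}


def test_true_summary_values(small_panel):
    cfg = _single_clone_config(small_panel)
    s = true_summary(cfg)
    assert s.average_ploidy == 2.0 and s.n_patterns == 1

    mixed = SimConfig(
        panel=small_panel,
        clones=(
            SimClone("c0", (2,) * 5, None, 0.5),
            SimClone("c1", (4,) * 5, "c0", 0.5, n_wgd=1),
        ),
        n_cells=100,
        p_drop=0,
        p_split=0,
    )
    s = true_summary(mixed)
    assert s.average_ploidy == pytest.approx(3.0)
    assert s.n_patterns == 2
    assert s.polyploid_fraction == pytest.approx(50.0)
    assert math.isinf(s.tetra_octo_ratio)


def test_config_validation(small_panel):
    with pytest.raises(SimulationError, match="sum"):
        SimConfig(
            panel=small_panel,
            clones=(SimClone("c0", (2,) * 5, None, 0.5),),
            n_cells=10,
        )
    with pytest.raises(SimulationError, match="diploid"):
        SimConfig(
            panel=small_panel,
            clones=(SimClone("c0", (3,) * 5, None, 1.0),),
            n_cells=10,
        )
    with pytest.raises(SimulationError, match="doublings"):
        random_clone_tree(small_panel, n_clones=2, n_wgd=2)
    with pytest.raises(SimulationError):
        # three doublings on one lineage exceed the per-lineage budget
        SimConfig(
            panel=small_panel,
            clones=(
                SimClone("c0", (2,) * 5, None, 0.25),
                SimClone("c1", (4,) * 5, "c0", 0.25, n_wgd=1),
                SimClone("c2", (8,) * 5, "c1", 0.25, n_wgd=1),
                SimClone("c3", (16,) * 5, "c2", 0.25, n_wgd=1),
            ),
            n_cells=10,
        )


def test_wgd_budget_respected_in_random_trees(small_panel):
    for seed in range(5):
        clones = random_clone_tree(
            small_panel, n_clones=7, n_wgd=2, steps_per_edge=1, seed=seed
        )
        by_id = {c.clone_id: c for c in clones}
        assert sum(c.n_wgd for c in clones) == 2
        for c in clones:
            used, cur = 0, c
            while cur.parent_id is not None:
                used += cur.n_wgd
                cur = by_id[cur.parent_id]
            assert used <= 2
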