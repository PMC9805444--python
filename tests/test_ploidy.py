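import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mifish import (
    PloidyError,
    SignalPattern,
    SimClone,
    SimConfig,
    aberrant_filter,
    annotate_cells,
    assign_ploidy,
    call_clones,
    code_gain_loss,
    diversification_class,
    enumerate_patterns,
    export_color_chart,
    instability_index,
    nas_binning,
    polyploidy_metrics,
    sample_cells,
    summarize_sample,
)


def _frame(small_panel, count_rows, sample_id="s1"):
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": [f"c{i}" for i in range(len(count_rows))],
            **{
                name: [row[j] for row in count_rows]
                for j, name in enumerate(small_panel.names)
            },
            "qc": "",
        }
    )


@pytest.mark.parametrize(
    "cep, expected",
    [
        ((2, 2), (2, 2)),
        ((4, 4), (4, 4)),
        ((4, 3), (4, 4)),  # mean 3.5 rounds half-up; class nearest-of-{2,4,8}
        ((3, 3), (3, 2)),  # reference 3, class tie resolved down to diploid
        ((6, 6), (6, 4)),  # class tie at 6 resolved down to tetraploid
        ((8, 8), (8, 8)),
        ((1, 0), (1, 2)),
    ],
)
def test_assign_ploidy(small_panel, cep, expected):
    counts = (2, 2, 2) + cep
    assert assign_ploidy(counts, small_panel) == expected


def test_assign_ploidy_unassignable(small_panel):
    with pytest.raises(PloidyError):
        assign_ploidy((2, 2, 2, 0, 0), small_panel)


def test_gain_loss_coding(panel):
    # diploid nucleus with a MYC gain to 4 copies
    counts = [2] * 10
    counts[panel.index("MYC")] = 4
    coding = code_gain_loss(counts, 2, panel)
    assert coding[panel.gene_names.index("MYC")] == 1
    # tetraploid nucleus with TP53 at 2 copies: a relative loss
    counts = [4] * 10
    counts[panel.index("TP53")] = 2
    coding = code_gain_loss(counts, 4, panel)
    assert coding[panel.gene_names.index("TP53")] == -1
    # balanced nucleus: all neutral
    assert (code_gain_loss([3] * 10, 3, panel) == 0).all()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=9), min_size=5, max_size=5),
)
def test_coding_is_idempotent(small_panel, counts):
    """Recomputing the coding from (counts, ploidy_ref) never changes it."""
    if counts[3] + counts[4] == 0:
        counts = counts[:3] + [2, 2]
    sp = SignalPattern.from_counts(counts, small_panel)
    again = SignalPattern.from_counts(sp.counts, small_panel)
    assert again == sp
    assert sp.coding == tuple(code_gain_loss(sp.counts, sp.ploidy_ref, small_panel))


def test_patterns_key_on_full_vector(small_panel):
    cells = _frame(small_panel, [[2] * 5] * 60 + [[4] * 5] * 40)
    annotated, _ = annotate_cells(cells, small_panel)
    patterns = enumerate_patterns(annotated, small_panel)
    # balanced diploid and balanced tetraploid are distinct patterns
    assert len(patterns) == 2
    assert sum(patterns.values()) == 100


def test_clonality_threshold_is_strict(small_panel):
    patterns = {(2, 2, 2, 2, 2): 287, (3, 2, 2, 2, 2): 7, (2, 3, 2, 2, 2): 6}
    clones = call_clones(patterns, 300, small_panel)
    flags = {cp.pattern.counts: cp.clonal for cp in clones}
    assert flags[(3, 2, 2, 2, 2)] is True  # 7/300 = 2.33% > 2%
    assert flags[(2, 3, 2, 2, 2)] is False  # 6/300 = 2.00%, not strictly above
    assert clones[0].pattern.counts == (2, 2, 2, 2, 2)  # major clone first

    single = call_clones({(2, 2, 2, 2, 2): 50}, 50, small_panel)
    assert single[0].clonal and single[0].fraction == 1.0


@pytest.mark.parametrize(
    "n_patterns, n, expected",
    [(1, 100, 1.0), (82, 296, 27.7), (44, 282, 15.6)],
)
def test_instability_index_reporting(n_patterns, n, expected):
    assert round(instability_index(n_patterns, n), 1) == expected


def test_instability_bounds_and_duplicates(small_panel):
    cells = _frame(small_panel, [[2, 2, 3, 2, 2]] * 4 + [[2] * 5] * 6)
    annotated, _ = annotate_cells(cells, small_panel)
    n = len(annotated)
    idx = instability_index(len(enumerate_patterns(annotated, small_panel)), n)
    assert 100.0 / n <= idx <= 100.0
    # duplicating an existing cell cannot add a pattern
    dup = pd.concat([cells, cells.iloc[[0]]], ignore_index=True)
    annotated2, _ = annotate_cells(dup, small_panel)
    assert len(enumerate_patterns(annotated2, small_panel)) == len(
        enumerate_patterns(annotated, small_panel)
    )


def test_aberrant_filter_modes(small_panel):
    rows = [
        [2, 2, 2, 2, 2],  # balanced diploid -> normal everywhere
        [4, 4, 3, 4, 4],  # tetraploid with a relative loss -> aberrant
        [8, 8, 8, 8, 8],  # balanced octoploid: mode-dependent
    ]
    annotated, _ = annotate_cells(_frame(small_panel, rows), small_panel)
    aberrant_hcc, normal_hcc = aberrant_filter(annotated, small_panel, mode="hcc")
    assert set(aberrant_hcc["cell_id"]) == {"c1", "c2"}
    aberrant_naf, normal_naf = aberrant_filter(annotated, small_panel, mode="nafld")
    assert set(aberrant_naf["cell_id"]) == {"c1"}
    # the split partitions the input in both modes
    for aberrant, normal in [(aberrant_hcc, normal_hcc), (aberrant_naf, normal_naf)]:
        assert len(aberrant) + len(normal) == 3


def test_polyploidy_metrics_basic(small_panel):
    diploid = _frame(small_panel, [[2] * 5] * 100)
    annotated, _ = annotate_cells(diploid, small_panel)
    m = polyploidy_metrics(annotated, small_panel)
    assert m.polyploid_fraction == 0.0
    assert m.mean_ploidy_2dp == 2.00
    assert math.isnan(m.tetra_octo_ratio)

    mixed = _frame(
        small_panel, [[2] * 5] * 90 + [[4, 4, 4, 4, 4]] * 9 + [[8] * 5]
    )
    annotated, _ = annotate_cells(mixed, small_panel)
    m = polyploidy_metrics(annotated, small_panel)
    assert m.polyploid_fraction == pytest.approx(10.0)
    assert m.tetra_octo_ratio == pytest.approx(9.0)


def test_polyploidy_metrics_reproduce_biopsy_case(small_panel):
    """Class counts 54 diploid / 5 tetraploid / 1 octoploid with one
    near-tetraploid nucleus reproduce fraction 10.00%, ratio 5:1 and a
    mean ploidy of 2.26."""
    rows = (
        [[2, 2, 2, 2, 2]] * 54
        + [[4, 4, 4, 4, 4]] * 4
        + [[4, 4, 4, 4, 3]]  # centromere mean 3.5 -> class 4
        + [[8, 8, 8, 8, 8]]
    )
    annotated, _ = annotate_cells(_frame(small_panel, rows), small_panel)
    m = polyploidy_metrics(annotated, small_panel)
    assert m.polyploid_fraction == pytest.approx(10.0)
    assert m.tetra_octo_ratio == pytest.approx(5.0)
    assert m.mean_ploidy_2dp == 2.26


@pytest.mark.parametrize("n, expected", [(5, "low"), (6, "low"), (7, "high"), (14, "high")])
def test_diversification_class(n, expected):
    assert diversification_class(n) == expected


def test_nas_binning():
    bins = nas_binning([3, 3, 1, 4, 4, 3, 2, 5, 5, 5, 5])
    assert bins.as_tuple() == (2, 5, 4)
    assert nas_binning([8]).as_tuple() == (0, 0, 1)
    zeros = nas_binning([0, 0])
    assert zeros.as_tuple() == (0, 0, 0) and zeros.zeros == 2
    with pytest.raises(PloidyError):
        nas_binning([9])


def test_summarize_sample_consistency(small_panel):
    clones = (
        SimClone("c0", (2, 2, 2, 2, 2), None, 0.55),
        SimClone("c1", (2, 2, 3, 2, 2), "c0", 0.30),
        SimClone("c2", (4, 4, 6, 4, 4), "c1", 0.15, n_wgd=1),
    )
    cfg = SimConfig(
        panel=small_panel, clones=clones, n_cells=1000, p_drop=0, p_split=0, seed=2
    )
    s = summarize_sample(sample_cells(cfg), small_panel, mode="hcc")
    assert s.n_analyzed == 1000
    assert s.n_patterns == 3
    assert s.n_clonal_patterns == 3
    assert sum(cp.n_cells for cp in s.clonal_patterns) == 1000
    assert sum(cp.fraction for cp in s.clonal_patterns) == pytest.approx(1.0)
    assert s.instability_index == pytest.approx(0.3)
    # gene-level calls come from the aberrant clonal patterns
    assert s.gene_calls["GENE_C"] == "gain"
    assert s.gene_calls["GENE_A"] == "none"


def test_clone_recovery_on_noise_free_sample(small_panel):
    """Called clones on a noise-free sample equal the simulated clones with
    frequency above the 2% threshold (exact set equality)."""
    clones = (
        SimClone("c0", (2, 2, 2, 2, 2), None, 0.90),
        SimClone("c1", (2, 3, 2, 2, 2), "c0", 0.09),
        SimClone("c2", (1, 2, 2, 2, 2), "c0", 0.01),  # below threshold
    )
    cfg = SimConfig(
        panel=small_panel, clones=clones, n_cells=5000, p_drop=0, p_split=0, seed=6
    )
    s = summarize_sample(sample_cells(cfg), small_panel)
    called = {cp.pattern.counts for cp in s.clonal_patterns if cp.clonal}
    assert called == {c.genotype for c in clones if c.frequency > 0.02}


def test_mean_ploidy_estimator_under_noise(small_panel):
    clones = (
        SimClone("c0", (2, 2, 2, 2, 2), None, 0.7),
        SimClone("c1", (4, 4, 4, 4, 4), "c0", 0.3, n_wgd=1),
    )
    n = 4000
    cfg = SimConfig(
        panel=small_panel, clones=clones, n_cells=n,
        p_drop=0.05, p_split=0.02, seed=13,
    )
    s = summarize_sample(sample_cells(cfg), small_panel)
    true_mean = 0.7 * 2 + 0.3 * 4  # 2.6
    expected = true_mean + (-0.05 + 0.02)  # additive -p_drop+p_split per probe
    se = 0.95 / math.sqrt(n)  # bound on the SD of the mean-ploidy estimator
    assert abs(s.average_ploidy - expected) < 3 * se + 0.01


def test_color_chart_export(tmp_path, small_panel):
    cells = _frame(small_panel, [[2, 2, 2, 2, 2]] * 3 + [[4, 2, 2, 2, 2]] * 2)
    path = tmp_path / "chart.tsv"
    chart = export_color_chart(cells, small_panel, path)
    assert path.exists()
    assert list(chart.columns[:3]) == ["cell_id", "ploidy_class", "pattern_n_cells"]
    assert set(chart["GENE_A"]) == {"neutral", "gain"}
    assert len(chart) == 5
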