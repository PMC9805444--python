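import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mifish import (
    EditModel,
    OracleBoundsError,
    TreeError,
    brute_force_tree,
    build_tree,
    classify_polyploidization,
    edit_cost,
    random_instance,
)

vectors = st.lists(st.integers(min_value=0, max_value=8), min_size=2, max_size=5)


def test_edit_cost_prefers_single_doubling_over_steps():
    cost, events = edit_cost((2,) * 10, (4,) * 10)
    assert cost == 1.0
    assert events == [("wgd",)]


def test_edit_cost_single_step():
    cost, events = edit_cost((2, 2, 2), (2, 3, 2))
    assert cost == 1.0
    assert events == [("step", 1, 1)]


def test_edit_cost_doubling_plus_residual_steps():
    cost, events = edit_cost((2, 2, 2, 2), (4, 5, 4, 3), wgd_allowed=1)
    assert cost == 3.0
    assert events[0] == ("wgd",)
    assert sorted(events[1:]) == [("step", 1, 1), ("step", 3, -1)]


def test_no_ploidy_reduction_by_default():
    """Evolution downward from tetraploid to diploid is pure step losses:
    two per probe on a 10-probe panel, not a cheap halving."""
    cost, events = edit_cost((4,) * 10, (2,) * 10)
    assert cost == 20.0
    assert all(e[0] == "step" for e in events)
    # the experimental halving flag makes it a single event
    model = EditModel(allow_ploidy_reduction=True)
    cost_h, events_h = edit_cost((4,) * 10, (2,) * 10, model)
    assert cost_h == model.wgd_cost
    assert events_h == [("halve",)]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(v=vectors.filter(lambda v: sum(v) >= 2))
def test_doubling_fidelity(v):
    """cost(v -> 2v) is exactly one doubling for any genotype with at least
    two signals (below that, unit steps are no more expensive)."""
    cost, events = edit_cost(tuple(v), tuple(2 * x for x in v))
    assert cost == EditModel().wgd_cost
    assert events == [("wgd",)]


@settings(max_examples=100, deadline=None, derandomize=True)
@given(a=vectors, b=vectors, c=vectors)
def test_triangle_inequality(a, b, c):
    n = min(len(a), len(b), len(c))
    a, b, c = tuple(a[:n]), tuple(b[:n]), tuple(c[:n])
    direct, _ = edit_cost(a, c, wgd_allowed=2)
    via1, _ = edit_cost(a, b, wgd_allowed=1)
    via2, _ = edit_cost(b, c, wgd_allowed=1)
    assert direct <= via1 + via2 + 1e-9


def test_single_pattern_tree_is_root_only():
    t = build_tree([(2,) * 10])
    assert t.total_cost == 0.0
    assert t.nodes == [(2,) * 10]
    assert t.graph.nodes[(2,) * 10]["observed"]


def test_wgd_pair_attaches_by_doubling():
    """A diploid clone with one loss and its exact tetraploid double are one
    step plus one doubling from the root."""
    p1 = (2, 2, 2, 2, 1, 2, 2, 2, 2, 2)
    p2 = tuple(2 * x for x in p1)
    t = build_tree([p1, p2])
    assert t.total_cost == 2.0
    assert t.graph.edges[p1, p2]["n_wgd"] == 1
    # same instance at oracle scale
    q1, q2 = (2, 2, 1), (4, 4, 2)
    assert build_tree([q1, q2]).total_cost == brute_force_tree([q1, q2]) == 2.0


def test_brute_force_examples():
    assert brute_force_tree([(2, 2)]) == 0.0
    assert brute_force_tree([(2, 2), (3, 2), (2, 3)]) == 2.0
    assert brute_force_tree([(2, 2), (4, 4), (4, 5)]) == 2.0


def test_brute_force_refuses_out_of_bounds():
    with pytest.raises(OracleBoundsError):
        brute_force_tree([(2,) * 5])  # too many probes
    with pytest.raises(OracleBoundsError):
        brute_force_tree([(7, 2)])  # count above 6
    with pytest.raises(OracleBoundsError):
        brute_force_tree([(i, 2) for i in range(6)])  # six patterns
    with pytest.raises(TreeError):
        build_tree([])


def test_heuristic_matches_oracle_on_random_instances():
    rng = np.random.default_rng(7)
    for _ in range(30):
        inst = random_instance(rng)
        assert build_tree(inst).total_cost == pytest.approx(
            brute_force_tree(inst), abs=1e-6
        )


def test_wgd_budget_never_exceeded():
    """No returned tree realizes a third doubling, even when a 16n pattern
    would tempt one."""
    t = build_tree([(2, 2), (4, 4), (8, 8), (16, 16)])
    assert t.max_wgd_per_path() <= 2
    # only two of the three doubling gaps may use the doubling event; the
    # cheapest remaining gap (2n -> 4n) costs four unit steps
    assert t.total_cost == 6.0
    assert sum(k for _, _, k in t.wgd_edges()) == 2
    rng = np.random.default_rng(3)
    for _ in range(20):
        t = build_tree(random_instance(rng))
        assert t.max_wgd_per_path() <= 2


def test_classification_equivalent_vs_accumulated():
    p1 = (2, 2, 1)
    t = build_tree([p1, (4, 4, 2)])
    call = classify_polyploidization(t)
    assert call.has_polyploidization and call.sample_label == "equivalent"

    t = build_tree([p1, (4, 5, 2)])  # doubled parent plus an extra gain
    call = classify_polyploidization(t)
    assert call.has_polyploidization and call.sample_label == "accumulated"

    t = build_tree([(2, 2, 2), (2, 3, 2)])  # no doubling anywhere
    call = classify_polyploidization(t)
    assert not call.has_polyploidization and call.sample_label is None


def test_exports(panel):
    p1 = (2, 2, 2, 2, 1, 2, 2, 2, 2, 2)
    t = build_tree([p1, tuple(2 * x for x in p1)], panel=panel)
    newick = t.to_newick(panel)
    assert newick.endswith(";") and newick.count("(") == newick.count(")")
    doc = t.to_json(panel)
    assert '"total_cost": 2.0' in doc
    assert "digraph" in t.to_dot()
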