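import math

import numpy as np
import pytest

from graphfm import (
    build_fm_index,
    build_imt,
    build_rank_maps,
    compact_intervals,
    encode_graph,
    single_vertex_ranges,
)
from graphfm.translate import check_interval_set, merge_interval_sets


def naive_translate(leaf_sets, a, b):
    """Oracle: plain union of covered leaves' members, then compaction."""
    values = []
    for s in leaf_sets[a : b + 1]:
        for lo, hi in s:
            values.extend(range(lo, hi + 1))
    return compact_intervals(values)


def random_interval_set(rng, universe):
    members = rng.choice(universe, size=int(rng.integers(0, universe + 1)), replace=False)
    return compact_intervals(int(m) for m in members)


def test_compact_merges_adjacent_and_singletons():
    assert compact_intervals([(1, 2), (3, 5)]) == ((1, 5),)
    assert compact_intervals([]) == ()
    assert compact_intervals([0, 2, 1]) == ((0, 2),)
    assert compact_intervals([(4, 6), (0, 1), 3]) == ((0, 1), (3, 6))


@pytest.mark.parametrize("seed", range(30))
def test_compaction_pigeonhole_bound(seed):
    """Any subset of 0..N-1 compacts to at most ceil(N/2) intervals."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 40))
    s = random_interval_set(rng, n)
    check_interval_set(s)
    assert len(s) <= math.ceil(n / 2)


def test_merge_equals_compact_of_union():
    rng = np.random.default_rng(5)
    for _ in range(50):
        a = random_interval_set(rng, 20)
        b = random_interval_set(rng, 20)
        merged = merge_interval_sets(a, b)
        check_interval_set(merged)
        assert merged == compact_intervals(list(a) + list(b))


@pytest.fixture(scope="module")
def cyc_parts(cyc_graph):
    enc = encode_graph(cyc_graph)
    fm = build_fm_index(enc.text, enc.alphabet_order, sa_period=1)
    maps = build_rank_maps(enc, fm)
    return enc, fm, maps


def test_cycle_fixture_rank_maps(cyc_parts):
    _, _, maps = cyc_parts
    # sigma0 block sorts "(C)1$" before "(TA)...": rank 0 is vertex 1
    assert maps.r_sigma0 == (1, 0)
    assert maps.r_sigma1 == (0, 1)  # identity permutation


def test_single_vertex_maps():
    from graphfm import StringGraph

    g = StringGraph(labels=["ACG"], edges=set())
    enc = encode_graph(g)
    fm = build_fm_index(enc.text, enc.alphabet_order, sa_period=1)
    maps = build_rank_maps(enc, fm)
    assert maps.r_sigma0 == (0,) and maps.r_sigma1 == (0,)


def test_cycle_fixture_single_vertex_ranges(cyc_parts, cyc_graph):
    _, _, maps = cyc_parts
    assert single_vertex_ranges(cyc_graph, maps, 0) == ((0, 0),)
    assert single_vertex_ranges(cyc_graph, maps, 1) == ((1, 1),)


def test_source_vertex_translates_to_empty():
    from graphfm import StringGraph

    g = StringGraph(labels=["A", "C"], edges={(0, 1)})
    enc = encode_graph(g)
    fm = build_fm_index(enc.text, enc.alphabet_order, sa_period=1)
    maps = build_rank_maps(enc, fm)
    source_rank = maps.r_sigma0.index(0)  # vertex 0 has no in-edges
    assert single_vertex_ranges(g, maps, source_rank) == ()


def test_imt_single_leaf():
    imt = build_imt([((0, 0),)])
    assert imt.translate(0, 0) == ((0, 0),)


def test_imt_cycle_fixture_root_value():
    imt = build_imt([((0, 0),), ((1, 1),)])
    assert imt.root.value == ((0, 1),)
    assert imt.translate(0, 1) == ((0, 1),)


def _check_node(node, leaf_sets):
    """Every node's value equals the compacted union of its leaf descendants."""
    assert node.value == naive_translate(leaf_sets, node.lo, node.hi)
    if node.left is not None:
        _check_node(node.left, leaf_sets)
        _check_node(node.right, leaf_sets)


def test_imt_node_invariant_random_64():
    rng = np.random.default_rng(9)
    leaf_sets = [random_interval_set(rng, 64) for _ in range(64)]
    imt = build_imt(leaf_sets)
    _check_node(imt.root, leaf_sets)


@pytest.mark.parametrize("n", range(1, 11))
def test_imt_translate_exhaustive_small(n):
    """All O(N^2) query intervals agree with the naive oracle for N <= 10."""
    rng = np.random.default_rng(n)
    leaf_sets = [random_interval_set(rng, n) for _ in range(n)]
    imt = build_imt(leaf_sets)
    for a in range(n):
        for b in range(a, n):
            assert imt.translate(a, b) == naive_translate(leaf_sets, a, b)


def test_imt_translate_randomized_up_to_256():
    rng = np.random.default_rng(77)
    for _ in range(20):
        n = int(rng.integers(2, 257))
        leaf_sets = [random_interval_set(rng, min(n, 30)) for _ in range(n)]
        imt = build_imt(leaf_sets)
        for _ in range(25):
            a = int(rng.integers(n))
            b = int(rng.integers(a, n))
            got = imt.translate(a, b)
            check_interval_set(got)
            assert got == naive_translate(leaf_sets, a, b)


def test_imt_rejects_out_of_range_queries():
    imt = build_imt([((0, 0),), ((1, 1),)])
    with pytest.raises(IndexError):
        imt.translate(0, 2)
    with pytest.raises(ValueError):
        build_imt([])
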