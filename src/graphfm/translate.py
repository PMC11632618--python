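"""Suffix-array range translation: rank maps, interval compaction, merge tree.

Graph connectivity is realised in the BWT domain by translating σ0 ranges
(edge destinations — a partial match that has reached the start of one or
more labels) into σ1 ranges (edge sources — the incoming neighbours whose
labels the match may continue into).

Two lookup tables bridge the text and suffix-array domains:

* ``r_sigma0[j]`` — the vertex whose opening σ0 occupies row j of the σ0
  suffix-array block;
* ``r_sigma1[v]`` — the σ1-block row of vertex v's closing σ1 (equal to Π(v)
  when the codewords enforce the permutation).

The single-vertex translator maps a σ0-block rank i to the compacted set of
σ1-block ranks of the in-neighbours of ``r_sigma0[i]``.  Arbitrary σ0-rank
intervals are answered by the interval-merge tree (IMT): a binary tree over
ranks whose leaves hold the single-vertex sets and whose internal nodes hold
the compacted merge of their children, so a query interval decomposes into
O(log V) pre-merged node values.

Interval sets are kept sorted, pairwise disjoint and non-adjacent; compaction
of any subset of {0..N-1} yields at most ⌈N/2⌉ intervals (pigeonhole: each
extra interval needs a gap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .encoding import GraphEncoding
from .fm import FMIndex
from .graph import StringGraph

Interval = tuple[int, int]  # inclusive [a, b], a <= b
IntervalSet = tuple[Interval, ...]  # sorted, disjoint, non-adjacent


def check_interval_set(s: IntervalSet) -> None:
    """Assert the IntervalSet invariants (sorted, disjoint, non-adjacent)."""
    for a, b in s:
        if a > b:
            raise ValueError(f"malformed interval [{a}, {b}]")
    for (a, b), (c, d) in zip(s, s[1:]):
        if c <= b + 1:
            raise ValueError(f"intervals [{a},{b}] and [{c},{d}] overlap or touch")


def compact_intervals(
    values: Iterable[int | Interval],
) -> IntervalSet:
    """Minimal sorted disjoint non-adjacent interval cover of the input union.

    Accepts a mix of integers and inclusive ``(a, b)`` pairs; adjacent
    intervals ([1,2] next to [3,5]) are merged.
    """
    items: list[Interval] = []
    for v in values:
        if isinstance(v, tuple):
            a, b = v
        else:
            a = b = int(v)
        if a > b:
            raise ValueError(f"malformed interval [{a}, {b}]")
        items.append((a, b))
    items.sort()
    out: list[Interval] = []
    for a, b in items:
        if out and a <= out[-1][1] + 1:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return tuple(out)


def merge_interval_sets(left: IntervalSet, right: IntervalSet) -> IntervalSet:
    """Compacted union of two already-compacted sets (linear merge)."""
    out: list[Interval] = []
    i = j = 0
    while i < len(left) or j < len(right):
        if j >= len(right) or (i < len(left) and left[i] <= right[j]):
            a, b = left[i]
            i += 1
        else:
            a, b = right[j]
            j += 1
        if out and a <= out[-1][1] + 1:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return tuple(out)


@dataclass(frozen=True)
class RankMaps:
    """σ0 SA-block rank → vertex id, and vertex id → σ1 SA-block rank."""

    r_sigma0: tuple[int, ...]
    r_sigma1: tuple[int, ...]


def build_rank_maps(enc: GraphEncoding, fmi: FMIndex) -> RankMaps:
    """Derive the rank maps from the suffix array of the encoding.

    Decodes every row of the σ0 and σ1 SA blocks and identifies the owning
    vertex through the label offset tables.
    """
    n = enc.n_vertices
    sigma0_block = fmi.char_range(enc.sigma0)
    sigma1_block = fmi.char_range(enc.sigma1)
    if len(sigma0_block) != n or len(sigma1_block) != n:
        raise ValueError("marker block size does not match vertex count")
    # vertex i's σ0 sits one position before its label; its σ1 at label end
    sigma0_pos = {enc.label_starts[i] - 1: i for i in range(n)}
    sigma1_pos = {enc.label_ends[i]: i for i in range(n)}
    r_sigma0 = []
    for row in range(sigma0_block.start, sigma0_block.end):
        r_sigma0.append(sigma0_pos[fmi.sa_value(row)])
    r_sigma1 = [0] * n
    for j, row in enumerate(range(sigma1_block.start, sigma1_block.end)):
        r_sigma1[sigma1_pos[fmi.sa_value(row)]] = j
    return RankMaps(r_sigma0=tuple(r_sigma0), r_sigma1=tuple(r_sigma1))


def single_vertex_ranges(
    graph: StringGraph, maps: RankMaps, i: int
) -> IntervalSet:
    """σ1-block ranks of the in-neighbours of the vertex at σ0-block rank i.

    Empty for source vertices (no incoming edges).  Ranks are σ1-block
    relative; the query engine shifts them by the σ1 block's SA start.
    """
    if not (0 <= i < len(maps.r_sigma0)):
        raise IndexError(f"σ0 rank {i} out of range")
    vertex = maps.r_sigma0[i]
    return compact_intervals(maps.r_sigma1[k] for k in graph.in_neighbors(vertex))


@dataclass
class IMTNode:
    lo: int
    hi: int
    value: IntervalSet
    left: "IMTNode | None" = None
    right: "IMTNode | None" = None


@dataclass
class IMT:
    """Interval-merge tree over σ0-block ranks 0..N-1.

    Leaves [k,k] hold the single-vertex translator's set for rank k; each
    parent holds the compacted merge of its children.  Built in
    Θ(N log N) with O(N) interval storage; a query interval is answered by
    recursive descent, merging the values of the O(log N) maximal nodes the
    interval covers.
    """

    root: IMTNode
    n_keys: int
    leaf_sets: tuple[IntervalSet, ...]

    def translate(self, a: int, b: int) -> IntervalSet:
        """Compacted union of leaf sets for ranks in the inclusive [a, b]."""
        if not (0 <= a <= b < self.n_keys):
            raise IndexError(f"query [{a}, {b}] outside key range 0..{self.n_keys - 1}")
        return _query(self.root, a, b)


def _query(node: IMTNode, a: int, b: int) -> IntervalSet:
    if a <= node.lo and node.hi <= b:
        return node.value
    if node.left is None:  # leaf not fully covered cannot happen (lo==hi)
        return node.value
    mid = node.left.hi
    if b <= mid:
        return _query(node.left, a, b)
    if a > mid:
        return _query(node.right, a, b)
    return merge_interval_sets(_query(node.left, a, mid), _query(node.right, mid + 1, b))


def _build(lo: int, hi: int, leaf_sets: Sequence[IntervalSet]) -> IMTNode:
    if lo == hi:
        return IMTNode(lo, hi, leaf_sets[lo])
    mid = (lo + hi) // 2
    left = _build(lo, mid, leaf_sets)
    right = _build(mid + 1, hi, leaf_sets)
    return IMTNode(lo, hi, merge_interval_sets(left.value, right.value), left, right)


def build_imt(per_rank_sets: Sequence[IntervalSet]) -> IMT:
    """Build the tree over the per-σ0-rank single-vertex sets."""
    if not per_rank_sets:
        raise ValueError("cannot build an IMT over zero keys")
    sets = tuple(tuple(s) for s in per_rank_sets)
    for s in sets:
        check_interval_set(s)
    return IMT(root=_build(0, len(sets) - 1, sets), n_keys=len(sets), leaf_sets=sets)


def build_translator(graph: StringGraph, maps: RankMaps) -> IMT:
    """Convenience: single-vertex sets for every σ0 rank, then the IMT."""
    sets = [
        single_vertex_ranges(graph, maps, i) for i in range(len(maps.r_sigma0))
    ]
    return build_imt(sets)
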