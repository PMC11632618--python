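"""Index assembly and the Find/Locate/Walk query algorithms.

The assembled index is a 4-tuple: an FM-index over the graph encoding, the
interval-merge-tree range translator, the σ0 rank map, and an optional
precomputed range cache — plus the decode tables and the graph itself
(retained for Walk reconstruction).

A query Q is matched backwards, last character first.  The engine tracks a
set U of disjoint suffix-array ranges — each the range of suffixes prefixed
by the partial match — and runs |Q| − 1 iterations of three phases:

fork
    A tracked range whose BWT slice contains σ0 has reached the start of one
    or more vertex labels: the partial match is a prefix of walks departing
    those vertices.  The σ0-advanced range, rebased to σ0-block ranks, is
    translated through the IMT into σ1-block intervals of the incoming
    neighbours — the "forks".
compact
    Forks from all tracked ranges are merged into a minimal interval set
    (never more than ⌈|V|/2⌉ intervals, by pigeonhole).
advance
    Every tracked range and fork is advanced by the next query character;
    ranges in which the character never precedes die.  Advancing a σ1 fork
    lands on the final character of an in-neighbour's label, and the search
    then walks backwards through that label until its σ0 triggers the next
    fork.

The surviving ranges decode to exactly the walk roots: (vertex, offset)
pairs from which some walk's label concatenation contains Q at that offset,
with the walk ending inside the vertex holding Q's final character
(minimality).  The effective query length |Q|′ counts LF advances — one for
the initial character refinement plus one per range advanced in the loop —
so a single-vertex (linear) graph has |Q|′ = |Q| and relative overhead
Δ(Q) = (|Q|′ − |Q|)/|Q| = 0, exactly as for a plain FM-index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from . import cache as cache_mod
from .cache import MISS, RangeCache, build_cache, encode_cache
from .encoding import (
    DEFAULT_CODE_ALPHABET,
    DEFAULT_SENTINEL,
    DEFAULT_SIGMA0,
    DEFAULT_SIGMA1,
    GraphEncoding,
    NotALabelPosition,
    encode_graph,
)
from .fm import FMIndex, SARange, build_fm_index
from .graph import StringGraph, Walk, WalkRoot
from .translate import (
    IMT,
    RankMaps,
    build_rank_maps,
    build_translator,
    compact_intervals,
)

logger = logging.getLogger("graphfm")

RangeSet = tuple[tuple[int, int], ...]


@dataclass
class QueryStats:
    """Instrumentation of one Find run.

    ``advance_invocations`` is the effective query length |Q|′ — the number
    of LF-mapping range advances performed.  ``tracked_intervals_per_iteration``
    records |U| after the initial refinement (or cache seed) and after each
    loop iteration; ``seeded_length`` is the number of query characters the
    cache pre-matched (0 without a cache).
    """

    query_length: int
    advance_invocations: int = 0
    forks_total: int = 0
    tracked_intervals_per_iteration: list[int] = field(default_factory=list)
    seeded_length: int = 0


def relative_effective_query_length(stats: QueryStats) -> float:
    """Δ(Q) = (|Q|′ − |Q|) / |Q|: query overhead relative to a linear FM-index."""
    if stats.query_length < 1:
        raise ValueError("query length must be >= 1")
    return (stats.advance_invocations - stats.query_length) / stats.query_length


@dataclass
class IndexOptions:
    """Construction options, recorded in the serialized header."""

    sigma0: str = DEFAULT_SIGMA0
    sigma1: str = DEFAULT_SIGMA1
    sentinel: str = DEFAULT_SENTINEL
    code_alphabet: tuple[str, ...] = DEFAULT_CODE_ALPHABET
    sa_period: int = 32
    rank_period: int = 64
    cache_depth: int = 0
    cache_backend: str = "table"


class GraphIndex:
    """Full-text index over a string graph answering walk-root queries."""

    def __init__(
        self,
        graph: StringGraph,
        encoding: GraphEncoding,
        fm: FMIndex,
        maps: RankMaps,
        translator: IMT,
        cache: RangeCache | None = None,
        options: IndexOptions | None = None,
    ):
        self.graph = graph
        self.encoding = encoding
        self.fm = fm
        self.maps = maps
        self.translator = translator
        self.cache = cache
        self.options = options or IndexOptions()
        self._sigma0_start = fm.char_range(encoding.sigma0).start
        self._sigma1_start = fm.char_range(encoding.sigma1).start
        self._label_chars = set(graph.alphabet)

    @property
    def n_vertices(self) -> int:
        return self.graph.n_vertices

    # -- engine primitives ---------------------------------------------------

    def _initial_state(self, c: str) -> RangeSet:
        """State after matching a single character: its full SA char block."""
        if c not in self._label_chars:
            return ()
        r = self.fm.char_range(c)
        return ((r.start, r.end),) if not r.empty else ()

    def _forks(self, state: RangeSet) -> tuple[RangeSet, int]:
        """Translate every σ0 hit in the tracked ranges into σ1 forks."""
        sigma0 = self.encoding.sigma0
        pieces = []
        for s, e in state:
            lo = self.fm.occ(sigma0, s)
            hi = self.fm.occ(sigma0, e)
            if hi > lo:
                pieces.extend(self.translator.translate(lo, hi - 1))
        if not pieces:
            return (), 0
        compacted = compact_intervals(pieces)
        base = self._sigma1_start
        return tuple((base + a, base + b + 1) for a, b in compacted), len(compacted)

    def _iterate_state(self, state: RangeSet, c: str) -> RangeSet:
        new_state, _ = self._iterate_counted(state, c)
        return new_state

    def _iterate_counted(self, state: RangeSet, c: str) -> tuple[RangeSet, int]:
        """One fork + compact + advance step; returns (state, n_advanced)."""
        forks, _ = self._forks(state)
        advanced = set()
        n_adv = 0
        for s, e in state + forks:
            n_adv += 1
            r = self.fm.advance_range(SARange(s, e), c)
            if not r.empty:
                advanced.add((r.start, r.end))
        return tuple(sorted(advanced)), n_adv

    # -- queries --------------------------------------------------------------

    def find(self, q: str) -> tuple[set[SARange], QueryStats]:
        """Suffix-array ranges whose decoded positions are the walk roots of ``q``."""
        if not q:
            raise ValueError("query must be non-empty")
        stats = QueryStats(query_length=len(q))
        unknown = set(q) - self._label_chars
        if unknown:
            logger.warning(
                "query contains characters outside the label alphabet: %s",
                "".join(sorted(unknown)),
            )
            return set(), stats

        if self.cache is not None and self.cache.depth >= 1:
            k = min(self.cache.depth, len(q))
            seeded = self.cache.lookup(q[len(q) - k :])
            if seeded is MISS:
                return set(), stats
            state: RangeSet = tuple(seeded)
            stats.seeded_length = k
            remaining = q[: len(q) - k]
        else:
            state = self._initial_state(q[-1])
            stats.advance_invocations = 1
            remaining = q[:-1]
        stats.tracked_intervals_per_iteration.append(len(state))

        for c in reversed(remaining):
            if not state:
                break
            forks, n_forks = self._forks(state)
            stats.forks_total += n_forks
            advanced = set()
            for s, e in state + forks:
                stats.advance_invocations += 1
                r = self.fm.advance_range(SARange(s, e), c)
                if not r.empty:
                    advanced.add((r.start, r.end))
            state = tuple(sorted(advanced))
            stats.tracked_intervals_per_iteration.append(len(state))
        return {SARange(s, e) for s, e in state}, stats

    def locate(self, q: str) -> tuple[set[WalkRoot], QueryStats]:
        """Walk roots (vertex, offset) of ``q``, deduplicated."""
        ranges, stats = self.find(q)
        roots: set[WalkRoot] = set()
        for r in ranges:
            for off in self.fm.sa_decode(r):
                try:
                    roots.add(self.encoding.decode_offset(off))
                except NotALabelPosition:  # pragma: no cover - engine invariant
                    continue
        return roots, stats

    def walk(
        self, q: str, max_walks: int = 1000
    ) -> tuple[list[Walk], bool, QueryStats]:
        """Reconstruct every minimal walk inducing ``q`` from each root.

        Localized DFS from each located root, exploring out-edges in
        ascending destination order; output sorted by (root, vertex sequence).
        Returns (walks, truncated, stats); ``truncated`` is set when
        ``max_walks`` stopped the enumeration early.
        """
        if max_walks < 1:
            raise ValueError("max_walks must be >= 1")
        roots, stats = self.locate(q)
        walks: list[Walk] = []
        truncated = False

        def dfs(vertex: int, qi: int, path: list[int], start: int) -> bool:
            label = self.graph.labels[vertex]
            pos = start if len(path) == 1 else 0
            while qi < len(q) and pos < len(label):
                if label[pos] != q[qi]:
                    return True
                pos += 1
                qi += 1
            if qi == len(q):
                walks.append(
                    Walk(vertices=tuple(path), start_offset=start, end_offset=pos)
                )
                return len(walks) < max_walks
            for nxt in self.graph.out_neighbors(vertex):
                path.append(nxt)
                ok = dfs(nxt, qi, path, start)
                path.pop()
                if not ok:
                    return False
            return True

        for root in sorted(roots):
            if not dfs(root.vertex, 0, [root.vertex], root.offset):
                truncated = True
                break
        walks.sort(key=lambda w: (w.vertices[0], w.start_offset, w.vertices))
        return walks, truncated, stats


def build_index(
    graph: StringGraph,
    permutation: list[int] | None = None,
    options: IndexOptions | None = None,
) -> GraphIndex:
    """Assemble the index: encoding, FM-index, rank maps, IMT, optional cache."""
    options = options or IndexOptions()
    encoding = encode_graph(
        graph,
        permutation=permutation,
        sigma0=options.sigma0,
        sigma1=options.sigma1,
        sentinel=options.sentinel,
        code_alphabet=options.code_alphabet,
    )
    fm = build_fm_index(
        encoding.text,
        encoding.alphabet_order,
        sa_period=options.sa_period,
        rank_period=options.rank_period,
    )
    maps = build_rank_maps(encoding, fm)
    translator = build_translator(graph, maps)
    index = GraphIndex(graph, encoding, fm, maps, translator, options=options)
    if options.cache_depth >= 1:
        cache = build_cache(index, options.cache_depth)
        if options.cache_backend == "fm_encoded":
            cache = encode_cache(cache)
        index.cache = cache
    return index


def interval_bound_holds(stats: QueryStats, n_vertices: int) -> bool:
    """Check |U| at iteration t never exceeds (t−1)·⌈|V|/2⌉ + 1.

    ``t`` counts from 1 at the initial character refinement; cache-seeded
    queries start at t = seeded length.
    """
    half = math.ceil(n_vertices / 2)
    t0 = max(stats.seeded_length, 1)
    for j, count in enumerate(stats.tracked_intervals_per_iteration):
        t = t0 + j
        if count > (t - 1) * half + 1:
            return False
    return True


# re-export for callers that treat the cache module through the engine surface
__all__ = [
    "GraphIndex",
    "IndexOptions",
    "QueryStats",
    "build_index",
    "relative_effective_query_length",
    "interval_bound_holds",
    "build_cache",
    "encode_cache",
    "cache_mod",
]
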