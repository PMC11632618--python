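"""Depth-d precomputed suffix-array range cache.

Backward search processes a query from its last character to its first, so
the first d characters processed are the query's final d characters.  The
cache maps every string K of length ≤ d induced by some walk to the full set
of suffix-array ranges the query engine tracks after matching K.  A query Q
longer than d is then seeded with the cached state for its last d characters
and only iterates |Q| − d more times; the early iterations — the expensive
ones, where forks proliferate before most die — are skipped entirely.  The
cache is a pure accelerator: results are identical with and without it.

Two interchangeable backends are provided:

* ``table`` — a plain dict from key to interval set;
* ``fm_encoded`` — the keys concatenated as  σ K_1 σ K_2 ... σ K_m σ $  with
  a marker σ outside the label alphabet, indexed by an FM-index.  Looking up
  σ K σ yields at most one match (keys are unique and marker-flanked); the
  matched row's rank within the σ suffix-array block addresses a permuted
  list of interval sets.  This mirrors how a static string→value map can be
  stored compressed yet queried at FM-index speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .fm import AlphabetOrder, FMIndex, build_fm_index

if TYPE_CHECKING:  # pragma: no cover
    from .engine import GraphIndex

# absolute SA ranges are stored half-open as (start, end) tuples
RangeSet = tuple[tuple[int, int], ...]

MISS = object()  # sentinel: key not induced by any walk

CACHE_MARKER = "#"
CACHE_SENTINEL = "$"


@dataclass
class CacheEncoding:
    """FM-index-backed storage of the key → interval-list map."""

    text: str
    marker: str
    fm: FMIndex
    lists: tuple[RangeSet | None, ...]  # indexed by σ-block row of each key's marker


@dataclass
class RangeCache:
    """Engine states for all induced strings of length 1..depth."""

    depth: int
    entries: dict[str, RangeSet]
    backend: str = "table"
    encoding: CacheEncoding | None = field(default=None, repr=False)

    def lookup(self, q: str):
        """Stored state for ``q``, or :data:`MISS` when not induced.

        Raises for ``|q| > depth`` — the caller must truncate to the cache
        depth before looking up.
        """
        if len(q) > self.depth:
            raise ValueError(
                f"lookup key of length {len(q)} exceeds cache depth {self.depth}"
            )
        if self.backend == "fm_encoded" and self.encoding is not None:
            return _fm_lookup(self.encoding, q)
        return self.entries.get(q, MISS)


def build_cache(index: "GraphIndex", depth: int) -> RangeCache:
    """Enumerate engine states for every induced string up to ``depth``.

    Breadth-first in the suffix-array domain: level-1 states come from each
    label character's initial range; level l+1 states extend each live key K
    by one engine iteration per alphabet character c (state(cK) =
    iterate(state(K), c)).  Dead states are pruned, so only strings actually
    induced by walks are enumerated — never the full Σ^d cube.  Keys whose
    every extension dies are still stored: a query may legitimately end there.
    """
    if depth < 1:
        raise ValueError("cache depth must be >= 1")
    sigma = sorted(index.graph.alphabet)
    entries: dict[str, RangeSet] = {}
    frontier: dict[str, RangeSet] = {}
    for c in sigma:
        state = index._initial_state(c)
        if state:
            frontier[c] = state
    entries.update(frontier)
    for _ in range(depth - 1):
        nxt: dict[str, RangeSet] = {}
        for key, state in frontier.items():
            for c in sigma:
                extended = index._iterate_state(state, c)
                if extended:
                    nxt[c + key] = extended
        entries.update(nxt)
        frontier = nxt
        if not frontier:
            break
    return RangeCache(depth=depth, entries=entries)


def encode_cache(
    cache: RangeCache,
    marker: str = CACHE_MARKER,
    sentinel: str = CACHE_SENTINEL,
) -> RangeCache:
    """Build the FM-encoded backend from a table-backed cache.

    The key text is  σ K_1 σ ... σ K_m σ $  (keys in sorted order, each
    preceded by the marker σ, one trailing marker, then the sentinel).  The
    interval lists are stored permuted by the σ-block suffix-array order of
    each key's leading marker, so a lookup's matched row addresses its list
    directly.
    """
    keys = sorted(cache.entries)
    label_chars = sorted({c for k in keys for c in k})
    if marker in label_chars or sentinel in label_chars or marker == sentinel:
        raise ValueError("cache marker/sentinel collide with key characters")
    text = "".join(marker + k for k in keys) + marker + sentinel
    order = AlphabetOrder((sentinel, marker, *label_chars))
    fm = build_fm_index(text, order, sa_period=1, rank_period=64)

    # text offset of the marker opening key i
    marker_offsets = []
    pos = 0
    for k in keys:
        marker_offsets.append(pos)
        pos += 1 + len(k)
    offset_to_key = {off: i for i, off in enumerate(marker_offsets)}

    block = fm.char_range(marker)
    lists: list[RangeSet | None] = [None] * len(block)
    for j, row in enumerate(range(block.start, block.end)):
        off = fm.sa_value(row)
        i = offset_to_key.get(off)
        if i is not None:
            lists[j] = cache.entries[keys[i]]
    enc = CacheEncoding(text=text, marker=marker, fm=fm, lists=tuple(lists))
    return RangeCache(
        depth=cache.depth,
        entries=dict(cache.entries),
        backend="fm_encoded",
        encoding=enc,
    )


def _fm_lookup(enc: CacheEncoding, q: str):
    """Backward-search σqσ; the match's σ-block rank addresses the list."""
    for c in q:
        if c not in enc.fm.alphabet.chars:
            return MISS
    r = enc.fm.search(enc.marker + q + enc.marker)
    if r.empty:
        return MISS
    block = enc.fm.char_range(enc.marker)
    idx = r.start - block.start
    value = enc.lists[idx]
    return MISS if value is None else value
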