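"""Graph encoding: flatten a string graph into an indexable text.

The encoding of a graph with vertices 0..N-1 (labels S_0..S_{N-1}) under a
vertex permutation Π is the string

    σ0 S_0 σ1 A_0  σ0 S_1 σ1 A_1  ...  σ0 S_{N-1} σ1 A_{N-1}  $

where σ0/σ1 are reserved markers opening and closing each label, A_i is a
fixed-length codeword over a code alphabet disjoint from everything else, and
'$' is the sentinel.  The alphabet is totally ordered as

    sentinel < σ0 < σ1 < code alphabet < label alphabet.

Because the suffix starting at vertex i's σ1 continues with A_i, and the
codewords are distinct strings of equal length, the sort order of the σ1
suffix-array block is exactly the sort order of the codewords.  Assigning
vertex i the codeword of sorted rank Π(i) therefore pins its σ1 to row Π(i)
of the σ1 block — the permutation is enforced purely through the text,
independent of the graph.

Text offsets inside label regions map back to (vertex, offset) walk roots by
binary search over the per-vertex label start table.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass

from .fm import AlphabetOrder
from .graph import StringGraph, WalkRoot, validate_graph

DEFAULT_SIGMA0 = "("
DEFAULT_SIGMA1 = ")"
DEFAULT_SENTINEL = "$"
DEFAULT_CODE_ALPHABET = ("0", "1")


class NotALabelPosition(ValueError):
    """Text offset points at a reserved-character region, not inside a label."""


@dataclass(frozen=True)
class Codebook:
    """Fixed-length codewords enforcing a vertex permutation.

    ``codewords`` is the lexicographically sorted list X_0 < ... < X_{N-1};
    ``assignment[i]`` is the codeword appended after vertex i's σ1, chosen so
    that the σ1 of vertex i receives σ1-block suffix-array rank Π(i).
    """

    code_alphabet: tuple[str, ...]
    codewords: tuple[str, ...]
    assignment: tuple[str, ...]


def assign_codewords(
    n: int,
    permutation: list[int],
    code_alphabet: tuple[str, ...] = DEFAULT_CODE_ALPHABET,
) -> Codebook:
    """Generate N sorted fixed-length codewords and assign them along Π.

    Codeword length is ``ceil(log_b N)`` for code alphabet size b, with a
    floor of 1 so the degenerate N=1 graph still places a code character
    after its σ1.  ``assignment[i] = codewords[permutation[i]]``.
    """
    if n <= 0:
        raise ValueError("vertex count must be positive")
    if len(code_alphabet) < 2:
        raise ValueError("code alphabet needs at least 2 characters")
    if sorted(permutation) != list(range(n)):
        raise ValueError("permutation is not a bijection on 0..n-1")
    b = len(code_alphabet)
    length = max(1, math.ceil(math.log(n, b))) if n > 1 else 1
    while b**length < n:  # guard float log rounding
        length += 1
    # the n lexicographically smallest base-b strings of that length
    chars = tuple(sorted(code_alphabet))
    codewords = []
    for value in range(n):
        digits = []
        v = value
        for _ in range(length):
            digits.append(chars[v % b])
            v //= b
        codewords.append("".join(reversed(digits)))
    assignment = tuple(codewords[permutation[i]] for i in range(n))
    return Codebook(
        code_alphabet=chars,
        codewords=tuple(codewords),
        assignment=assignment,
    )


@dataclass
class GraphEncoding:
    """The encoded text plus the tables needed to decode it."""

    text: str
    sigma0: str
    sigma1: str
    sentinel: str
    permutation: tuple[int, ...]
    label_starts: tuple[int, ...]
    label_ends: tuple[int, ...]
    alphabet_order: AlphabetOrder
    codebook: Codebook

    @property
    def n_vertices(self) -> int:
        return len(self.label_starts)

    def decode_offset(self, text_offset: int) -> WalkRoot:
        """Map a text offset inside a label region to its (vertex, offset).

        O(log V) binary search over the label start table.  Raises
        :class:`NotALabelPosition` for offsets in marker/codeword/sentinel
        regions (callers filter those out of suffix-array decodes).
        """
        i = bisect_right(self.label_starts, text_offset) - 1
        if i < 0 or text_offset >= self.label_ends[i]:
            raise NotALabelPosition(
                f"text offset {text_offset} is not inside a vertex label"
            )
        return WalkRoot(i, text_offset - self.label_starts[i])

    def is_label_position(self, text_offset: int) -> bool:
        i = bisect_right(self.label_starts, text_offset) - 1
        return i >= 0 and text_offset < self.label_ends[i]


def reserved_characters(
    sigma0: str = DEFAULT_SIGMA0,
    sigma1: str = DEFAULT_SIGMA1,
    sentinel: str = DEFAULT_SENTINEL,
    code_alphabet: tuple[str, ...] = DEFAULT_CODE_ALPHABET,
) -> set[str]:
    """The full reserved set a graph's labels must avoid."""
    res = {sigma0, sigma1, sentinel, *code_alphabet}
    if len(res) != 3 + len(set(code_alphabet)):
        raise ValueError("reserved characters must be pairwise distinct")
    return res


def encode_graph(
    graph: StringGraph,
    permutation: list[int] | None = None,
    codebook: Codebook | None = None,
    sigma0: str = DEFAULT_SIGMA0,
    sigma1: str = DEFAULT_SIGMA1,
    sentinel: str = DEFAULT_SENTINEL,
    code_alphabet: tuple[str, ...] = DEFAULT_CODE_ALPHABET,
) -> GraphEncoding:
    """Build the encoded text of ``graph`` under ``permutation``.

    ``permutation`` defaults to the identity.  The label alphabet must be
    disjoint from {σ0, σ1, sentinel} ∪ code alphabet; violations raise.
    """
    n = graph.n_vertices
    if n == 0:
        raise ValueError("cannot encode an empty graph")
    if permutation is None:
        permutation = list(range(n))
    reserved = reserved_characters(sigma0, sigma1, sentinel, code_alphabet)
    violations = validate_graph(graph, reserved)
    if violations:
        raise ValueError("invalid graph: " + "; ".join(violations))
    if codebook is None:
        codebook = assign_codewords(n, permutation, code_alphabet)
    if len(codebook.assignment) != n:
        raise ValueError("codebook size does not match vertex count")

    parts: list[str] = []
    label_starts: list[int] = []
    label_ends: list[int] = []
    pos = 0
    for i, label in enumerate(graph.labels):
        parts.append(sigma0)
        pos += 1
        label_starts.append(pos)
        parts.append(label)
        pos += len(label)
        label_ends.append(pos)
        parts.append(sigma1)
        parts.append(codebook.assignment[i])
        pos += 1 + len(codebook.assignment[i])
    parts.append(sentinel)
    text = "".join(parts)

    label_chars = sorted(graph.alphabet)
    order = AlphabetOrder(
        (sentinel, sigma0, sigma1, *codebook.code_alphabet, *label_chars)
    )
    return GraphEncoding(
        text=text,
        sigma0=sigma0,
        sigma1=sigma1,
        sentinel=sentinel,
        permutation=tuple(permutation),
        label_starts=tuple(label_starts),
        label_ends=tuple(label_ends),
        alphabet_order=order,
        codebook=codebook,
    )
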