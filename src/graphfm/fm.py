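"""FM-index over an arbitrary totally ordered alphabet.

The index stores the Burrows-Wheeler transform (BWT) of the text, the C array
of cumulative character counts, rank checkpoints at a fixed stride, and a
sampled suffix array.  Backward search refines a half-open suffix-array row
range by prepending one character at a time (``advance_range``); sampled-SA
walk-back converts rows to text offsets (``sa_decode``).

The alphabet order is explicit rather than ASCII: graph encodings need the
reserved markers to sort below the codeword alphabet, which in turn sorts
below the label alphabet.  All comparisons go through the order's
character-to-code table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AlphabetOrder:
    """Total order over the text's characters, smallest first.

    The first character is the sentinel: it must occur exactly once in the
    text, at the end, and sorts strictly below everything else.
    """

    chars: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.chars)) != len(self.chars):
            raise ValueError("alphabet order has duplicate characters")
        if not self.chars:
            raise ValueError("alphabet order is empty")

    @property
    def sentinel(self) -> str:
        return self.chars[0]

    def code(self, c: str) -> int:
        try:
            return self.chars.index(c)
        except ValueError:
            raise KeyError(f"character {c!r} not in alphabet") from None

    def encode(self, text: str) -> np.ndarray:
        table = {c: i for i, c in enumerate(self.chars)}
        try:
            return np.fromiter(
                (table[c] for c in text), dtype=np.int32, count=len(text)
            )
        except KeyError as e:
            raise ValueError(f"text character {e.args[0]!r} not in alphabet") from None


@dataclass(frozen=True)
class SARange:
    """Half-open row interval ``[start, end)`` over the suffix array."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid SA range [{self.start}, {self.end})")

    @property
    def empty(self) -> bool:
        return self.start == self.end

    def __len__(self) -> int:
        return self.end - self.start


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling.

    O(n log² n); the sentinel (smallest, unique, final) guarantees all
    suffixes are distinguishable.
    """
    n = len(codes)
    rank = np.asarray(codes, dtype=np.int64)
    sa = np.argsort(rank, kind="stable")
    tmp = np.empty(n, dtype=np.int64)
    k = 1
    while k < n:
        # sort by (rank[i], rank[i+k]); absent second key sorts first
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        sa = np.lexsort((second, rank))
        tmp[sa[0]] = 0
        prev = sa[0]
        for j in range(1, n):  # re-rank; numpy-free tie walk
            cur = sa[j]
            tmp[cur] = tmp[prev] + (
                rank[cur] != rank[prev] or second[cur] != second[prev]
            )
            prev = cur
        rank = tmp.copy()
        if rank[sa[-1]] == n - 1:
            break
        k *= 2
    return sa.astype(np.int64)


def rank(s: str, c: str, i: int) -> int:
    """Occurrences of ``c`` in ``s[0..i]`` inclusive of position ``i``."""
    if not (0 <= i < len(s)):
        raise IndexError(f"rank position {i} out of bounds for length {len(s)}")
    return s.count(c, 0, i + 1)


@dataclass
class FMIndex:
    """FM-index: BWT + C array + rank checkpoints + sampled suffix array."""

    alphabet: AlphabetOrder
    bwt: str
    counts: dict[str, int]
    rank_period: int
    sa_period: int
    sampled_sa: dict[int, int]  # SA row -> text offset, rows where offset % period == 0
    text_length: int
    _bwt_codes: np.ndarray = field(default=None, repr=False, compare=False)
    _checkpoints: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._bwt_codes is None:
            self._bwt_codes = self.alphabet.encode(self.bwt)
        if self._checkpoints is None:
            self._checkpoints = _build_checkpoints(
                self._bwt_codes, len(self.alphabet.chars), self.rank_period
            )

    # -- rank / LF ---------------------------------------------------------

    def occ(self, c: str, i: int) -> int:
        """Occurrences of ``c`` in ``bwt[0:i]`` (exclusive prefix count)."""
        code = self.alphabet.code(c)
        return self._occ_code(code, i)

    def _occ_code(self, code: int, i: int) -> int:
        cp = i // self.rank_period
        base = int(self._checkpoints[cp, code])
        lo = cp * self.rank_period
        if lo == i:
            return base
        return base + int(np.count_nonzero(self._bwt_codes[lo:i] == code))

    def lf(self, i: int) -> int:
        """LF mapping: SA row of the suffix one character to the left."""
        code = int(self._bwt_codes[i])
        c = self.alphabet.chars[code]
        return self.counts[c] + self._occ_code(code, i)

    # -- search ------------------------------------------------------------

    def full_range(self) -> SARange:
        return SARange(0, self.text_length)

    def char_range(self, c: str) -> SARange:
        """SA rows of suffixes starting with ``c``."""
        code = self.alphabet.code(c)
        start = self.counts[c]
        if code + 1 < len(self.alphabet.chars):
            end = self.counts[self.alphabet.chars[code + 1]]
        else:
            end = self.text_length
        return SARange(start, end)

    def advance_range(self, r: SARange, c: str) -> SARange:
        """One backward-search step: range of suffixes ``c`` + (pattern of r)."""
        code = self.alphabet.code(c)
        base = self.counts[c]
        return SARange(
            base + self._occ_code(code, r.start), base + self._occ_code(code, r.end)
        )

    def search(self, q: str) -> SARange:
        """SA range of all suffixes prefixed by ``q`` (empty range if absent)."""
        if not q:
            raise ValueError("query must be non-empty")
        r = self.char_range(q[-1])
        for c in reversed(q[:-1]):
            if r.empty:
                return r
            r = self.advance_range(r, c)
        return r

    def count(self, q: str) -> int:
        return len(self.search(q))

    def sa_value(self, row: int) -> int:
        """Text offset for a single SA row via sampled-SA LF walk-back."""
        steps = 0
        while row not in self.sampled_sa:
            row = self.lf(row)
            steps += 1
        return (self.sampled_sa[row] + steps) % self.text_length

    def sa_decode(self, r: SARange) -> list[int]:
        """Text offsets of all rows in ``r``, sorted for determinism."""
        return sorted(self.sa_value(i) for i in range(r.start, r.end))

    def locate_linear(self, q: str) -> list[int]:
        """All start offsets of ``q`` in the text, sorted."""
        return self.sa_decode(self.search(q))

    def reconstruct_text(self) -> str:
        """Invert the BWT (sanity/identity check)."""
        out = []
        row = 0  # sentinel row; its BWT character is the text's last non-sentinel
        for _ in range(self.text_length - 1):
            out.append(self.bwt[row])
            row = self.lf(row)
        return "".join(reversed(out)) + self.alphabet.sentinel


def _build_checkpoints(codes: np.ndarray, n_chars: int, period: int) -> np.ndarray:
    n = len(codes)
    n_cp = n // period + 1
    cps = np.zeros((n_cp, n_chars), dtype=np.int64)
    running = np.zeros(n_chars, dtype=np.int64)
    for cp in range(1, n_cp):
        lo, hi = (cp - 1) * period, cp * period
        chunk = codes[lo:hi]
        running += np.bincount(chunk, minlength=n_chars)
        cps[cp] = running
    return cps


def build_fm_index(
    text: str,
    order: AlphabetOrder,
    sa_period: int = 32,
    rank_period: int = 64,
    sa: np.ndarray | None = None,
) -> FMIndex:
    """Build an FM-index over ``text``.

    ``text`` must end with the order's sentinel, occurring exactly once.  A
    precomputed suffix array may be supplied (it is validated for length
    only); otherwise one is computed by prefix doubling.
    """
    if not text:
        raise ValueError("text is empty")
    sentinel = order.sentinel
    if text[-1] != sentinel or text.count(sentinel) != 1:
        raise ValueError(
            "text must end with the sentinel, occurring exactly once"
        )
    codes = order.encode(text)
    if sa is None:
        sa = suffix_array(codes)
    sa = np.asarray(sa, dtype=np.int64)
    if len(sa) != len(text):
        raise ValueError("suffix array length mismatch")
    n = len(text)
    bwt_codes = codes[(sa - 1) % n]
    bwt = "".join(order.chars[c] for c in bwt_codes)
    # C array: SA start row of each character's block
    char_counts = np.bincount(codes, minlength=len(order.chars))
    starts = np.concatenate([[0], np.cumsum(char_counts)[:-1]])
    counts = {c: int(starts[i]) for i, c in enumerate(order.chars)}
    sampled = {
        int(row): int(off)
        for row, off in enumerate(sa)
        if off % sa_period == 0
    }
    return FMIndex(
        alphabet=order,
        bwt=bwt,
        counts=counts,
        rank_period=rank_period,
        sa_period=sa_period,
        sampled_sa=sampled,
        text_length=n,
        _bwt_codes=bwt_codes.astype(np.int32),
    )
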