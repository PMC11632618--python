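"""String-labelled directed graphs and their file dialects.

A string graph is a directed graph whose vertices carry non-empty string
labels; walks through the graph induce strings by concatenating the labels
they visit.  This module holds the in-memory model plus readers/writers for
two plain-text dialects:

* a GFA1 subset — ``S`` lines give vertex labels, ``L`` lines with ``+``/``+``
  orientations and ``0M`` overlap give edges; anything else (reverse strands,
  non-trivial overlaps, P/W lines) raises rather than being silently guessed;
* a simple TSV dialect — ``V <id> <label>`` and ``E <src> <dst>`` records.

Vertex ids are dense and 0-based internally regardless of the names used in
the input file; the original names are retained for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

DEFAULT_ALPHABET = frozenset("ACGTN")


class GraphParseError(ValueError):
    """Malformed line in a graph file; carries the 1-based line number."""


class UnsupportedFeatureError(GraphParseError):
    """Input uses a dialect feature that is deliberately not supported."""


@dataclass(frozen=True, order=True)
class WalkRoot:
    """A (vertex, offset) pair from which some walk induces a query.

    ``offset`` is 0-based into the vertex's label.
    """

    vertex: int
    offset: int

    def __iter__(self):
        return iter((self.vertex, self.offset))


@dataclass(frozen=True, order=True)
class Walk:
    """A matched walk: vertex sequence plus match offsets.

    ``start_offset`` is the 0-based match start within the first vertex's
    label; ``end_offset`` is exclusive within the last vertex's label.
    Consecutive vertices must be joined by graph edges; a single-vertex walk
    is allowed.
    """

    vertices: tuple[int, ...]
    start_offset: int
    end_offset: int


@dataclass
class StringGraph:
    """Directed graph with non-empty string labels on vertices.

    Parameters
    ----------
    labels
        Vertex labels; the list index is the 0-based vertex id.
    edges
        Set of ``(source, destination)`` vertex-id pairs.  Duplicate edges
        are collapsed (it is a set); self-loops and cycles are permitted.
    names
        Optional original vertex names from the input file, for reporting.
    """

    labels: list[str]
    edges: set[tuple[int, int]]
    names: list[str] | None = None
    _in_neighbors: dict[int, list[int]] | None = field(
        default=None, repr=False, compare=False
    )
    _out_neighbors: dict[int, list[int]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.edges = set(self.edges)

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def alphabet(self) -> set[str]:
        return set().union(*(set(s) for s in self.labels)) if self.labels else set()

    def in_neighbors(self, v: int) -> list[int]:
        """Sorted in-neighbour ids of ``v`` (sources of edges into ``v``)."""
        if self._in_neighbors is None:
            nbr: dict[int, list[int]] = {i: [] for i in range(self.n_vertices)}
            for s, d in sorted(self.edges):
                nbr[d].append(s)
            for v_ in nbr:
                nbr[v_].sort()
            self._in_neighbors = nbr
        return self._in_neighbors[v]

    def out_neighbors(self, v: int) -> list[int]:
        """Sorted out-neighbour ids of ``v``."""
        if self._out_neighbors is None:
            nbr = {i: [] for i in range(self.n_vertices)}
            for s, d in sorted(self.edges):
                nbr[s].append(d)
            for v_ in nbr:
                nbr[v_].sort()
            self._out_neighbors = nbr
        return self._out_neighbors[v]

    def total_label_length(self) -> int:
        return sum(len(s) for s in self.labels)


def validate_graph(graph: StringGraph, reserved: Iterable[str] = ()) -> list[str]:
    """Check graph invariants; returns human-readable violations (never raises).

    Verifies non-empty labels, edge endpoints in range, and that no label
    character collides with the ``reserved`` set (the encoding's marker
    characters, codeword alphabet and sentinel must stay disjoint from the
    label alphabet).
    """
    reserved = set(reserved)
    violations: list[str] = []
    n = graph.n_vertices
    for i, label in enumerate(graph.labels):
        if not label:
            violations.append(f"vertex {i}: empty label")
        for ch in set(label) & reserved:
            violations.append(f"vertex {i}: label contains reserved character {ch!r}")
    for s, d in sorted(graph.edges):
        if not (0 <= s < n):
            violations.append(f"edge ({s},{d}): source {s} is not a vertex")
        if not (0 <= d < n):
            violations.append(f"edge ({s},{d}): destination {d} is not a vertex")
    return violations


def _renumber(
    names: Sequence[str], labels: dict[str, str], edge_names: set[tuple[str, str]]
) -> StringGraph:
    index = {name: i for i, name in enumerate(names)}
    edges = {(index[s], index[d]) for s, d in edge_names}
    return StringGraph(
        labels=[labels[n] for n in names], edges=edges, names=list(names)
    )


def _load_gfa(lines: Iterable[str]) -> StringGraph:
    names: list[str] = []
    labels: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    pending_edges: list[tuple[str, str, int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "H":
            continue
        if tag == "S":
            if len(fields) < 3:
                raise GraphParseError(f"line {lineno}: S line needs name and sequence")
            name, seq = fields[1], fields[2]
            if seq == "" or seq == "*":
                raise GraphParseError(f"line {lineno}: empty label for segment {name!r}")
            if name in labels:
                raise GraphParseError(f"line {lineno}: duplicate segment {name!r}")
            names.append(name)
            labels[name] = seq
        elif tag == "L":
            if len(fields) < 6:
                raise GraphParseError(f"line {lineno}: L line needs 6 fields")
            src, so, dst, do, overlap = fields[1:6]
            if so != "+" or do != "+":
                raise UnsupportedFeatureError(
                    f"line {lineno}: only '+'/'+' orientations are supported "
                    "(no reverse-complementing is performed)"
                )
            if overlap not in ("0M", "*"):
                raise UnsupportedFeatureError(
                    f"line {lineno}: only 0M overlaps are supported, got {overlap!r}"
                )
            pending_edges.append((src, dst, lineno))
        else:
            raise UnsupportedFeatureError(
                f"line {lineno}: unsupported GFA record type {tag!r}"
            )
    for src, dst, lineno in pending_edges:
        if src not in labels or dst not in labels:
            raise GraphParseError(f"line {lineno}: edge references unknown segment")
        edges.add((src, dst))
    return _renumber(names, labels, edges)


def _load_tsv(lines: Iterable[str]) -> StringGraph:
    names: list[str] = []
    labels: dict[str, str] = {}
    pending: list[tuple[str, str, int]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        tag = fields[0]
        if tag == "V":
            if len(fields) != 3:
                raise GraphParseError(f"line {lineno}: V record needs id and label")
            name, label = fields[1], fields[2]
            if not label:
                raise GraphParseError(f"line {lineno}: empty label")
            if name in labels:
                raise GraphParseError(f"line {lineno}: duplicate vertex {name!r}")
            names.append(name)
            labels[name] = label
        elif tag == "E":
            if len(fields) != 3:
                raise GraphParseError(f"line {lineno}: E record needs src and dst")
            pending.append((fields[1], fields[2], lineno))
        else:
            raise GraphParseError(f"line {lineno}: unknown record type {tag!r}")
    edges: set[tuple[str, str]] = set()
    for src, dst, lineno in pending:
        if src not in labels or dst not in labels:
            raise GraphParseError(f"line {lineno}: edge references unknown vertex")
        edges.add((src, dst))
    return _renumber(names, labels, edges)


def load_graph(path, format: str = "tsv") -> StringGraph:
    """Read a string graph from ``path`` in the named dialect (``gfa``/``tsv``)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    if format == "gfa":
        return _load_gfa(lines)
    if format == "tsv":
        return _load_tsv(lines)
    raise ValueError(f"unknown graph format {format!r}")


def write_graph(graph: StringGraph, path, format: str = "tsv") -> None:
    """Write ``graph`` so that :func:`load_graph` round-trips labels and edges."""
    names = graph.names if graph.names is not None else [
        str(i) for i in range(graph.n_vertices)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        if format == "gfa":
            fh.write("H\tVN:Z:1.0\n")
            for name, label in zip(names, graph.labels):
                fh.write(f"S\t{name}\t{label}\n")
            for s, d in sorted(graph.edges):
                fh.write(f"L\t{names[s]}\t+\t{names[d]}\t+\t0M\n")
        elif format == "tsv":
            for name, label in zip(names, graph.labels):
                fh.write(f"V\t{name}\t{label}\n")
            for s, d in sorted(graph.edges):
                fh.write(f"E\t{names[s]}\t{names[d]}\n")
        else:
            raise ValueError(f"unknown graph format {format!r}")


def reverse_strand_duplicated(graph: StringGraph) -> StringGraph:
    """Return a graph with reverse-complement copies of all vertices appended.

    Convenience helper (off by default in the CLI): vertex ``i`` gains a twin
    ``N+i`` labelled with the reverse complement, and every edge ``(s, d)``
    gains the reversed twin ``(N+d, N+s)``.  Forward and reverse strands stay
    separate — there are no cross-strand edges.  Only meaningful for DNA
    alphabets.
    """
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    n = graph.n_vertices
    labels = list(graph.labels) + [
        s.translate(comp)[::-1] for s in graph.labels
    ]
    edges = set(graph.edges) | {(n + d, n + s) for s, d in graph.edges}
    names = None
    if graph.names is not None:
        names = list(graph.names) + [f"{nm}_rc" for nm in graph.names]
    return StringGraph(labels=labels, edges=edges, names=names)
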