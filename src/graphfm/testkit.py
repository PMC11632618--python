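"""Ground-truth oracles, canonical fixtures and the synthetic graph generator.

Everything the index computes cleverly in the suffix-array domain is
recomputed here the slow, obvious way: try every (vertex, offset) root and
walk the graph character by character.  The oracle bounds its exploration by
the remaining query length rather than a visited set — the same vertex may
legally appear many times in one walk (a length-6 query on a two-vertex
cycle needs it) — so it terminates even on cyclic graphs.

The generator produces seeded random graphs spanning the topology factors
that stress the index: short labels, high in/out-degree, and cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import StringGraph, Walk, WalkRoot


# -- canonical fixtures -------------------------------------------------------


def fixtures() -> dict[str, StringGraph]:
    """Named tiny graphs used throughout the test suite.

    * ``FIX-LIN`` — one vertex "ACGT", no edges: degenerates to linear text.
    * ``FIX-CYC`` — labels ["TA", "C"], edges 0→1 and 1→0: the smallest cycle;
      its encoding "(TA)0(C)1$" is the worked example for the whole pipeline.
    * ``FIX-FAN`` — a hub with three in- and three out-neighbours with short
      labels: maximal forking at one vertex.
    * ``FIX-OVL`` — a braided region where walks matching one query overlap
      and one root yields several walks.
    """
    fan_labels = ["A", "C", "G", "TT", "A", "C", "G"]  # 3 → hub(3) → 3
    fan_edges = {(0, 3), (1, 3), (2, 3), (3, 4), (3, 5), (3, 6)}
    ovl_labels = ["CAT", "A", "G", "CA", "TA"]
    ovl_edges = {(0, 1), (0, 2), (1, 3), (2, 3), (3, 4), (4, 0)}
    return {
        "FIX-LIN": StringGraph(labels=["ACGT"], edges=set()),
        "FIX-CYC": StringGraph(labels=["TA", "C"], edges={(0, 1), (1, 0)}),
        "FIX-FAN": StringGraph(labels=fan_labels, edges=fan_edges),
        "FIX-OVL": StringGraph(labels=ovl_labels, edges=ovl_edges),
    }


# -- synthetic graph generator ------------------------------------------------


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic graph generator; ``seed`` is mandatory."""

    n_vertices: int = 30
    label_length_range: tuple[int, int] = (1, 8)
    alphabet: str = "ACGT"
    edges_per_vertex_mean: float = 1.5
    allow_cycles: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.label_length_range
        if lo < 1 or hi < lo:
            raise ValueError("label lengths must satisfy 1 <= lo <= hi")
        if self.n_vertices < 1:
            raise ValueError("need at least one vertex")


def generate_graph(params: GeneratorParams) -> StringGraph:
    """Seeded random string graph honouring ``params``.

    Edge count is Poisson-ish: ``n_vertices * edges_per_vertex_mean`` draws of
    (source, destination) pairs, deduplicated.  With ``allow_cycles=False``
    only forward edges (source < destination) are kept, giving a DAG.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.label_length_range
    alphabet = list(params.alphabet)
    labels = [
        "".join(rng.choice(alphabet, size=int(rng.integers(lo, hi + 1))))
        for _ in range(params.n_vertices)
    ]
    n_edges = int(round(params.n_vertices * params.edges_per_vertex_mean))
    edges: set[tuple[int, int]] = set()
    for _ in range(n_edges):
        s = int(rng.integers(params.n_vertices))
        d = int(rng.integers(params.n_vertices))
        if params.allow_cycles:
            edges.add((s, d))
        elif s < d:
            edges.add((s, d))
        elif d < s:
            edges.add((d, s))
        # s == d dropped in the DAG case (self-loop is a cycle)
    return StringGraph(labels=labels, edges=edges)


# -- brute-force oracles ------------------------------------------------------


def _walks_from(
    graph: StringGraph, q: str, vertex: int, offset: int
) -> list[tuple[tuple[int, ...], int]]:
    """All minimal walks inducing ``q`` rooted at (vertex, offset).

    Returns (vertex sequence, end offset in last label) pairs.  DFS bounded
    by the remaining query length, so it terminates on cycles.
    """
    out: list[tuple[tuple[int, ...], int]] = []

    def dfs(v: int, qi: int, path: tuple[int, ...], pos: int) -> None:
        label = graph.labels[v]
        while qi < len(q) and pos < len(label):
            if label[pos] != q[qi]:
                return
            pos += 1
            qi += 1
        if qi == len(q):
            out.append((path, pos))
            return
        for nxt in graph.out_neighbors(v):
            dfs(nxt, qi, path + (nxt,), 0)

    dfs(vertex, 0, (vertex,), offset)
    return out


def brute_force_roots(graph: StringGraph, q: str) -> set[WalkRoot]:
    """Every (vertex, offset) from which some walk induces ``q``."""
    roots: set[WalkRoot] = set()
    for v, label in enumerate(graph.labels):
        for o in range(len(label)):
            if _walks_from(graph, q, v, o):
                roots.add(WalkRoot(v, o))
    return roots


def brute_force_walks(graph: StringGraph, q: str) -> list[Walk]:
    """Every minimal walk inducing ``q``, sorted like the engine's output."""
    walks: list[Walk] = []
    for v, label in enumerate(graph.labels):
        for o in range(len(label)):
            for path, end in _walks_from(graph, q, v, o):
                walks.append(Walk(vertices=path, start_offset=o, end_offset=end))
    walks.sort(key=lambda w: (w.vertices[0], w.start_offset, w.vertices))
    return walks


# -- randomized evaluation suite -----------------------------------------------


def suite_graphs(seed: int, n_graphs: int = 200) -> list[StringGraph]:
    """The standard randomized evaluation suite: seeded small graphs.

    Up to 30 vertices, label lengths 1-8 over ACGT, edge densities spanning
    0 to 3 edges per vertex, alternating cyclic and acyclic topologies.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n_graphs):
        params = GeneratorParams(
            n_vertices=int(rng.integers(2, 31)),
            label_length_range=(1, 8),
            edges_per_vertex_mean=float(rng.uniform(0.0, 3.0)),
            allow_cycles=(i % 2 == 0),
            seed=int(rng.integers(2**31)),
        )
        graphs.append(generate_graph(params))
    return graphs


def suite_queries(
    graph: StringGraph, n_queries: int, seed: int, max_length: int = 24
) -> list[str]:
    """Mixed hit/miss queries for one graph: alternating induced and random.

    Induced queries are cut from actual walks (shortened when the graph
    admits no walk string of the drawn length); random queries over ACGT are
    usually misses.  Lengths are drawn uniformly from 1..max_length.
    """
    rng = np.random.default_rng(seed)
    queries: list[str] = []
    for j in range(n_queries):
        length = int(rng.integers(1, max_length + 1))
        if j % 2 == 0:
            queries.append(_induced_query(graph, length, rng))
        else:
            queries.append("".join(rng.choice(list("ACGT"), size=length)))
    return queries


def _induced_query(graph: StringGraph, length: int, rng) -> str:
    """A string cut from a random walk; as long as the walk allows, up to
    ``length`` (labels are non-empty, so at least one character)."""
    v = int(rng.integers(graph.n_vertices))
    pos = int(rng.integers(len(graph.labels[v])))
    chars: list[str] = []
    while len(chars) < length:
        label = graph.labels[v]
        take = min(len(label) - pos, length - len(chars))
        chars.extend(label[pos : pos + take])
        succ = graph.out_neighbors(v)
        if len(chars) >= length or not succ:
            break
        v = succ[int(rng.integers(len(succ)))]
        pos = 0
    return "".join(chars)


# -- adversarial query sampling ----------------------------------------------


def sample_adversarial_queries(
    graph: StringGraph, length: int, count: int, seed: int = 0
) -> list[str]:
    """Seeded random-walk queries biased towards spanning many vertices.

    Walks greedily prefer successors with short labels (ties broken by the
    seeded rng), so each query crosses as many edges as the topology allows.
    Every query is cut from an actual walk's label concatenation, hence
    guaranteed to have at least one root.  Raises when no walk of the
    requested length exists.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_vertices
    queries: list[str] = []
    attempts = 0
    max_attempts = count * 50 + 100
    while len(queries) < count and attempts < max_attempts:
        attempts += 1
        v = int(rng.integers(n))
        offset = int(rng.integers(len(graph.labels[v])))
        chars: list[str] = []
        cur = v
        pos = offset
        while len(chars) < length:
            label = graph.labels[cur]
            take = min(len(label) - pos, length - len(chars))
            chars.extend(label[pos : pos + take])
            if len(chars) >= length:
                break
            succ = graph.out_neighbors(cur)
            if not succ:
                break
            shortest = min(len(graph.labels[s]) for s in succ)
            pool = [s for s in succ if len(graph.labels[s]) == shortest]
            cur = pool[int(rng.integers(len(pool)))]
            pos = 0
        if len(chars) == length:
            queries.append("".join(chars))
    if len(queries) < count:
        raise ValueError(
            f"graph admits no {length}-character walk strings "
            f"(found {len(queries)} of {count})"
        )
    return queries
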