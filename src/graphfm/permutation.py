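"""Vertex-permutation optimisation via Consecutive Block Minimization.

The permutation Π controls where each vertex's σ1 lands in the σ1 block of
the suffix array.  A good Π places the σ1s of vertices that are
in-neighbours of walks sharing a prefix next to each other, so the range
translator returns fewer intervals and queries track fewer ranges.  Choosing
the optimal Π is the NP-hard Consecutive Block Minimization (CBM) problem on
a binary matrix whose rows are constraint sets: for each sampled walk prefix
Q, the set of in-neighbours of all vertices from which a walk labelled Q...
departs.  We approximate the optimum with seeded simulated annealing over
column transpositions; an exhaustive enumerator over all n! permutations
serves as the test oracle for tiny instances.

Correctness of query answers never depends on Π — it is purely a
performance lever — which the test suite asserts end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import StringGraph


@dataclass(frozen=True)
class ConstraintMatrix:
    """Binary constraint matrix in sparse row form.

    ``rows[r]`` is the set of column (vertex) ids whose bit is set in row r;
    duplicates are removed at build time.
    """

    rows: tuple[frozenset[int], ...]
    n_cols: int

    def __post_init__(self):
        for row in self.rows:
            for j in row:
                if not (0 <= j < self.n_cols):
                    raise ValueError(f"column id {j} out of range")


def collect_constraints(
    graph: StringGraph,
    prefix_length: int = 4,
    max_prefixes: int = 100_000,
    seed: int = 0,
) -> ConstraintMatrix:
    """Enumerate walk-prefix constraint sets.

    For each distinct string Q of length ``prefix_length`` that labels the
    start of some walk (bounded DFS from every vertex at label offset 0), the
    row is the union of in-neighbour ids over all vertices rooting such a
    walk.  When more than ``max_prefixes`` distinct prefixes exist, a seeded
    uniform subsample of rows is kept.
    """
    if prefix_length < 1:
        raise ValueError("prefix_length must be >= 1")
    n = graph.n_vertices
    prefix_roots: dict[str, set[int]] = {}

    def dfs(root: int, vertex: int, acc: str) -> None:
        label = graph.labels[vertex]
        take = min(len(label), prefix_length - len(acc))
        acc = acc + label[:take]
        if len(acc) == prefix_length or not graph.out_neighbors(vertex):
            prefix_roots.setdefault(acc, set()).add(root)
            return
        for nxt in graph.out_neighbors(vertex):
            dfs(root, nxt, acc)

    for v in range(n):
        dfs(v, v, "")

    rows = []
    for q in sorted(prefix_roots):
        members: set[int] = set()
        for root in prefix_roots[q]:
            members.update(graph.in_neighbors(root))
        rows.append(frozenset(members))
    rows = sorted(set(rows), key=sorted)
    if len(rows) > max_prefixes:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(rows), size=max_prefixes, replace=False)
        rows = [rows[i] for i in sorted(keep)]
    return ConstraintMatrix(rows=tuple(rows), n_cols=n)


def _row_runs(columns: list[int]) -> int:
    """Number of maximal runs of consecutive integers in a sorted list."""
    runs = 0
    prev = None
    for c in columns:
        if prev is None or c != prev + 1:
            runs += 1
        prev = c
    return runs


def cbm_cost(matrix: ConstraintMatrix, pi: list[int]) -> int:
    """Total number of maximal 1-runs over all rows under column order ``pi``.

    Column j of the original matrix moves to position ``pi[j]``.
    """
    if sorted(pi) != list(range(matrix.n_cols)):
        raise ValueError("pi is not a bijection on 0..n_cols-1")
    total = 0
    for row in matrix.rows:
        total += _row_runs(sorted(pi[j] for j in row))
    return total


def exhaustive_cbm(matrix: ConstraintMatrix) -> tuple[list[int], int]:
    """Globally optimal permutation by enumeration (oracle; n_cols <= 8).

    Ties are broken by the lexicographically smallest permutation.
    """
    from itertools import permutations

    n = matrix.n_cols
    if n > 8:
        raise ValueError("exhaustive search is limited to n_cols <= 8")
    best_pi = list(range(n))
    best_cost = cbm_cost(matrix, best_pi)
    for perm in permutations(range(n)):
        pi = list(perm)
        cost = cbm_cost(matrix, pi)
        if cost < best_cost:
            best_cost, best_pi = cost, pi
    return best_pi, best_cost


def optimize_permutation(
    matrix: ConstraintMatrix,
    iterations: int = 10_000,
    cooling: float = 0.995,
    seed: int = 0,
) -> list[int]:
    """Simulated annealing over column transpositions.

    Starts at the identity; neighbour move swaps two columns' positions;
    acceptance by the Metropolis rule with geometric cooling.  The initial
    temperature is set from the cost spread of 100 random transpositions.
    Deterministic under ``seed``; the best permutation seen is returned, so
    the result never costs more than the identity.
    """
    n = matrix.n_cols
    if n == 0:
        raise ValueError("empty constraint matrix")
    if n == 1 or not matrix.rows:
        return list(range(n))
    rng = np.random.default_rng(seed)
    pi = list(range(n))

    # rows touching each original column, for incremental re-costing
    col_rows: list[list[int]] = [[] for _ in range(n)]
    for r, row in enumerate(matrix.rows):
        for j in row:
            col_rows[j].append(r)
    row_cols = [sorted(row) for row in matrix.rows]
    row_cost = [
        _row_runs(sorted(pi[j] for j in cols)) for cols in row_cols
    ]
    cost = sum(row_cost)

    def delta_for_swap(a: int, b: int) -> tuple[int, list[tuple[int, int]]]:
        """Cost change if original columns a and b swap positions."""
        affected = set(col_rows[a]) | set(col_rows[b])
        pi[a], pi[b] = pi[b], pi[a]
        updates = []
        delta = 0
        for r in affected:
            new = _row_runs(sorted(pi[j] for j in row_cols[r]))
            delta += new - row_cost[r]
            updates.append((r, new))
        pi[a], pi[b] = pi[b], pi[a]
        return delta, updates

    # initial temperature from the spread of random-move costs
    deltas = []
    for _ in range(min(100, max(1, n * (n - 1) // 2))):
        a, b = rng.choice(n, size=2, replace=False)
        d, _ = delta_for_swap(int(a), int(b))
        deltas.append(abs(d))
    temperature = max(1.0, float(np.mean(deltas)) * 2.0)

    best_pi, best_cost = list(pi), cost
    for _ in range(iterations):
        a, b = rng.choice(n, size=2, replace=False)
        a, b = int(a), int(b)
        delta, updates = delta_for_swap(a, b)
        if delta <= 0 or rng.random() < math.exp(-delta / max(temperature, 1e-12)):
            pi[a], pi[b] = pi[b], pi[a]
            for r, new in updates:
                row_cost[r] = new
            cost += delta
            if cost < best_cost:
                best_cost, best_pi = cost, list(pi)
        temperature *= cooling
    return best_pi
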