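# graphfm

Full-text indexing of string-labelled directed graphs — pangenome graphs,
splicing graphs, or any directed graph whose vertices carry non-empty string
labels — supporting **exact substring queries of unrestricted length** over
*all walks* of the graph, without enumerating walks.

## The problem

A string graph G(V, E, 𝕊) induces a string S whenever some walk
W = V_{a₁} → … → V_{a_w} has S as a substring of the label concatenation
S_W = S_{a₁}…S_{a_w}. Given a query Q, we want every **walk root**: each
(Vᵢ, oᵢ) pair such that a walk starting at Vᵢ contains Q at offset oᵢ of its
label concatenation, with the walk ending inside the vertex that holds Q's
final character (minimality). The number of *walks* matching Q can be
exponential, but the number of *roots* is polynomial — so that is what the
index returns (and walks can be reconstructed per root on demand).

## The method

The graph is flattened into a single text over a totally ordered alphabet,

```
GE(G, Π) = σ₀ S₁ σ₁ A₁  σ₀ S₂ σ₁ A₂ … σ₀ S_N σ₁ A_N $,    $ < σ₀ < σ₁ < Σ_Π < Σ
```

where σ₀/σ₁ are reserved markers opening/closing each vertex label and the
Aᵢ are fixed-length codewords over a disjoint alphabet Σ_Π that pin vertex
i's σ₁ to row Π(i) of the σ₁ suffix-array block. An FM-index over GE answers
backward search; whenever a partial match reaches a label start (σ₀ precedes
the tracked suffix-array range), a **range translator** R maps the σ₀ range
— the reachable edge destinations — to compacted σ₁-block intervals of their
incoming neighbours ("forks"), realised as an **interval-merge tree** (IMT)
that answers any σ₀-rank interval in O(log |V|) pre-merged node lookups.
Compaction never returns more than ⌈|V|/2⌉ intervals, which bounds the
tracked set at loop iteration t by (t−1)⌈|V|/2⌉ + 1.

Two optional accelerators change performance but never answers:

* a **vertex permutation Π** chosen by simulated annealing on a Consecutive
  Block Minimization instance, so σ₁ rows of vertices that co-occur as
  in-neighbours of shared walk prefixes become consecutive and compact well;
* a **depth-d range cache** storing the engine state for every induced
  string of length ≤ d (optionally stored behind its own FM-index), seeding
  a query with its last d characters so only |Q| − d iterations run.

Query overhead relative to a linear FM-index is measured by the relative
effective query length Δ(Q) = (|Q|′ − |Q|)/|Q|, where |Q|′ counts LF-mapping
range advances; Δ(Q) = 0 exactly on a single-vertex (linear) graph.

## Worked example

A two-vertex cycle — labels "TA" and "C", edges 0→1 and 1→0 — encoded as
`(TA)0(C)1$`:

```sh
$ cat toy.tsv
V	0	TA
V	1	C
E	0	1
E	1	0

$ graphfm index --graph toy.tsv --out toy.idx
$ printf 'AC\nCTAC\nGG\n' > queries.txt
$ graphfm query --index toy.idx --mode locate --queries queries.txt --stats
q1	0	1
q2	1	0
#stats	q1	2	3	0.5000	1
#stats	q2	4	6	0.5000	2
#stats	q3	2	0	-1.0000	0
```

Query `AC` has one root: vertex 0, offset 1 (the "A" of "TA", continuing
into "C" across the edge). Its stats row reads |Q| = 2, |Q|′ = 3 (one extra
LF advance paid for crossing the edge), Δ(Q) = 0.5, one fork. `CTAC` wraps
the cycle from vertex 1 and forks twice. `GG` contains a character absent
from every label and returns no rows (with a warning on stderr).

```sh
$ graphfm query --index toy.idx --mode walk --queries queries.txt
q1	1	1	0,1
q2	0	1	1,0,1
```

Walk rows give (start offset, end offset): vertex sequence — `CTAC` is
induced by the walk 1→0→1, visiting vertex 1 twice, matching from offset 0
and ending after character 1 of the final vertex.

`graphfm index --permutation anneal` optimizes Π before encoding;
`graphfm cache --index toy.idx --depth 4` adds a range cache;
`graphfm selftest --seed 1` checks the engine against the brute-force oracle
on random graphs.

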