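# Methods

## Model and data structures

A string graph is a directed graph whose vertices carry non-empty labels
over an alphabet Σ; a walk induces every substring of its label
concatenation. The index answers three query types: **Find** (suffix-array
ranges of walk roots), **Locate** (the roots as (vertex, offset) pairs), and
**Walk** (reconstructed walks per root). A root is *minimal*: the walk
starts inside the root vertex and ends inside the vertex containing the
query's final character — walks are never extended past the match.

Vertex ids are 0-based throughout (files may use arbitrary names; they are
densely renumbered in input order and the names retained for reporting).

### Graph encoding

`GE(G, Π) = σ₀S₀σ₁A₀ … σ₀S_{N−1}σ₁A_{N−1} $` with the alphabet ordered
`$ < σ₀ < σ₁ < Σ_Π < Σ`. The trailing terminator is an explicit sentinel
character: suffix sorting requires a unique smallest final symbol. The
codewords Aᵢ are the N lexicographically smallest fixed-length strings over
Σ_Π, of length ⌈log_{|Σ_Π|} N⌉ with a floor of 1 (the N = 1 graph would
otherwise get zero-length codewords and leave the σ₁ suffix order tied to
arbitrary downstream text). Assigning vertex i the codeword of sorted rank
Π(i) pins its σ₁ to σ₁-block suffix-array row Π(i): the suffixes starting at
σ₁s differ first in their equal-length, distinct codewords, so the codeword
order *is* the block order. Fixed-length codes only; variable-length
uniquely decodable codes would shrink the encoding but are not implemented.

Defaults: σ₀ = `(`, σ₁ = `)`, sentinel = `$`, Σ_Π = {`0`,`1`}. All are
configurable; label alphabets are arbitrary as long as they stay disjoint
from the reserved set (validated at encode time, reported by
`validate_graph`).

### FM-index

Plain text-domain FM-index: BWT, C array, rank checkpoints at a fixed stride
(default 64), suffix-array samples at text positions divisible by the
sampling period (default 32, both configurable). Suffix arrays are built by
prefix doubling over numpy lexsort — O(n log² n), exact for any alphabet
order — and verified against a naive comparison sort in the tests. The
`rank(s, c, i)` convention exposed by the API is *inclusive* of position i;
backward search internally uses the exclusive prefix count. Suffix-array
decoding walks LF to the nearest sampled row; position 0 is always sampled,
so the walk terminates without wrapping.

### Range translation

Two lookup tables bridge domains: `r_σ0[j]` is the vertex whose σ₀ occupies
σ₀-block row j; `r_σ1[v]` is the σ₁-block row of vertex v (equal to Π(v)
with enforced codewords — asserted in the tests against a naive suffix
sort). Each vertex has exactly one σ₁, so the single-vertex translator maps
a σ₀ rank to the compacted set of singleton σ₁ ranks of the vertex's
in-neighbours; a source vertex maps to the empty set.

The interval-merge tree (IMT) over σ₀ ranks [0, N−1] splits each node's key
range at the midpoint; leaves hold the single-vertex sets, parents the
compacted merge of their children. Queries descend recursively and merge the
maximal covered nodes (the priority-queue k-way merge is an equivalent
alternative; the recursive variant is what ships). Interval sets are kept
sorted, disjoint and non-adjacent; compacting any subset of {0..N−1} yields
at most ⌈N/2⌉ intervals (pigeonhole), which is what bounds the engine's
tracked set. The IMT's key domain (σ₀ suffix-array block rank) coincides
with the BWT occurrence rank of σ₀ because LF preserves relative order
within one character — the bridging fact the engine relies on when it
rebases a σ₀-advanced range to block ranks.

### Query loop

Backward search, last character first. State: a set of disjoint tracked
suffix-array ranges. Per iteration: (1) *fork* — for each tracked range
whose BWT slice contains σ₀, advance by σ₀, rebase to σ₀-block ranks, and
translate through the IMT into σ₁-block intervals; (2) *compact* — merge all
forks into one minimal interval set; (3) *advance* — advance every tracked
range and fork by the next query character, dropping empties. Tracked ranges
and forks live in disjoint character blocks and advancing preserves
disjointness, so deduplication is a safety net rather than a correctness
requirement. Roots reachable through multiple walks are reported once
(Locate returns a set).

The effective query length |Q|′ counts range advances: 1 for the initial
character refinement plus one per range advanced in the loop. This makes
|Q|′ = |Q| exact on a linear (single-vertex, edge-free) graph for every
occurring query, hence Δ(Q) = (|Q|′−|Q|)/|Q| = 0 there. Two boundary cases
are worth stating: a query that stops matching terminates early (fewer
advances than characters, Δ(Q) < 0), exactly as a plain FM-index backward
search would; and a fully-cached query (|Q| ≤ cache depth) performs no
advances at all. The tracked-interval bound is checked as
|U| ≤ (t−1)⌈|V|/2⌉ + 1 at iteration t, counting the initial refinement as
t = 1 (the +1 covers the initial range, which the pigeonhole argument on
forks does not).

Query characters outside the label alphabet produce an empty result and a
stderr warning rather than an exception, so batch FASTA querying never
aborts mid-file.

### Vertex permutation

Constraint rows are collected by bounded DFS from every vertex at label
offset 0: for each distinct walk-label prefix of the configured length
(default 4; rows capped at 10⁵ with seeded subsampling), the row is the
union of in-neighbour ids over all root vertices of that prefix. Walks that
dead-end early contribute their maximal shorter prefix — a row the full
reduction also implies, and harmless after deduplication. Minimizing the
total number of 1-runs over rows under a column permutation is the NP-hard
Consecutive Block Minimization problem; it is approximated by simulated
annealing (transposition moves, Metropolis acceptance, geometric cooling
0.995, default 10⁴ iterations, initial temperature from the cost spread of
100 random transpositions, incremental re-costing of affected rows only,
fully seeded). The returned permutation is the best seen, so it never costs
more than the identity. An exhaustive enumerator (n ≤ 8) is the test
oracle. The permutation affects only performance: the suite asserts
end-to-end that Locate output is identical under identity and annealed Π.

### Range cache

The cache maps every walk-induced string of length ≤ d (default depth 4
when enabled) to the engine state after matching it. It is built
breadth-first in the suffix-array domain — level 1 from each character's
initial range, level l+1 by one engine iteration per alphabet character —
so only live (induced) strings are enumerated, never the Σ^d cube. Keys
shorter than d whose every extension dies are stored too: a query may end
there. Because backward search consumes the query from its end, the lookup
key for a query Q is its final min(d, |Q|) characters; a miss proves Q is
not induced. The FM-encoded backend concatenates the keys as
`σK₁σK₂…σK_mσ$` with a marker σ ∉ Σ, indexes that text, and stores the
interval lists permuted by the σ-block suffix-array order of each key's
leading marker; looking up σQσ yields at most one match whose σ-block rank
addresses the list directly. Both backends are asserted equal on all keys.

## Synthetic data

The generator draws labels uniformly (lengths 1–8 over ACGT by default) and
edges as repeated uniform (source, destination) draws — roughly Poisson
degree — with an acyclic mode that keeps only forward edges. It reproduces
the structural drivers of query overhead (short labels, high degree,
cycles) but none of the statistics of real pangenomes or transcriptomes: no
shared-haplotype structure, no length/degree correlation, no biased base
composition. Passing the oracle-equivalence suite therefore demonstrates
*correctness* of the engine on arbitrary topologies at desk scale, not
performance at genome scale; the measured Δ(Q) values characterise these
synthetic topologies only. The evaluation suite uses 200 graphs of ≤ 30
vertices and 20 mixed hit/miss queries of length 1–24 each — sizes chosen so
the brute-force oracles (which enumerate walks explicitly) remain exact and
fast; all invariants tested are size-independent.

Adversarial queries are sampled from actual walks, greedily preferring
short-label successors to maximize vertices spanned per character — the
worst case for the fork machinery.

## Numerical and degenerate-input choices

* Tie-breaks: exhaustive CBM returns the lexicographically smallest optimal
  permutation; walk DFS explores out-edges in ascending id order and output
  is sorted by (root, vertex sequence); `sa_decode` sorts offsets.
* Degenerate inputs: N = 1 graphs (length-1 codewords), source vertices
  (empty translator sets), self-loops and revisited vertices (exploration
  bounded by remaining query length, not visited sets), queries of length 1
  (no loop iterations), empty caches (encode to `σ$`).
* Serialization is JSON with a version tag; the IMT is stored as leaf sets
  and rebuilt, the FM-encoded cache is re-encoded from its table on load.
  Round trips reproduce query results and statistics bit-exactly.
* Determinism: every random choice (generator, annealing, sampling) flows
  from an explicit seed; rebuilding an index from the same inputs is
  bit-identical.

## Limitations

One FM-index backend (no wavelet trees, r-index or move structures); no
reverse-complement-aware indexing (a reverse-strand duplication helper
exists as an explicit, off-by-default CLI flag); GFA support is a deliberate
S/L-only subset with `+`/`+` orientations and 0M overlaps — anything else
errors loudly rather than guessing coordinates; fixed-length codewords only;
no inexact matching or alignment scoring; single-threaded. Construction
materialises the encoding and its suffix array in memory, which is fine for
the desk-scale graphs the package targets and for moderately sized inputs,
but not for multi-gigabase pangenomes.
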