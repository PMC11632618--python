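"""Versioned on-disk container for the index and its cache.

The container is a single JSON document (the indexed graphs are desk-scale;
a text format keeps the layout self-documenting and diff-able):

* ``version`` — format version tag;
* ``options`` — the construction options, for provenance;
* ``graph`` — labels, edges and original vertex names;
* ``encoding`` — reserved characters, permutation, codeword assignment and
  the label offset tables;
* ``fm`` — alphabet order, BWT, C array, checkpoint/sampling strides and the
  sampled suffix array (the checkpoints themselves are recomputed on load);
* ``rank_maps`` — the σ0 and σ1 rank tables;
* ``imt_leaves`` — the interval-merge tree's leaf sets (tree rebuilt on load);
* ``cache`` — optional; table backend stores the key → interval map, the
  FM-encoded backend additionally marks itself so it is re-encoded on load.

Round trips are bit-exact: a loaded index answers every query identically to
the in-memory original.
"""

from __future__ import annotations

import json

from .cache import RangeCache, encode_cache
from .encoding import Codebook, GraphEncoding
from .engine import GraphIndex, IndexOptions
from .fm import AlphabetOrder, FMIndex
from .graph import StringGraph
from .translate import RankMaps, build_imt

FORMAT_VERSION = "graphfm-index-1"


def save_index(index: GraphIndex, path) -> None:
    doc = {
        "version": FORMAT_VERSION,
        "options": {
            "sigma0": index.options.sigma0,
            "sigma1": index.options.sigma1,
            "sentinel": index.options.sentinel,
            "code_alphabet": list(index.options.code_alphabet),
            "sa_period": index.options.sa_period,
            "rank_period": index.options.rank_period,
            "cache_depth": index.options.cache_depth,
            "cache_backend": index.options.cache_backend,
        },
        "graph": {
            "labels": index.graph.labels,
            "edges": sorted(index.graph.edges),
            "names": index.graph.names,
        },
        "encoding": {
            "text": index.encoding.text,
            "permutation": list(index.encoding.permutation),
            "label_starts": list(index.encoding.label_starts),
            "label_ends": list(index.encoding.label_ends),
            "codewords": list(index.encoding.codebook.codewords),
            "assignment": list(index.encoding.codebook.assignment),
        },
        "fm": {
            "alphabet": list(index.fm.alphabet.chars),
            "bwt": index.fm.bwt,
            "counts": index.fm.counts,
            "rank_period": index.fm.rank_period,
            "sa_period": index.fm.sa_period,
            "sampled_sa": sorted(index.fm.sampled_sa.items()),
            "text_length": index.fm.text_length,
        },
        "rank_maps": {
            "r_sigma0": list(index.maps.r_sigma0),
            "r_sigma1": list(index.maps.r_sigma1),
        },
        "imt_leaves": [list(map(list, s)) for s in index.translator.leaf_sets],
        "cache": None,
    }
    if index.cache is not None:
        doc["cache"] = {
            "depth": index.cache.depth,
            "backend": index.cache.backend,
            "entries": {k: list(map(list, v)) for k, v in index.cache.entries.items()},
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_index(path) -> GraphIndex:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(f"unsupported index format {doc.get('version')!r}")
    o = doc["options"]
    options = IndexOptions(
        sigma0=o["sigma0"],
        sigma1=o["sigma1"],
        sentinel=o["sentinel"],
        code_alphabet=tuple(o["code_alphabet"]),
        sa_period=o["sa_period"],
        rank_period=o["rank_period"],
        cache_depth=o["cache_depth"],
        cache_backend=o["cache_backend"],
    )
    g = doc["graph"]
    graph = StringGraph(
        labels=list(g["labels"]),
        edges={tuple(e) for e in g["edges"]},
        names=g["names"],
    )
    e = doc["encoding"]
    codebook = Codebook(
        code_alphabet=options.code_alphabet,
        codewords=tuple(e["codewords"]),
        assignment=tuple(e["assignment"]),
    )
    order = AlphabetOrder(tuple(doc["fm"]["alphabet"]))
    encoding = GraphEncoding(
        text=e["text"],
        sigma0=options.sigma0,
        sigma1=options.sigma1,
        sentinel=options.sentinel,
        permutation=tuple(e["permutation"]),
        label_starts=tuple(e["label_starts"]),
        label_ends=tuple(e["label_ends"]),
        alphabet_order=order,
        codebook=codebook,
    )
    f = doc["fm"]
    fm = FMIndex(
        alphabet=order,
        bwt=f["bwt"],
        counts=dict(f["counts"]),
        rank_period=f["rank_period"],
        sa_period=f["sa_period"],
        sampled_sa={int(r): int(v) for r, v in f["sampled_sa"]},
        text_length=f["text_length"],
    )
    maps = RankMaps(
        r_sigma0=tuple(doc["rank_maps"]["r_sigma0"]),
        r_sigma1=tuple(doc["rank_maps"]["r_sigma1"]),
    )
    translator = build_imt(
        [tuple(tuple(iv) for iv in s) for s in doc["imt_leaves"]]
    )
    index = GraphIndex(graph, encoding, fm, maps, translator, options=options)
    if doc["cache"] is not None:
        c = doc["cache"]
        cache = RangeCache(
            depth=c["depth"],
            entries={
                k: tuple(tuple(iv) for iv in v) for k, v in c["entries"].items()
            },
        )
        if c["backend"] == "fm_encoded":
            cache = encode_cache(cache)
        index.cache = cache
    return index
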