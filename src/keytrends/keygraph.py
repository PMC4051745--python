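"""KeyGraph keyword extraction over a tokenized corpus.

KeyGraph builds a sentence-level co-occurrence graph in three stages:

1. *Black nodes* — the most frequent terms (top ``n_black_nodes`` by total
   occurrence count).
2. *Black links* — the strongest co-occurrence edges between black nodes
   (top ``n_black_links`` pairs by association weight, where the
   association of two terms is the sum over sentences of the minimum of
   their within-sentence counts). Connected components of the linked black
   nodes form the *clusters* (the "foundations" of the corpus).
3. *Red nodes* — terms, not necessarily frequent, whose *key score* is
   high: ``key(w) = 1 - prod_g (1 - based(w, g) / neighbors(g))`` over
   clusters ``g``, where ``based(w, g)`` counts co-occurrence of ``w`` with
   cluster members and ``neighbors(g)`` totals ``based`` over all terms.
   A red node touching two or more clusters bridges distinct foundations
   and is flagged as such.

All orderings use deterministic tie-breaks (count, then document
frequency, then lexicographic) so identical inputs give identical graphs
on any platform.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .corpus_io import Corpus


@dataclass(frozen=True)
class KeyGraphConfig:
    """Graph-size parameters: number of black nodes, black links, red nodes."""

    n_black_nodes: int = 30
    n_black_links: int = 20
    n_red_nodes: int = 10

    def __post_init__(self) -> None:
        for name in ("n_black_nodes", "n_black_links", "n_red_nodes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class TermStats:
    """Per-term tallies: total occurrences, sentence frequency, document frequency."""

    count: dict[str, int]
    sentence_freq: dict[str, int]
    doc_freq: dict[str, int]

    def terms(self) -> set[str]:
        return set(self.count)


@dataclass(frozen=True)
class KeyGraphResult:
    black_nodes: tuple[str, ...]
    black_links: tuple[tuple[str, str, int], ...]
    clusters: tuple[frozenset[str], ...]
    key_scores: dict[str, float]
    red_nodes: tuple[str, ...]
    red_links: tuple[tuple[str, str, int], ...]
    bridging_flags: dict[str, bool]
    stats: TermStats | None = None


def _sentences(corpus: Corpus):
    for d in corpus.documents:
        for s in d.sentences:
            yield s


def term_frequencies(corpus: Corpus) -> TermStats:
    """Tally term occurrences, sentence frequencies and document frequencies."""
    count: Counter[str] = Counter()
    sentence_freq: Counter[str] = Counter()
    doc_freq: Counter[str] = Counter()
    n_sentences = 0
    for d in corpus.documents:
        doc_terms: set[str] = set()
        for s in d.sentences:
            n_sentences += 1
            count.update(s)
            sentence_freq.update(set(s))
            doc_terms.update(s)
        doc_freq.update(doc_terms)
    if n_sentences == 0:
        raise ValueError("empty corpus: no sentences to analyze")
    return TermStats(dict(count), dict(sentence_freq), dict(doc_freq))


def select_black_nodes(stats: TermStats, config: KeyGraphConfig) -> tuple[str, ...]:
    """Top ``n_black_nodes`` terms by count; ties by document frequency then term."""
    if not stats.count:
        raise ValueError("no terms")
    order = sorted(
        stats.count,
        key=lambda t: (-stats.count[t], -stats.doc_freq.get(t, 0), t),
    )
    return tuple(order[: config.n_black_nodes])


def association(term_i: str, term_j: str, corpus: Corpus) -> int:
    """Co-occurrence weight: sum over sentences of min(count_i, count_j)."""
    if term_i == term_j:
        raise ValueError("association requires two distinct terms")
    total = 0
    for s in _sentences(corpus):
        ci = cj = 0
        for t in s:
            if t == term_i:
                ci += 1
            elif t == term_j:
                cj += 1
        total += min(ci, cj)
    return total


def _pair_associations(
    nodes: tuple[str, ...], corpus: Corpus
) -> dict[tuple[str, str], int]:
    node_set = set(nodes)
    weights: Counter[tuple[str, str]] = Counter()
    for s in _sentences(corpus):
        present = Counter(t for t in s if t in node_set)
        if len(present) < 2:
            continue
        for a, b in combinations(sorted(present), 2):
            weights[(a, b)] += min(present[a], present[b])
    return dict(weights)


def build_black_links(
    black_nodes: tuple[str, ...], corpus: Corpus, config: KeyGraphConfig
) -> tuple[tuple[tuple[str, str, int], ...], tuple[frozenset[str], ...]]:
    """Top ``n_black_links`` black-node pairs by association, plus clusters.

    Clusters are the connected components of the graph on linked nodes
    only; unlinked black nodes belong to no cluster.
    """
    if not black_nodes:
        raise ValueError("black_nodes must be non-empty")
    weights = _pair_associations(black_nodes, corpus)
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    links = tuple(
        (a, b, w) for (a, b), w in ranked[: config.n_black_links] if w > 0
    )
    g = nx.Graph()
    g.add_edges_from((a, b) for a, b, _ in links)
    clusters = tuple(
        sorted((frozenset(c) for c in nx.connected_components(g)), key=sorted)
    )
    return links, clusters


def _based_and_neighbors(
    corpus: Corpus, clusters: tuple[frozenset[str], ...]
) -> tuple[list[dict[str, int]], list[int]]:
    """based[g][w] = sum_s count(w,s) * count(g\\{w}, s); neighbors[g] = sum_w based."""
    based: list[Counter[str]] = [Counter() for _ in clusters]
    for s in _sentences(corpus):
        c = Counter(s)
        for gi, g in enumerate(clusters):
            total_g = sum(c[t] for t in g if t in c)
            if total_g == 0:
                continue
            b = based[gi]
            for w, cw in c.items():
                b[w] += cw * (total_g - (cw if w in g else 0))
    return [dict(b) for b in based], [sum(b.values()) for b in based]


def key_scores(
    corpus: Corpus, clusters: tuple[frozenset[str], ...]
) -> dict[str, float]:
    """Key score in [0, 1] for every term, given the cluster foundations.

    A cluster with ``neighbors == 0`` contributes nothing (factor 1).
    """
    if not clusters:
        raise ValueError("no foundations: key scores need at least one cluster")
    based, neighbors = _based_and_neighbors(corpus, clusters)
    scores: dict[str, float] = {}
    terms = set()
    for b in based:
        terms.update(b)
    for d in corpus.documents:
        for s in d.sentences:
            terms.update(s)
    for w in terms:
        prod = 1.0
        for gi in range(len(clusters)):
            if neighbors[gi] == 0:
                continue
            prod *= 1.0 - based[gi].get(w, 0) / neighbors[gi]
        scores[w] = 1.0 - prod
    return scores


def key_score(
    term: str, clusters: tuple[frozenset[str], ...], corpus: Corpus
) -> float:
    """Key score of a single term (convenience wrapper over :func:`key_scores`)."""
    return key_scores(corpus, clusters).get(term, 0.0)


def _red_links(
    red_nodes: tuple[str, ...],
    clusters: tuple[frozenset[str], ...],
    corpus: Corpus,
) -> tuple[tuple[tuple[str, str, int], ...], dict[str, bool]]:
    """Connect each red node to its strongest black partner per touched cluster."""
    links: list[tuple[str, str, int]] = []
    bridging: dict[str, bool] = {}
    # Per-sentence counters reused across red nodes.
    sent_counts = [Counter(s) for s in _sentences(corpus)]
    for r in red_nodes:
        touched = 0
        for g in clusters:
            best: tuple[int, str] | None = None
            for b in sorted(g):
                if b == r:
                    continue
                w = sum(min(c[r], c[b]) for c in sent_counts if r in c and b in c)
                if w > 0 and (best is None or w > best[0]):
                    best = (w, b)
            if best is not None:
                links.append((r, best[1], best[0]))
                touched += 1
        bridging[r] = touched >= 2
    return tuple(links), bridging


def run_keygraph(corpus: Corpus, config: KeyGraphConfig | None = None) -> KeyGraphResult:
    """Run the full KeyGraph chain on a corpus.

    Red nodes are the top ``n_red_nodes`` non-black terms by key score
    (strictly positive scores only, ties lexicographic); bridging flags
    record whether a red node's links touch two or more clusters.
    """
    config = config or KeyGraphConfig()
    stats = term_frequencies(corpus)
    black = select_black_nodes(stats, config)
    links, clusters = build_black_links(black, corpus, config)
    if clusters:
        scores = key_scores(corpus, clusters)
    else:
        scores = {}
    black_set = set(black)
    candidates = sorted(
        (t for t, v in scores.items() if t not in black_set and v > 0),
        key=lambda t: (-scores[t], t),
    )
    red = tuple(candidates[: config.n_red_nodes])
    red_links, bridging = _red_links(red, clusters, corpus)
    return KeyGraphResult(
        black_nodes=black,
        black_links=links,
        clusters=clusters,
        key_scores=scores,
        red_nodes=red,
        red_links=red_links,
        bridging_flags=bridging,
        stats=stats,
    )


# ---------------------------------------------------------------------------
# Export

def _to_nx(result: KeyGraphResult) -> nx.Graph:
    g = nx.Graph()
    stats = result.stats
    for t in result.black_nodes:
        g.add_node(
            t,
            role="black",
            count=stats.count.get(t, 0) if stats else 0,
            key_score=float(result.key_scores.get(t, 0.0)),
        )
    for t in result.red_nodes:
        g.add_node(
            t,
            role="red",
            count=stats.count.get(t, 0) if stats else 0,
            key_score=float(result.key_scores.get(t, 0.0)),
            bridging=bool(result.bridging_flags.get(t, False)),
        )
    for a, b, w in result.black_links:
        g.add_edge(a, b, weight=int(w), type="black")
    for r, b, w in result.red_links:
        if not g.has_edge(r, b):
            g.add_edge(r, b, weight=int(w), type="red")
    return g


def result_to_dict(result: KeyGraphResult) -> dict:
    return {
        "black_nodes": list(result.black_nodes),
        "black_links": [[a, b, w] for a, b, w in result.black_links],
        "clusters": [sorted(c) for c in result.clusters],
        "key_scores": {t: result.key_scores[t] for t in sorted(result.key_scores)},
        "red_nodes": list(result.red_nodes),
        "red_links": [[a, b, w] for a, b, w in result.red_links],
        "bridging_flags": {t: result.bridging_flags[t] for t in sorted(result.bridging_flags)},
    }


def result_from_dict(d: dict) -> KeyGraphResult:
    return KeyGraphResult(
        black_nodes=tuple(d["black_nodes"]),
        black_links=tuple((a, b, w) for a, b, w in d["black_links"]),
        clusters=tuple(frozenset(c) for c in d["clusters"]),
        key_scores=dict(d["key_scores"]),
        red_nodes=tuple(d["red_nodes"]),
        red_links=tuple((a, b, w) for a, b, w in d["red_links"]),
        bridging_flags=dict(d["bridging_flags"]),
    )


def _write_dot(g: nx.Graph, path: str) -> None:
    def q(s: str) -> str:
        return '"' + s.replace('"', '\\"') + '"'

    lines = ["graph keygraph {"]
    for n, attrs in sorted(g.nodes(data=True)):
        a = ", ".join(f"{k}={json.dumps(v)}" for k, v in sorted(attrs.items()))
        lines.append(f"  {q(n)} [{a}];")
    for a, b, attrs in sorted(g.edges(data=True)):
        at = ", ".join(f"{k}={json.dumps(v)}" for k, v in sorted(attrs.items()))
        lines.append(f"  {q(a)} -- {q(b)} [{at}];")
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def export_graph(result: KeyGraphResult, format: str, path: str) -> None:
    """Write the keyword graph as ``graphml``, ``dot`` or ``json``.

    GraphML and DOT carry node roles, counts, key scores and edge weights
    for graph tooling; the JSON form round-trips through
    :func:`result_from_dict` losslessly.
    """
    if format == "graphml":
        nx.write_graphml(_to_nx(result), path)
    elif format == "dot":
        _write_dot(_to_nx(result), path)
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(result_to_dict(result), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown graph format {format!r}")
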