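"""KeyGraph extraction: frequencies, links, clusters, key scores, exports."""

from collections import Counter
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from keytrends.keygraph import (
    KeyGraphConfig,
    association,
    build_black_links,
    export_graph,
    key_score,
    key_scores,
    result_from_dict,
    result_to_dict,
    run_keygraph,
    select_black_nodes,
    term_frequencies,
)

from conftest import make_corpus, random_corpus


# --- independent brute-force oracles -------------------------------------

def brute_counts(corpus):
    count, sent_freq, doc_freq = Counter(), Counter(), Counter()
    for d in corpus.documents:
        seen = set()
        for s in d.sentences:
            count.update(s)
            sent_freq.update(set(s))
            seen.update(s)
        doc_freq.update(seen)
    return count, sent_freq, doc_freq


def brute_association(a, b, corpus):
    total = 0
    for d in corpus.documents:
        for s in d.sentences:
            c = Counter(s)
            total += min(c[a], c[b])
    return total


def brute_key(term, clusters, corpus):
    sents = [Counter(s) for d in corpus.documents for s in d.sentences]
    prod = 1.0
    for g in clusters:
        def based(w):
            tot = 0
            for c in sents:
                in_g = sum(c[t] for t in g) - (c[w] if w in g else 0)
                tot += c[w] * in_g
            return tot
        terms = set()
        for c in sents:
            terms.update(c)
        neighbors = sum(based(w) for w in terms)
        if neighbors:
            prod *= 1 - based(term) / neighbors
    return 1 - prod


class TestTermFrequencies:
    def test_hand_tally(self):
        c = make_corpus([[["a", "b", "a"], ["b"]]])
        stats = term_frequencies(c)
        assert stats.count == {"a": 2, "b": 2}
        assert stats.sentence_freq == {"a": 1, "b": 2}
        assert stats.doc_freq == {"a": 1, "b": 1}

    def test_single_token(self):
        stats = term_frequencies(make_corpus([[["x"]]]))
        assert stats.count == {"x": 1}

    def test_empty_corpus_errors(self):
        from keytrends.corpus_io import Corpus, Document
        c = Corpus((Document("d0", "s", "2009-01", ()),))
        with pytest.raises(ValueError, match="empty corpus"):
            term_frequencies(c)


class TestBlackNodes:
    def test_truncates_to_available_terms(self):
        c = make_corpus([[["a", "b"], ["c", "d", "e"]]])
        assert len(select_black_nodes(term_frequencies(c), KeyGraphConfig())) == 5

    def test_tie_break_lexicographic(self):
        # z and b tied on count and doc freq; one slot -> lexicographically smaller
        c = make_corpus([[["z"] * 7 + ["b"] * 7 + ["a"] * 9]])
        top = select_black_nodes(term_frequencies(c), KeyGraphConfig(n_black_nodes=2))
        assert top == ("a", "b")

    def test_agrees_with_brute_force_sort(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c = random_corpus(rng, n_docs=6, n_terms=20)
            stats = term_frequencies(c)
            got = select_black_nodes(stats, KeyGraphConfig(n_black_nodes=8))
            ranked = sorted(
                stats.count,
                key=lambda t: (-stats.count[t], -stats.doc_freq[t], t),
            )
            assert list(got) == ranked[:8]


class TestAssociation:
    def test_min_sum_definition(self):
        c = make_corpus([[["a", "a", "b", "b", "b"]] * 4])
        assert association("a", "b", c) == 8

    def test_never_co_sentential(self):
        c = make_corpus([[["a"], ["b"]]])
        assert association("a", "b", c) == 0

    def test_identical_terms_rejected(self):
        with pytest.raises(ValueError):
            association("a", "a", make_corpus([[["a"]]]))

    def test_symmetric_and_matches_brute_force(self):
        for seed in range(40):
            rng = np.random.default_rng(seed)
            c = random_corpus(rng, n_docs=4, n_terms=6)
            assert association("t00", "t01", c) == association("t01", "t00", c)
            assert association("t00", "t01", c) == brute_association("t00", "t01", c)


class TestBlackLinks:
    def test_top_pairs_and_components(self):
        # (a,b) assoc 5, (c,d) assoc 4, (a,c) assoc 1
        c = make_corpus([
            [["a", "b"]] * 5 + [["c", "d"]] * 4 + [["a", "c"]],
        ])
        links, clusters = build_black_links(
            ("a", "b", "c", "d"), c, KeyGraphConfig(n_black_links=2)
        )
        assert {(a, b) for a, b, _ in links} == {("a", "b"), ("c", "d")}
        assert set(clusters) == {frozenset("ab"), frozenset("cd")}

    def test_chain_forms_one_cluster(self):
        c = make_corpus([[["a", "b"]] * 3 + [["b", "c"]] * 2])
        links, clusters = build_black_links(("a", "b", "c"), c, KeyGraphConfig())
        assert clusters == (frozenset("abc"),)

    def test_no_positive_association(self):
        c = make_corpus([[["a"], ["b"]]])
        links, clusters = build_black_links(("a", "b"), c, KeyGraphConfig())
        assert links == () and clusters == ()


class TestKeyScore:
    def _toy(self):
        sents = [["a", "b"], ["a", "b", "e"], ["c", "d"],
                 ["c", "d", "e"], ["a", "b"], ["c", "d"]]
        corpus = make_corpus([[s] for s in sents])
        clusters = (frozenset("ab"), frozenset("cd"))
        return corpus, clusters

    def test_bridging_term_hand_oracle(self):
        """Six-sentence toy: based(e,g)=2 and neighbors(g)=8 per cluster,
        so key(e) = 1 - (1 - 2/8)^2 = 0.4375."""
        corpus, clusters = self._toy()
        assert key_score("e", clusters, corpus) == pytest.approx(0.4375, abs=1e-12)
        assert key_score("e", clusters, corpus) == pytest.approx(
            brute_key("e", clusters, corpus), abs=1e-12)

    def test_no_cooccurrence_scores_zero(self):
        corpus, clusters = self._toy()
        lone = make_corpus([[s] for s in
                            [["a", "b"], ["c", "d"], ["q"]]])
        assert key_score("q", (frozenset("ab"), frozenset("cd")), lone) == 0.0

    def test_sole_cooccurrer_scores_one(self):
        # e accounts for ALL co-occurrence with cluster {a, b}: a and b
        # never share a sentence, so neighbors(g) comes entirely from e.
        corpus = make_corpus([[s] for s in [["a", "e"], ["b", "e"]]])
        assert key_score("e", (frozenset("ab"),), corpus) == pytest.approx(1.0)

    def test_requires_clusters(self):
        corpus, _ = self._toy()
        with pytest.raises(ValueError, match="no foundations"):
            key_scores(corpus, ())

    def test_scores_in_unit_interval_and_match_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            c = random_corpus(rng, n_docs=5, n_terms=8)
            clusters = (frozenset({"t00", "t01"}), frozenset({"t02", "t03"}))
            scores = key_scores(c, clusters)
            for term, v in scores.items():
                assert 0.0 <= v <= 1.0
                assert v == pytest.approx(brute_key(term, clusters, c), abs=1e-12)

    def test_monotone_under_added_cooccurrence(self):
        corpus, clusters = self._toy()
        before = key_score("e", clusters, corpus)
        from keytrends.corpus_io import Corpus, Document
        extra = Document("extra", "s", "2009-01", (("e", "a", "b"),))
        bigger = Corpus(corpus.documents + (extra,))
        assert key_score("e", clusters, bigger) >= before


class TestRunKeyGraph:
    def test_repeated_sentence_corpus(self):
        c = make_corpus([[["a", "b"]]] * 4)
        r = run_keygraph(c)
        assert set(r.black_nodes) == {"a", "b"}
        assert len(r.black_links) == 1
        assert r.red_nodes == ()  # no non-black terms exist

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        c = random_corpus(rng, n_docs=10, n_terms=25)
        assert result_to_dict(run_keygraph(c)) == result_to_dict(run_keygraph(c))

    def test_invariant_to_document_order(self):
        from keytrends.corpus_io import Corpus
        rng = np.random.default_rng(4)
        c = random_corpus(rng, n_docs=10, n_terms=25)
        shuffled = Corpus(tuple(reversed(c.documents)), window=c.window)
        assert result_to_dict(run_keygraph(c)) == result_to_dict(run_keygraph(shuffled))

    def test_red_nodes_are_non_black_by_key_score(self):
        rng = np.random.default_rng(5)
        c = random_corpus(rng, n_docs=12, n_terms=30)
        r = run_keygraph(c, KeyGraphConfig(n_black_nodes=10, n_black_links=8,
                                           n_red_nodes=5))
        assert set(r.red_nodes).isdisjoint(r.black_nodes)
        for t in r.red_nodes:
            assert r.key_scores[t] > 0

    def test_bridging_flag_set_when_two_clusters_touched(self):
        sents = [["a", "b"], ["a", "b", "e"], ["c", "d"],
                 ["c", "d", "e"], ["a", "b"], ["c", "d"]]
        c = make_corpus([[s] for s in sents])
        r = run_keygraph(c, KeyGraphConfig(n_black_nodes=4, n_black_links=2,
                                           n_red_nodes=1))
        assert r.red_nodes == ("e",)
        assert r.bridging_flags["e"] is True
        # red links touch both clusters
        assert len(r.red_links) == 2


class TestExport:
    @pytest.fixture()
    def result(self):
        c = make_corpus([[["a", "b"]]] * 3)
        return run_keygraph(c)

    def test_graphml_parses(self, result, tmp_path):
        p = tmp_path / "g.graphml"
        export_graph(result, "graphml", str(p))
        g = nx.read_graphml(str(p))
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g.nodes["a"]["role"] == "black"

    def test_json_round_trip(self, result, tmp_path):
        import json
        p = tmp_path / "g.json"
        export_graph(result, "json", str(p))
        restored = result_from_dict(json.loads(p.read_text()))
        assert result_to_dict(restored) == result_to_dict(result)

    def test_dot_edge_count(self, result, tmp_path):
        p = tmp_path / "g.dot"
        export_graph(result, "dot", str(p))
        text = p.read_text()
        assert text.count(" -- ") == len(result.black_links) + len(result.red_links)

    def test_unknown_format_rejected(self, result, tmp_path):
        with pytest.raises(ValueError, match="unknown graph format"):
            export_graph(result, "gexf", str(tmp_path / "g"))
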