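"""Shared fixtures and small random-corpus builders."""

from __future__ import annotations

import numpy as np
import pytest

from keytrends.corpus_io import Corpus, Document
from keytrends.lexicon import hpv_lexicon


def make_corpus(sentence_lists, stream="s", month="2009-01"):
    """Build a corpus of single-document-per-entry from lists of sentences.

    ``sentence_lists`` is a list of documents, each a list of sentences,
    each a list of tokens.
    """
    docs = tuple(
        Document(f"d{i}", stream, month, tuple(tuple(s) for s in sents))
        for i, sents in enumerate(sentence_lists)
    )
    return Corpus(docs)


def random_corpus(rng: np.random.Generator, n_docs=5, n_terms=12, max_sents=4,
                  max_len=6, months=("2009-01",)):
    """A small random corpus over a closed vocabulary, for oracle checks."""
    vocab = [f"t{i:02d}" for i in range(n_terms)]
    docs = []
    for i in range(n_docs):
        n_sents = int(rng.integers(1, max_sents + 1))
        sents = tuple(
            tuple(rng.choice(vocab, size=int(rng.integers(1, max_len + 1))))
            for _ in range(n_sents)
        )
        month = months[int(rng.integers(len(months)))]
        docs.append(Document(f"d{i}", "s", month, sents))
    return Corpus(tuple(docs), window=(min(months), max(months)))


@pytest.fixture(scope="session")
def lexicon():
    return hpv_lexicon()
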