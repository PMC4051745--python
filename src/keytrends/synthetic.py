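"""Seeded synthetic two-stream corpora with known burst, lag and agreement
structure.

The generator emulates the statistical shape of a media-surveillance
corpus — a newspaper stream with a sharp early-2010 surge in positive
coverage and a web stream whose negative coverage grows gradually and
covaries with the newspaper signal — without any linguistic realism:
background text is Zipf-distributed token soup, since counting and
co-occurrence operate on tokens, not meaning.

Each document draws 1-5 sentences of background tokens; for every
(stream, category) with a nonzero rate, one keyword of that category is
injected with probability ``baseline * burst(month)`` plus any coupled
contribution ``gain * source_coverage(t - lag)``, where the source
coverage is the *realized* fraction of source-stream documents containing
the source category — so a coupled target inherits the source's actual
month-to-month fluctuations at the injected lag. All randomness derives from
a single seed through per-(stream, month) substreams, so adding a stream
leaves other streams' draws untouched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Corpus, Document
from .lexicon import CATEGORIES, Lexicon, RaterLabels, hpv_lexicon
from .months import month_range

STUDY_WINDOW = ("2009-01", "2010-07")


@dataclass(frozen=True)
class Injection:
    """Per-document inclusion probability for one (stream, category).

    ``baseline`` is the flat per-document probability that a document
    contains a keyword of the category; ``burst`` maps months to
    multipliers (missing months multiply by 1).
    """

    baseline: float
    burst: dict[str, float] = field(default_factory=dict)

    def rate(self, month: str) -> float:
        return self.baseline * self.burst.get(month, 1.0)


@dataclass(frozen=True)
class Coupling:
    """Lagged linear drive from one (stream, category) intensity to another."""

    source: tuple[str, str]
    target: tuple[str, str]
    lag: int
    gain: float

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("coupling lag must be >= 0")
        if self.gain < 0:
            raise ValueError("coupling gain must be >= 0")


@dataclass(frozen=True)
class SimulationParams:
    months: tuple[str, ...]
    # stream -> Poisson mean, either flat or per-month {month: mean}
    docs_per_month: dict[str, float | dict[str, float]]
    injections: dict[tuple[str, str], Injection]
    couplings: tuple[Coupling, ...] = ()
    vocab_size: int = 200
    zipf_exponent: float = 1.3
    sentences_per_doc: tuple[int, int] = (1, 5)
    tokens_per_sentence: tuple[int, int] = (5, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.months:
            raise ValueError("months must be non-empty")
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        for (stream, cat), inj in self.injections.items():
            if cat not in CATEGORIES:
                raise ValueError(f"injections: invalid category {cat!r}")
            if not 0.0 <= inj.baseline <= 1.0:
                raise ValueError(f"injections[{stream},{cat}]: baseline outside [0,1]")
            if any(m < 0 for m in inj.burst.values()):
                raise ValueError(f"injections[{stream},{cat}]: negative burst multiplier")
        for c in self.couplings:
            if c.source not in self.injections:
                raise ValueError(f"coupling source {c.source} has no injection entry")
        for stream in self.docs_per_month:
            for m in self.months:
                if self.doc_mean(stream, m) < 0:
                    raise ValueError(f"docs_per_month[{stream}] must be >= 0")

    def doc_mean(self, stream: str, month: str) -> float:
        mean = self.docs_per_month[stream]
        if isinstance(mean, dict):
            return float(mean.get(month, 0.0))
        return float(mean)

    @property
    def streams(self) -> list[str]:
        return sorted(self.docs_per_month)


def _stream_key(stream: str) -> int:
    return zlib.crc32(stream.encode("utf-8"))


def _zipf_probs(vocab_size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


def expected_rate(
    params: SimulationParams, stream: str, category: str, t: int
) -> float:
    """Expected injection probability for month index ``t`` (clipped to [0, 1]).

    Coupled contributions use the expectation of the source's own rate at
    ``t - lag``; months before the window fall back to the source baseline.
    During generation the coupled term uses the *realized* source coverage
    fraction instead, whose expectation this is.
    """
    month = params.months[t]
    inj = params.injections.get((stream, category))
    rate = inj.rate(month) if inj else 0.0
    for c in params.couplings:
        if c.target != (stream, category):
            continue
        src = params.injections[c.source]
        ts = t - c.lag
        src_rate = src.rate(params.months[ts]) if ts >= 0 else src.baseline
        rate += c.gain * src_rate
    return float(min(max(rate, 0.0), 1.0))


def _stream_order(params: SimulationParams) -> list[str]:
    """Streams sorted so coupling sources are generated before their targets."""
    deps: dict[str, set[str]] = {s: set() for s in params.streams}
    for c in params.couplings:
        src_stream, tgt_stream = c.source[0], c.target[0]
        if src_stream != tgt_stream:
            deps[tgt_stream].add(src_stream)
    order: list[str] = []
    while deps:
        ready = sorted(s for s, d in deps.items() if not d)
        if not ready:
            raise ValueError(f"cyclic stream couplings among {sorted(deps)}")
        for s in ready:
            order.append(s)
            del deps[s]
        for d in deps.values():
            d.difference_update(ready)
    return order


def generate_corpus(
    params: SimulationParams, lexicon: Lexicon | None = None
) -> tuple[Corpus, dict]:
    """Draw a seeded corpus plus a ground-truth record of the generating rates.

    Returns ``(corpus, truth)`` where ``truth`` holds the per-month true
    injection rates per stream and category, the realized document counts,
    and the coupling structure — everything a recovery test needs.
    """
    lexicon = lexicon or hpv_lexicon()
    probs = _zipf_probs(params.vocab_size, params.zipf_exponent)
    vocab = np.array([f"w{i:04d}" for i in range(params.vocab_size)])
    # keywords are injected as tokenizer-normalized token runs so generated
    # corpora survive a write/read round trip unchanged
    from .corpus_io import tokenize

    cat_keywords = {
        cat: [
            seq
            for kw in lexicon.keywords(cat)
            if (seq := tuple(t for s in tokenize(kw) for t in s))
        ]
        for cat in CATEGORIES
    }

    docs: list[Document] = []
    truth_rates: dict[str, dict[str, dict[str, float]]] = {}
    realized: dict[tuple[str, str], list[float]] = {}
    n_docs: dict[str, dict[str, int]] = {}
    lo_s, hi_s = params.sentences_per_doc
    lo_t, hi_t = params.tokens_per_sentence

    def _realized_source_rate(coupling: Coupling, t: int) -> float:
        ts = t - coupling.lag
        if ts < 0:
            return params.injections[coupling.source].baseline
        return realized[coupling.source][ts]

    for stream in _stream_order(params):
        truth_rates[stream] = {c: {} for c in CATEGORIES}
        n_docs[stream] = {}
        for c in CATEGORIES:
            realized[(stream, c)] = []
        skey = _stream_key(stream)
        for t, month in enumerate(params.months):
            rng = np.random.default_rng(
                np.random.SeedSequence([params.seed, skey, t])
            )
            rates = {}
            for c in CATEGORIES:
                inj = params.injections.get((stream, c))
                rate = inj.rate(month) if inj else 0.0
                for cp in params.couplings:
                    if cp.target == (stream, c):
                        rate += cp.gain * _realized_source_rate(cp, t)
                rates[c] = float(min(max(rate, 0.0), 1.0))
                truth_rates[stream][c][month] = rates[c]
            n = int(rng.poisson(params.doc_mean(stream, month)))
            n_docs[stream][month] = n
            injected = {c: 0 for c in CATEGORIES}
            for k in range(n):
                n_sent = int(rng.integers(lo_s, hi_s + 1))
                lengths = rng.integers(lo_t, hi_t + 1, size=n_sent)
                flat = rng.choice(vocab, size=int(lengths.sum()), p=probs)
                sentences: list[list[str]] = []
                pos = 0
                for length in lengths:
                    sentences.append(list(flat[pos : pos + length]))
                    pos += int(length)
                for c in CATEGORIES:
                    if rates[c] > 0 and rng.random() < rates[c]:
                        injected[c] += 1
                        kws = cat_keywords[c]
                        kw = kws[int(rng.integers(len(kws)))]
                        sentences[int(rng.integers(n_sent))].extend(kw)
                docs.append(
                    Document(
                        doc_id=f"{stream}-{month}-{k:04d}",
                        stream=stream,
                        month=month,
                        sentences=tuple(tuple(s) for s in sentences),
                    )
                )
            for c in CATEGORIES:
                # realized coverage fraction; empty months fall back to the
                # expected rate so coupled targets see a finite signal
                realized[(stream, c)].append(
                    injected[c] / n if n > 0 else rates[c]
                )
    corpus = Corpus(tuple(docs), window=(params.months[0], params.months[-1]))
    truth = {
        "seed": params.seed,
        "months": list(params.months),
        "rates": truth_rates,
        "realized_rates": {
            f"{s}/{c}": vals for (s, c), vals in sorted(realized.items())
        },
        "n_docs": n_docs,
        "couplings": [
            {"source": list(c.source), "target": list(c.target), "lag": c.lag, "gain": c.gain}
            for c in params.couplings
        ],
    }
    return corpus, truth


def generate_rater_labels(
    lexicon: Lexicon, disagreement_rate: float, seed: int
) -> tuple[RaterLabels, RaterLabels]:
    """Simulate two raters: A labels per the lexicon; B independently flips
    each label to a uniformly random *different* category with the given
    probability."""
    if not lexicon.entries:
        raise ValueError("lexicon must be non-empty")
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5ABE15]))
    a_labels = dict(lexicon.entries)
    b_labels = {}
    for kw in sorted(a_labels):
        cat = a_labels[kw]
        if rng.random() < disagreement_rate:
            others = [c for c in CATEGORIES if c != cat]
            cat = others[int(rng.integers(len(others)))]
        b_labels[kw] = cat
    return RaterLabels("rater_a", a_labels), RaterLabels("rater_b", b_labels)


# Deterministic bumpy burst profile for lag-recovery experiments: strong
# month-to-month variation with little autocorrelation, so the injected lag
# dominates any accidental alignment.
_BUMPY_PROFILE = (
    1.0, 2.5, 0.6, 3.0, 1.0, 0.5, 2.0, 4.0, 1.2, 0.5, 1.8, 1.0,
    3.5, 0.8, 2.2, 0.5, 1.5, 3.0, 0.7, 2.8, 1.0, 0.5, 2.4, 1.2,
)


def coupled_pair_params(lag: int, seed: int, gain: float = 1.0) -> SimulationParams:
    """Minimal two-stream setup for lag-recovery experiments.

    A bursty newspaper-positive source (24 months, strongly varying burst
    profile) drives a quiet web-negative target at the given lag with high
    gain, so the target's growth series is essentially a lagged copy of
    the source's plus sampling noise. Staggering the target's growth
    against the source's recovers the lag:
    ``staggered_correlation(target_growth, source_growth, ...)``.
    """
    months = tuple(month_range("2009-01", "2010-12"))
    injections = {
        ("newspaper", "positive"): Injection(
            0.12, {m: _BUMPY_PROFILE[i] for i, m in enumerate(months)}
        ),
        ("web", "negative"): Injection(0.02, {}),
    }
    return SimulationParams(
        months=months,
        docs_per_month={"newspaper": 60.0, "web": 60.0},
        injections=injections,
        couplings=(
            Coupling(("newspaper", "positive"), ("web", "negative"), lag=lag, gain=gain),
        ),
        vocab_size=50,
        sentences_per_doc=(1, 2),
        tokens_per_sentence=(3, 5),
        seed=seed,
    )


def study_params(seed: int = 0) -> SimulationParams:
    """Default simulation mirroring the study's two-stream structure.

    Nineteen months (January 2009 - July 2010). The newspaper stream totals
    roughly 625 articles, flat through 2009 and surging through 2010 to a
    June peak; its positive-coverage rate is low and flat in 2009, jumps
    exceptionally in January 2010 (relative growth near 4, flagged
    downstream as an outlier), sits near 17 expected positive articles per
    month in February-April, and reaches about 47 in May — so the May
    growth statistic lands near 30/17. The web stream (120 pages per
    month; web volume is modeled as document counts, not search-hit
    estimates) grows gradually in every category, and its negative
    coverage is additionally driven by the newspaper positive signal at
    zero lag.
    """
    months = tuple(month_range(*STUDY_WINDOW))
    news_docs = {m: 20.0 for m in months}
    news_docs.update(
        {
            "2010-01": 40.0,
            "2010-02": 45.0,
            "2010-03": 45.0,
            "2010-04": 45.0,
            "2010-05": 70.0,
            "2010-06": 80.0,
            "2010-07": 60.0,
        }
    )
    # 2009: ordinary news-cycle fluctuation around the baseline (background
    # growth dispersion near 1, as monthly media tallies show); 2010: the surge
    surge = {
        "2009-01": 1.0, "2009-02": 0.6, "2009-03": 1.5, "2009-04": 0.8,
        "2009-05": 1.8, "2009-06": 1.2, "2009-07": 0.5, "2009-08": 1.1,
        "2009-09": 1.4, "2009-10": 0.7, "2009-11": 1.2, "2009-12": 0.9,
        "2010-01": 2.5,   # exceptional jump: ~20 positive articles after ~4/month
        "2010-02": 1.9,
        "2010-03": 1.9,
        "2010-04": 1.9,
        "2010-05": 3.35,  # ~47 positive articles
        "2010-06": 3.75,  # peak
        "2010-07": 3.35,
    }
    gradual = {m: 1.0 + 2.0 * i / (len(months) - 1) for i, m in enumerate(months)}
    injections = {
        ("newspaper", "positive"): Injection(0.20, dict(surge)),
        ("newspaper", "neutral"): Injection(0.25, dict(surge)),
        ("newspaper", "negative"): Injection(0.06, {}),
        ("web", "positive"): Injection(0.06, dict(gradual)),
        ("web", "neutral"): Injection(0.08, dict(gradual)),
        ("web", "negative"): Injection(0.04, dict(gradual)),
    }
    couplings = (
        Coupling(("newspaper", "positive"), ("web", "negative"), lag=0, gain=0.5),
    )
    return SimulationParams(
        months=months,
        docs_per_month={"newspaper": news_docs, "web": 120.0},
        injections=injections,
        couplings=couplings,
        seed=seed,
    )
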