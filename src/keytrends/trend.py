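"""Monthly keyword-category count series, the windowed growth statistic,
and exceptional-growth outlier exclusion.

For a stream x and month t, ``count_x(t)`` is the number of documents (or,
in occurrence mode, keyword matches) in that stream-month containing a
lexicon keyword of the chosen category. The growth statistic compares each
month with the mean of the preceding ``window_len`` months:

    growth_x(t) = (count_x(t) - m) / m,   m = mean of the window_len
                                              preceding counts

A four-month window smooths short-period noise; growth is undefined for
the first ``window_len`` months and wherever the preceding mean is zero.
Months with exceptionally large growth (iteratively, the maximum while it
exceeds mean + k*SD of the remaining values) are flagged and excluded from
downstream correlation rather than imputed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace

import numpy as np

from .corpus_io import Corpus, Document, TokenizerConfig, tokenize
from .lexicon import Lexicon
from .months import month_range

COUNT_MODES = ("document", "occurrence")


@dataclass(frozen=True)
class MonthlySeries:
    """Dense month -> integer count series for one stream and category."""

    stream: str
    category: str
    counts: dict[str, int]
    window: tuple[str, str]

    def __post_init__(self) -> None:
        expected = month_range(*self.window)
        if sorted(self.counts) != sorted(expected):
            raise ValueError("counts must cover exactly the window months")
        for m, c in self.counts.items():
            if not isinstance(c, int) or c < 0:
                raise ValueError(f"count for {m} must be a non-negative integer")

    @property
    def months(self) -> list[str]:
        return month_range(*self.window)


@dataclass(frozen=True)
class GrowthSeries:
    """Month -> growth values; months absent from ``values`` are undefined.

    ``excluded`` maps flagged months to a human-readable exclusion reason;
    excluded months keep their value but are dropped from correlations.
    """

    stream: str
    category: str
    values: dict[str, float]
    window: tuple[str, str]
    window_len: int = 4
    excluded: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.excluded is None:
            object.__setattr__(self, "excluded", {})
        for m in self.excluded:
            if m not in self.values:
                raise ValueError(f"excluded month {m} has no defined growth")

    def defined_months(self, include_excluded: bool = False) -> list[str]:
        return [
            m
            for m in month_range(*self.window)
            if m in self.values and (include_excluded or m not in self.excluded)
        ]


def _keyword_token_seqs(
    lexicon: Lexicon, category: str, tokenizer: TokenizerConfig | None = None
) -> list[tuple[str, ...]]:
    """Normalize keywords into token subsequences with the corpus tokenizer,
    so matching happens in the same token space as the documents."""
    tokenizer = tokenizer or TokenizerConfig()
    seqs = []
    for kw in lexicon.keywords(category):
        tokens = tuple(t for sent in tokenize(kw, tokenizer) for t in sent)
        if tokens:
            seqs.append(tokens)
    return seqs


def _count_matches(doc: Document, seqs: list[tuple[str, ...]]) -> int:
    """Number of (possibly overlapping-start) keyword matches in a document.

    Multi-word keywords match consecutive tokens within one sentence;
    matching is case-insensitive.
    """
    total = 0
    for sent in doc.sentences:
        low = [t.lower() for t in sent]
        for seq in seqs:
            k = len(seq)
            if k == 1:
                total += sum(1 for t in low if t == seq[0])
            elif k <= len(low):
                total += sum(
                    1 for i in range(len(low) - k + 1) if tuple(low[i : i + k]) == seq
                )
    return total


def monthly_counts(
    corpus: Corpus,
    lexicon: Lexicon,
    stream: str,
    category: str,
    mode: str = "document",
    tokenizer: TokenizerConfig | None = None,
) -> MonthlySeries:
    """Count keyword appearances per month for one stream and category.

    ``document`` mode counts documents containing at least one keyword of
    the category; ``occurrence`` mode counts every match. Every month of
    the corpus window gets a count, zero included. ``tokenizer`` normalizes
    the keywords and should match the one the corpus was tokenized with.
    """
    if stream not in corpus.streams:
        raise ValueError(f"stream {stream!r} not present in corpus")
    if mode not in COUNT_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    seqs = _keyword_token_seqs(lexicon, category, tokenizer)
    if not seqs:
        raise ValueError(f"category {category!r} has no keywords in the lexicon")
    if corpus.window is None:
        raise ValueError("corpus has no window (empty corpus)")
    counts = {m: 0 for m in month_range(*corpus.window)}
    for d in corpus.documents:
        if d.stream != stream:
            continue
        n = _count_matches(d, seqs)
        if mode == "document":
            counts[d.month] += 1 if n > 0 else 0
        else:
            counts[d.month] += n
    return MonthlySeries(stream, category, counts, corpus.window)


def growth(series: MonthlySeries, window_len: int = 4) -> GrowthSeries:
    """Relative increase of each month over the mean of the preceding window.

    growth(t) = (count(t) - m) / m with m the exact (unrounded) mean of the
    ``window_len`` preceding counts; undefined when the history is
    incomplete or m = 0.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    months = series.months
    if len(months) < window_len + 1:
        raise ValueError(
            f"series has {len(months)} months; needs at least {window_len + 1}"
        )
    values: dict[str, float] = {}
    for i in range(window_len, len(months)):
        window = [series.counts[months[j]] for j in range(i - window_len, i)]
        m = sum(window) / window_len
        if m == 0:
            continue
        values[months[i]] = (series.counts[months[i]] - m) / m
    return GrowthSeries(
        series.stream, series.category, values, series.window, window_len
    )


def detect_outliers(
    gs: GrowthSeries, k: float = 2.0, max_fraction: float = 0.2
) -> GrowthSeries:
    """Flag exceptionally large growth values as excluded.

    Iteratively excludes the maximum defined growth value while it exceeds
    mean + k*SD (sample SD) of the *remaining* defined values, up to
    ceil(max_fraction * n) exclusions. Returns a new series; the input is
    unchanged.
    """
    defined = {m: v for m, v in gs.values.items() if m not in gs.excluded}
    if len(defined) < 3:
        raise ValueError("outlier detection needs at least 3 defined growth values")
    cap = math.ceil(max_fraction * len(defined))
    excluded = dict(gs.excluded)
    remaining = dict(defined)
    while len(excluded) - len(gs.excluded) < cap and len(remaining) >= 3:
        m_star = max(remaining, key=lambda m: (remaining[m], m))
        rest = [v for m, v in remaining.items() if m != m_star]
        mu = float(np.mean(rest))
        sd = float(np.std(rest, ddof=1))
        if remaining[m_star] > mu + k * sd:
            excluded[m_star] = (
                f"exceptional growth: {remaining[m_star]:.4g} > "
                f"mean {mu:.4g} + {k:g}*SD {sd:.4g} of remaining values"
            )
            del remaining[m_star]
        else:
            break
    return replace(gs, excluded=excluded)


# ---------------------------------------------------------------------------
# CSV import/export

def export_series(series: MonthlySeries | GrowthSeries, path: str) -> None:
    """Write a series as CSV: month, value, excluded; metadata in # comments.

    Undefined growth months appear with an empty value field; the file
    round-trips losslessly through the matching reader.
    """
    is_growth = isinstance(series, GrowthSeries)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# stream: {series.stream}\n")
        fh.write(f"# category: {series.category}\n")
        if is_growth:
            fh.write(f"# window_len: {series.window_len}\n")
        w = csv.writer(fh)
        w.writerow(["month", "value", "excluded"])
        for m in month_range(*series.window):
            if is_growth:
                v = series.values.get(m)
                value = "" if v is None else repr(v)
                flag = "true" if m in series.excluded else ("" if v is None else "false")
            else:
                value = str(series.counts[m])
                flag = ""
            w.writerow([m, value, flag])


def _read_rows(path: str) -> tuple[dict[str, str], list[list[str]]]:
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line.strip():
                rows.append(next(csv.reader([line])))
    if rows and rows[0][:2] == ["month", "value"]:
        rows = rows[1:]
    return meta, rows


def read_monthly_series(path: str) -> MonthlySeries:
    meta, rows = _read_rows(path)
    counts = {r[0]: int(r[1]) for r in rows}
    months = sorted(counts)
    return MonthlySeries(
        meta.get("stream", ""), meta.get("category", ""), counts,
        (months[0], months[-1]),
    )


def read_growth_series(path: str) -> GrowthSeries:
    meta, rows = _read_rows(path)
    months = sorted(r[0] for r in rows)
    values = {r[0]: float(r[1]) for r in rows if r[1] != ""}
    excluded = {r[0]: "excluded (from file)" for r in rows if len(r) > 2 and r[2] == "true"}
    return GrowthSeries(
        meta.get("stream", ""), meta.get("category", ""), values,
        (months[0], months[-1]), int(meta.get("window_len", 4)), excluded,
    )
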