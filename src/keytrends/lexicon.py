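"""Keyword category lexicons, two-rater labeling, and chance-corrected agreement.

Keyword classification into positive / neutral / negative is a curated
input (expert judgment), not an automated sentiment step. Two raters label
the same keyword set independently; agreement is summarized by unweighted
Cohen's kappa and discordant items are settled by a designated final rater.

The bundled ``hpv_lexicon.csv`` fixture is the 13-keyword HPV-vaccination
media lexicon (4 positive, 5 neutral, 4 negative; the anti-vaccination
attorney's name is stored as the literal placeholder
``"[an attorney's name]"``).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

logger = logging.getLogger(__name__)

CATEGORIES = ("positive", "neutral", "negative")


@dataclass(frozen=True)
class Lexicon:
    """Mapping keyword -> category, categories restricted to CATEGORIES."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for kw, cat in self.entries.items():
            if not kw:
                raise ValueError("empty keyword")
            if cat not in CATEGORIES:
                raise ValueError(f"invalid category {cat!r} for keyword {kw!r}")

    def keywords(self, category: str | None = None) -> list[str]:
        if category is None:
            return sorted(self.entries)
        if category not in CATEGORIES:
            raise ValueError(f"invalid category {category!r}")
        return sorted(k for k, c in self.entries.items() if c == category)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class RaterLabels:
    rater_id: str
    labels: dict[str, str]

    def __post_init__(self) -> None:
        for kw, cat in self.labels.items():
            if cat not in CATEGORIES:
                raise ValueError(f"invalid category {cat!r} for keyword {kw!r}")


@dataclass(frozen=True)
class AgreementReport:
    """Cohen's kappa with its observed agreement and 3x3 confusion table."""

    kappa: float
    observed_agreement: float
    confusion: tuple[tuple[int, ...], ...]  # rows: rater a, cols: rater b
    n_items: int


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def load_lexicon(path: str) -> Lexicon:
    """Load a keyword,category CSV/TSV file into a :class:`Lexicon`.

    A header row naming the two columns is optional. Duplicate keywords with
    conflicting categories and invalid categories raise with the row named.
    """
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh]
    if not any(ln.strip() for ln in lines):
        logger.warning("lexicon file %s is empty", path)
        return Lexicon({})
    delim = _sniff_delimiter(next(ln for ln in lines if ln.strip()))
    for i, row in enumerate(csv.reader(lines, delimiter=delim), start=1):
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) < 2:
            raise ValueError(f"{path}: row {i}: expected keyword and category")
        kw, cat = row[0].strip(), row[1].strip().lower()
        if i == 1 and cat not in CATEGORIES and kw.lower() == "keyword":
            continue  # header row
        if cat not in CATEGORIES:
            raise ValueError(f"{path}: row {i}: invalid category {cat!r}")
        if kw in entries and entries[kw] != cat:
            raise ValueError(
                f"{path}: row {i}: keyword {kw!r} already labeled {entries[kw]!r}"
            )
        entries[kw] = cat
    return Lexicon(entries)


def save_lexicon(lexicon: Lexicon, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["keyword", "category"])
        for kw in sorted(lexicon.entries):
            w.writerow([kw, lexicon.entries[kw]])


def hpv_lexicon() -> Lexicon:
    """The bundled 13-keyword HPV-vaccination media lexicon."""
    ref = resources.files("keytrends.data").joinpath("hpv_lexicon.csv")
    with resources.as_file(ref) as p:
        return load_lexicon(str(p))


def load_rater_labels(path: str, rater_id: str) -> RaterLabels:
    """Load a rater's keyword,category file (same format as a lexicon)."""
    return RaterLabels(rater_id, dict(load_lexicon(path).entries))


def _check_same_items(a: RaterLabels, b: RaterLabels) -> list[str]:
    sa, sb = set(a.labels), set(b.labels)
    if sa != sb:
        diff = sorted(sa ^ sb)
        raise ValueError(f"raters labeled different keyword sets; difference: {diff}")
    return sorted(sa)


def cohen_kappa(a: RaterLabels, b: RaterLabels) -> AgreementReport:
    """Unweighted Cohen's kappa over the three categories.

    kappa = (p_o - p_e) / (1 - p_e), with p_e the chance agreement implied
    by the two raters' marginal label proportions. In the degenerate case
    p_e = 1 (both raters constant), kappa is defined as 1 when agreement is
    perfect.
    """
    items = _check_same_items(a, b)
    n = len(items)
    if n < 2:
        raise ValueError("kappa needs at least 2 items")
    idx = {c: i for i, c in enumerate(CATEGORIES)}
    confusion = np.zeros((3, 3), dtype=int)
    for kw in items:
        confusion[idx[a.labels[kw]], idx[b.labels[kw]]] += 1
    p_o = float(np.trace(confusion)) / n
    marg_a = confusion.sum(axis=1) / n
    marg_b = confusion.sum(axis=0) / n
    p_e = float(marg_a @ marg_b)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementReport(
        kappa=float(kappa),
        observed_agreement=p_o,
        confusion=tuple(tuple(int(x) for x in row) for row in confusion),
        n_items=n,
    )


def adjudicate(a: RaterLabels, b: RaterLabels, final_rater: str) -> Lexicon:
    """Merge two labelings: agreed items keep the shared label, discordant
    items take the final rater's label (and are logged)."""
    if final_rater not in (a.rater_id, b.rater_id):
        raise ValueError(
            f"final_rater {final_rater!r} is neither {a.rater_id!r} nor {b.rater_id!r}"
        )
    items = _check_same_items(a, b)
    final = a if final_rater == a.rater_id else b
    entries: dict[str, str] = {}
    for kw in items:
        if a.labels[kw] == b.labels[kw]:
            entries[kw] = a.labels[kw]
        else:
            entries[kw] = final.labels[kw]
            logger.info(
                "discordant keyword %r: %s=%s, %s=%s -> %s",
                kw, a.rater_id, a.labels[kw], b.rater_id, b.labels[kw], entries[kw],
            )
    return Lexicon(entries)
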