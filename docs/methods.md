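# Methods

This note records the models implemented in `keytrends`, the assumptions
behind them, the defaults that matter, and what the synthetic data do and
do not establish.

## Corpus model and tokenization

A corpus is a set of documents, each carrying a unique id, a stream label
(e.g. `newspaper`, `web`), a calendar month, and tokenized text. All
analysis is monthly; dates finer than a month are truncated on input,
because every downstream statistic (counts, growth, correlation) is a
monthly tally. Both newspaper articles and web pages are modelled as
documents distinguished only by their stream label; web volume is treated
as a document count, not a search-engine hit estimate, since hit totals
are opaque estimates rather than enumerable units.

The shipped tokenizer is delimiter-based: sentences split on
`.!?` (plus CJK equivalents) and newlines, tokens on whitespace and
punctuation, lowercased, with optional stopword and minimum-length
filters. Languages without delimiter-separated words (the motivating
corpora were Japanese) need pre-segmented text or an external morphological
tokenizer producing space-separated tokens; the core is deliberately
language-agnostic. Documents that tokenize to nothing are kept with zero
sentences — they remain countable documents but contribute nothing to
keyword statistics.

Keyword matching (see below) normalizes lexicon keywords with the same
tokenizer as the documents, so matching happens in one token space and
generated corpora survive a write/read round trip unchanged.

## KeyGraph

KeyGraph extracts keywords from a corpus as a co-occurrence graph built in
three stages over sentence-level counts:

- **Black nodes**: the `n_black_nodes` terms with the highest total
  occurrence count (default 30).
- **Black links**: between black nodes, the association of terms *i*, *j*
  is `Σ_s min(count(i, s), count(j, s))` over sentences *s*; the
  `n_black_links` strongest pairs are kept (default 20). Connected
  components of the linked nodes are the clusters ("foundations").
- **Red nodes / key scores**: for any term *w* and cluster *g*,
  `based(w, g) = Σ_s count(w, s) · count(g∖w, s)` and
  `neighbors(g) = Σ_w based(w, g)`;
  `key(w) = 1 − ∏_g (1 − based(w, g)/neighbors(g))`, a probability-like
  measure in [0, 1] of touching the corpus's foundations. A cluster with
  `neighbors = 0` contributes a neutral factor. The `n_red_nodes` top
  non-black terms with strictly positive key scores become red nodes
  (default 10). This is the canonical KeyGraph formulation; variants that
  prune candidates differently exist, and the classical "touches ≥ 2
  clusters" keyword criterion is retained as a per-node *bridging flag*
  rather than a filter so that the configured red-node count is honored
  exactly and testable.
- **Red links** connect each red node to its highest-association black
  node in every cluster it touches.

All orderings break ties deterministically (count, then document
frequency, then lexicographic; pairs lexicographically), so results are
identical across platforms and document orderings. The co-occurrence unit
is the sentence, not the document — documents may be long, and
sentence-level co-occurrence is the standard granularity for KeyGraph.

Cluster detection and GraphML export use networkx; the DOT emitter is a
small writer for the plain-text DOT syntax; the JSON export round-trips
the full result losslessly.

## Category lexicon and agreement

Keyword polarity (positive / neutral / negative with respect to promotion
of vaccination) is a curated input, mirroring expert manual
classification — not an automated sentiment model. The bundled lexicon has
13 keywords: 4 positive (public expense, subsidy, signature campaign,
recruitment), 5 neutral (vaccine, screening, cervarix, prevention,
vaccination), 4 negative (side effect, infertility, danger, and a redacted
anti-vaccination attorney's name stored as the literal placeholder
`[an attorney's name]`).

Two-rater agreement is unweighted Cohen's kappa over the three categories,
`κ = (p_o − p_e)/(1 − p_e)` with `p_e` from the raters' marginal label
proportions; no category distance is assumed, so weighting would be
arbitrary. The degenerate case `p_e = 1` (both raters constant and
agreeing) is defined as κ = 1. Kappa is computed over whatever item set is
supplied; it is the caller's choice whether rejected candidate keywords
are included. Discordant items are settled by a designated final rater and
logged.

## Monthly counts and growth

`count_x(t)` is, in the default *document* mode, the number of documents
in a stream-month containing at least one keyword of category *x*
(multi-word keywords match consecutive tokens within a sentence,
case-insensitively); *occurrence* mode counts every match instead.
Document mode is the default because published media-trend figures count
articles containing keywords, not keyword tokens. Months with no documents
count 0 — the series is dense, never missing.

The growth statistic is
`growth_x(t) = (count_x(t) − m)/m`, `m` = exact (unrounded) mean of the
`window_len` preceding months (default 4, chosen to smooth out
short-period fluctuation). Growth is undefined for the first `window_len`
months and wherever `m = 0`; undefined months are deleted pairwise
downstream rather than imputed, which is why a correlation over a
19-month window starts at its fifth month.

**Outlier rule.** Exceptional growth months are excluded by a formalized,
reproducible rule: iteratively flag the maximum defined value while it
exceeds mean + k·SD (sample SD) of the remaining defined values, with
k = 2 by default and a hard cap of ⌈20%⌉ of the defined points. On a
background of dispersion ≈1.2 this excludes a value near 4 while leaving
the next-largest value near 2.4 in place. Because the rule is a greedy
maximum-grab on right-skewed values, it can flag genuine surge months on
noisy small-count series; the cap bounds the damage, and every exclusion
records the comparison numbers in its reason string.

## Staggered correlation

For stagger dt = 0..dt_max, pairs `(a(t), b(t − dt))` are formed over all
months where both growth values are defined and neither is excluded
(pairwise deletion per dt; window edges truncate — no wraparound). Pearson
r is computed where at least `min_pairs` pairs exist with non-degenerate
variance; `best_dt` is the evaluable dt with maximal r, ties to the
smaller dt. Only non-negative dt is scanned by default, matching the
`b(t − dt)` construction; a symmetric scan is available via
`include_negative`. No significance test is attached — the statistic is a
descriptive measure of covariation and implies no causal direction.

The library default `min_pairs = 3` is a hard floor; the pipeline default
is 8, because on a ~19-month study a correlation computed from a handful
of pairs is noise and would otherwise dominate the argmax at large dt.

## Synthetic data

The generator emulates the statistical structure of a two-stream media
corpus, not its language: background text is Zipf-distributed token soup
(default vocabulary 200, exponent 1.3), since counting and co-occurrence
operate on tokens. Each document draws 1–5 sentences of 5–10 tokens; for
each (stream, category) with a configured injection, one keyword of the
category is appended to a random sentence with probability
`baseline · burst(month)`, clipped to [0, 1].

Cross-stream coupling adds `gain ×` the *realized* source coverage
fraction (the share of source-stream documents that actually received a
source-category keyword) at `t − lag`. Coupling through the realization
rather than the expectation is deliberate: a reacting stream responds to
what was actually printed, and it transmits the source's month-to-month
sampling fluctuations to the target, producing the strong zero-lag
covariation seen in real coupled streams. Streams are generated in
dependency order (cyclic stream couplings are rejected). All randomness
flows from one seed through per-(stream, month) substreams keyed by a CRC
of the stream name, so adding a stream leaves other streams' draws
untouched.

Two stock configurations:

- `study_params(seed)` — 19 months (2009-01..2010-07). Newspaper: ~625
  expected articles, flat at 20/month through 2009 and surging to an
  80-article June 2010 peak; positive coverage fluctuates around a 0.20
  baseline in 2009 (ordinary news-cycle variation, background growth
  dispersion near 1), jumps exceptionally in January 2010 (expected growth
  ≈ 4), sits near 17 expected positive articles in February–April and 47
  in May — so the May growth statistic lands at ≈ 30/17. Web: 120
  documents/month with gradually ramping coverage in all categories, its
  negative coverage additionally driven by newspaper positive coverage at
  zero lag with gain 0.5.
- `coupled_pair_params(lag, seed)` — a 24-month lag-recovery setup: a
  strongly bursty source (low-autocorrelation burst profile) driving a
  quiet target at the injected lag with gain 1.

What passing tests on these data show: the counting, growth, exclusion and
staggering machinery recovers known injected structure (burst months, lag,
categories) from realistic sampling noise. What they do not show: anything
about natural-language effects — topic drift, synonymy, segmentation
errors in real Japanese text, or search-engine hit-count dynamics — none
of which the generator models.

## Numerical and design choices

- Months are plain `"YYYY-MM"` strings with integer index arithmetic;
  no timezone or day semantics exist anywhere.
- Growth uses exact means; no rounding is applied to the denominator.
- Sample SD (ddof = 1) in the outlier rule; equal values are never
  excluded (the comparison is strict).
- Pearson r delegates to `scipy.stats.pearsonr` after explicit
  length/variance validation; zero-variance sequences raise rather than
  returning NaN.
- All pipeline file writes are atomic (temp file + rename); outputs are
  byte-reproducible for a fixed config and seed (JSON keys sorted, CSV
  field order fixed). The run report echoes the effective config verbatim;
  its timestamp is the only non-reproducible field.
- Errors name the offending record, row, field or stage.

## Problem sizes

Default test and acceptance runs use the stock configurations above:
synthetic study corpora of ~2,900 documents, lag-recovery batches of 100
simulations per lag at 24 months × 60 documents/month per stream, and
Monte-Carlo checks of 100–200 seeds on small flat corpora. These sizes
give stable statistics for every property tested while keeping a full run
in the low tens of seconds.

## Known limitations

- The argmax `best_dt` on a single 19-month realization is noisy when the
  outlier rule removes surge months; the generator's coupled-pair
  configuration, not the study configuration, is the appropriate testbed
  for lag recovery.
- The outlier rule is greedy and distribution-agnostic; on heavy-tailed
  growth it can exclude up to its cap. A robust (e.g. MAD-based) variant
  is not provided.
- Document-mode counting saturates: a category appearing in every document
  of a month cannot register further increase.
- The tokenizer does no stemming, normalization beyond lowercasing, or
  language detection.
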