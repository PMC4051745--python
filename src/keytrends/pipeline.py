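"""End-to-end orchestration: corpus -> keyword graph -> lexicon counts ->
growth -> outlier exclusion -> staggered correlation.

The pipeline mirrors the separable stages of a media-review analysis and
writes every intermediate artifact (graph files, agreement report, series
and growth CSVs, correlation tables) plus a provenance report into one
output directory. All file writes are atomic (temp file + rename) so a
failed run never leaves a truncated artifact behind.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from datetime import datetime, timezone

import yaml

from . import __version__
from .corpus_io import Corpus, TokenizerConfig, filter_window, read_corpus, write_corpus
from .keygraph import KeyGraphConfig, export_graph, run_keygraph
from .lexicon import (
    CATEGORIES,
    cohen_kappa,
    hpv_lexicon,
    load_lexicon,
    load_rater_labels,
)
from .lagcorr import export_lagcorr_csv, export_lagcorr_json, staggered_correlation
from .synthetic import generate_corpus, study_params
from .trend import detect_outliers, export_series, growth, monthly_counts


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    ``corpus_paths`` maps stream labels to JSONL/CSV corpus files; when
    empty, a synthetic study corpus is generated from ``seed``. The
    correlation compares growth of (``corr_a_stream``, ``corr_a_category``)
    against the lagged growth of (``corr_b_stream``, ``corr_b_category``).
    """

    out_dir: str = "keytrends_out"
    corpus_paths: dict[str, str] = field(default_factory=dict)
    window: tuple[str, str] | None = None
    lexicon_path: str | None = None  # None -> bundled HPV lexicon
    rater_a_path: str | None = None
    rater_b_path: str | None = None
    final_rater: str = "rater_a"
    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)
    keygraph: KeyGraphConfig = field(default_factory=KeyGraphConfig)
    count_mode: str = "document"
    growth_window: int = 4
    outlier_k: float = 2.0
    dt_max: int = 6
    # correlations on a handful of month pairs are noise; for a ~19-month
    # study require a more substantial overlap than the library minimum
    min_pairs: int = 8
    corr_a_stream: str = "newspaper"
    corr_a_category: str = "positive"
    corr_b_stream: str = "web"
    corr_b_category: str = "negative"
    seed: int = 0

    def validate(self) -> None:
        for stream, path in self.corpus_paths.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"corpus file for stream {stream!r}: {path}")
        if self.lexicon_path is not None and not os.path.exists(self.lexicon_path):
            raise FileNotFoundError(f"lexicon file: {self.lexicon_path}")
        for p in (self.rater_a_path, self.rater_b_path):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"rater label file: {p}")
        if self.count_mode not in ("document", "occurrence"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")
        if self.growth_window < 1 or self.dt_max < 0 or self.min_pairs < 2:
            raise ValueError("growth_window, dt_max or min_pairs out of range")


def load_config(path: str, **overrides) -> PipelineConfig:
    """Load a YAML config file; keyword overrides win over file values."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "window" in raw and raw["window"] is not None:
        raw["window"] = tuple(raw["window"])
    if "tokenizer" in raw and isinstance(raw["tokenizer"], dict):
        tok = dict(raw["tokenizer"])
        if "stopwords" in tok:
            tok["stopwords"] = frozenset(tok["stopwords"])
        raw["tokenizer"] = TokenizerConfig(**tok)
    if "keygraph" in raw and isinstance(raw["keygraph"], dict):
        raw["keygraph"] = KeyGraphConfig(**raw["keygraph"])
    return PipelineConfig(**raw)


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["tokenizer"]["stopwords"] = sorted(d["tokenizer"]["stopwords"])
    if d["window"] is not None:
        d["window"] = list(d["window"])
    return d


def _atomic_write(path: str, writer) -> None:
    """Run ``writer(tmp_path)`` then atomically rename onto ``path``."""
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


@dataclass(frozen=True)
class RunReport:
    outputs: dict[str, str]  # artifact name -> path
    config: dict
    version: str
    timestamp: str
    stages: tuple[str, ...]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _load_corpus(config: PipelineConfig) -> tuple[Corpus, dict | None]:
    if config.corpus_paths:
        docs = []
        for stream in sorted(config.corpus_paths):
            sub = read_corpus(config.corpus_paths[stream], tokenizer=config.tokenizer)
            docs.extend(
                dataclasses.replace(d, stream=stream) for d in sub.documents
            )
        return Corpus(tuple(docs)), None
    params = study_params(seed=config.seed)
    return generate_corpus(params)


def run_full(config: PipelineConfig) -> RunReport:
    """Execute all stages in order; any failure aborts with the stage named."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)
    outputs: dict[str, str] = {}
    stages: list[str] = []

    def stage(name: str):
        stages.append(name)
        return name

    # --- corpus ---
    name = stage("corpus")
    try:
        corpus, truth = _load_corpus(config)
        if config.window is not None:
            corpus = filter_window(corpus, *config.window)
        _atomic_write(out("corpus.jsonl"), lambda p: write_corpus(corpus, p))
        outputs["corpus"] = out("corpus.jsonl")
        if truth is not None:
            _atomic_write(
                out("ground_truth.json"),
                lambda p: _dump_json(truth, p),
            )
            outputs["ground_truth"] = out("ground_truth.json")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(name, exc) from exc

    # --- keyword extraction ---
    name = stage("keygraph")
    try:
        kg = run_keygraph(corpus, config.keygraph)
        for fmt, fname in (("graphml", "keygraph.graphml"), ("json", "keygraph.json"),
                           ("dot", "keygraph.dot")):
            _atomic_write(out(fname), lambda p, f=fmt: export_graph(kg, f, p))
            outputs[f"keygraph_{fmt}"] = out(fname)
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- classification / agreement ---
    name = stage("classification")
    try:
        lexicon = (
            load_lexicon(config.lexicon_path) if config.lexicon_path else hpv_lexicon()
        )
        if config.rater_a_path and config.rater_b_path:
            a = load_rater_labels(config.rater_a_path, "rater_a")
            b = load_rater_labels(config.rater_b_path, "rater_b")
            report = cohen_kappa(a, b)
            _atomic_write(
                out("agreement.json"),
                lambda p: _dump_json(
                    {
                        "kappa": report.kappa,
                        "observed_agreement": report.observed_agreement,
                        "confusion": [list(r) for r in report.confusion],
                        "n_items": report.n_items,
                        "categories": list(CATEGORIES),
                    },
                    p,
                ),
            )
            outputs["agreement"] = out("agreement.json")
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- monthly counting, growth, outliers ---
    name = stage("trend")
    growth_series = {}
    try:
        for stream in sorted(corpus.streams):
            for cat in CATEGORIES:
                series = monthly_counts(
                    corpus, lexicon, stream, cat, config.count_mode,
                    config.tokenizer,
                )
                fname = f"counts_{stream}_{cat}.csv"
                _atomic_write(out(fname), lambda p, s=series: export_series(s, p))
                outputs[f"counts_{stream}_{cat}"] = out(fname)
                gs = detect_outliers(
                    growth(series, config.growth_window), config.outlier_k
                )
                growth_series[(stream, cat)] = gs
                fname = f"growth_{stream}_{cat}.csv"
                _atomic_write(out(fname), lambda p, s=gs: export_series(s, p))
                outputs[f"growth_{stream}_{cat}"] = out(fname)
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- staggered correlation ---
    name = stage("lagcorr")
    try:
        a = growth_series[(config.corr_a_stream, config.corr_a_category)]
        b = growth_series[(config.corr_b_stream, config.corr_b_category)]
        lc = staggered_correlation(a, b, config.dt_max, config.min_pairs)
        _atomic_write(out("lagcorr.csv"), lambda p: export_lagcorr_csv(lc, p))
        _atomic_write(out("lagcorr.json"), lambda p: export_lagcorr_json(lc, p))
        outputs["lagcorr_csv"] = out("lagcorr.csv")
        outputs["lagcorr_json"] = out("lagcorr.json")
    except Exception as exc:
        raise StageError(name, exc) from exc

    report = RunReport(
        outputs=outputs,
        config=_config_echo(config),
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        stages=tuple(stages),
    )
    _atomic_write(
        out("report.json"),
        lambda p: _dump_json(
            {
                "outputs": report.outputs,
                "config": report.config,
                "version": report.version,
                "timestamp": report.timestamp,
                "stages": list(report.stages),
            },
            p,
        ),
    )
    return report


def _dump_json(obj, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
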