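"""Staggered-lag Pearson correlation between two growth series.

For each stagger dt in 0..dt_max, pairs (a(t), b(t - dt)) are formed over
every month t where both values are defined and neither month is excluded
(pairwise deletion per dt; no wraparound at the window edges). The dt
maximizing r locates the temporal offset of covariation between the two
media streams; no significance test is attached, and no causal reading is
implied.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .months import month_add
from .trend import GrowthSeries


@dataclass(frozen=True)
class LagCorrResult:
    """Per-dt Pearson r and pair counts; ``r`` is None where not evaluable."""

    records: dict[int, tuple[float | None, int]]
    best_dt: int
    dt_range: tuple[int, int]

    def r(self, dt: int) -> float | None:
        return self.records[dt][0]

    def n_pairs(self, dt: int) -> int:
        return self.records[dt][1]


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("sequences must be one-dimensional and equal-length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate sequence: zero variance")
    return float(sps.pearsonr(x, y).statistic)


def _pairs(a: GrowthSeries, b: GrowthSeries, dt: int) -> tuple[list[float], list[float]]:
    xs, ys = [], []
    for t in a.defined_months():
        t_lag = month_add(t, -dt)
        if t_lag in b.values and t_lag not in b.excluded:
            xs.append(a.values[t])
            ys.append(b.values[t_lag])
    return xs, ys


def staggered_correlation(
    a: GrowthSeries,
    b: GrowthSeries,
    dt_max: int,
    min_pairs: int = 3,
    include_negative: bool = False,
) -> LagCorrResult:
    """Scan Pearson r over staggers dt = 0..dt_max (b lagging behind a).

    A dt with fewer than ``min_pairs`` usable pairs, or with a degenerate
    (zero-variance) pair sequence, is recorded as not evaluable (r = None).
    ``best_dt`` is the evaluable dt with the largest r, ties going to the
    smallest dt. With ``include_negative`` the scan also covers
    dt = -dt_max..-1 (a lagging behind b).
    """
    if dt_max < 0:
        raise ValueError("dt_max must be >= 0")
    dts = list(range(-dt_max, dt_max + 1)) if include_negative else list(range(dt_max + 1))
    records: dict[int, tuple[float | None, int]] = {}
    for dt in dts:
        xs, ys = _pairs(a, b, dt)
        if len(xs) < min_pairs or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            records[dt] = (None, len(xs))
        else:
            records[dt] = (pearson(xs, ys), len(xs))
    evaluable = [dt for dt in dts if records[dt][0] is not None]
    if not evaluable:
        raise ValueError("no evaluable stagger: too few usable month pairs at every dt")
    best_dt = min(evaluable, key=lambda dt: (-records[dt][0], dt))
    return LagCorrResult(records, best_dt, (dts[0], dts[-1]))


def export_lagcorr_csv(result: LagCorrResult, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dt", "r", "n_pairs"])
        for dt in sorted(result.records):
            r, n = result.records[dt]
            w.writerow([dt, "" if r is None else repr(r), n])


def export_lagcorr_json(result: LagCorrResult, path: str) -> None:
    payload = {
        "best_dt": result.best_dt,
        "best_r": result.records[result.best_dt][0],
        "dt_range": list(result.dt_range),
        "records": {
            str(dt): {"r": r, "n_pairs": n}
            for dt, (r, n) in sorted(result.records.items())
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
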