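"""Cohort distribution summaries and per-entry percentile contextualization.

Quantiles use linear interpolation between closest order statistics (the
"type 7" convention, numpy's default); variance uses the n−1 denominator;
percentile ranks use mid-rank treatment of ties. These conventions are
echoed in output metadata rather than asserted to match any archive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classification import AXES, CategoryLabels
from .curation import MetricRecord

__all__ = [
    "CohortSummary",
    "PercentileContext",
    "summarize",
    "percentile_of",
    "central_interval",
    "category_table",
    "histogram_counts",
    "DEFAULT_BIN_WIDTHS",
]

QUANTILE_METHOD = "linear"  # numpy name for the type-7 convention

DEFAULT_BIN_WIDTHS = {
    "r_factor": 0.005,
    "wr_factor": 0.005,
    "goof": 0.01,
    "theta_max": 1.0,
    "d": 0.01,
    "rho_max": 0.05,
    "rho_min": 0.05,
    "shift_su": 0.001,
}


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean: float
    variance: float
    sd: float
    minimum: float
    p10: float
    lower_quartile: float
    median: float
    upper_quartile: float
    p90: float
    maximum: float

    def __post_init__(self):
        order = (self.minimum, self.p10, self.lower_quartile, self.median,
                 self.upper_quartile, self.p90, self.maximum)
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("quantile ordering violated")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def to_metadata() -> dict:
        return {"quantile_method": QUANTILE_METHOD, "variance_denominator": "n-1",
                "tie_treatment": "mid-rank"}


def summarize(values: Sequence[float] | np.ndarray) -> CohortSummary:
    """Full distribution summary of accepted values (n ≥ 1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("summarize requires at least one value")
    q = np.quantile(arr, [0.10, 0.25, 0.50, 0.75, 0.90], method=QUANTILE_METHOD)
    var = float(np.var(arr, ddof=1)) if arr.size > 1 else 0.0
    return CohortSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        variance=var,
        sd=math.sqrt(var),
        minimum=float(arr.min()),
        p10=float(q[0]),
        lower_quartile=float(q[1]),
        median=float(q[2]),
        upper_quartile=float(q[3]),
        p90=float(q[4]),
        maximum=float(arr.max()),
    )


def percentile_of(value: float, cohort: Sequence[float] | np.ndarray) -> float:
    """Percentile rank of ``value`` in ``cohort`` (0-100, mid-rank ties)."""
    arr = np.asarray(cohort, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile_of requires a non-empty cohort")
    below = int(np.count_nonzero(arr < value))
    equal = int(np.count_nonzero(arr == value))
    return 100.0 * (below + 0.5 * equal) / arr.size


@dataclass(frozen=True)
class PercentileContext:
    """Slider-style contextualization of one value against a reference cohort."""

    metric: str
    value: float
    rank: float
    cohort_n: int

    def __post_init__(self):
        if not 0.0 <= self.rank <= 100.0:
            raise ValueError("rank outside [0, 100]")


def central_interval(
    values: Sequence[float] | np.ndarray, coverage: float
) -> tuple[float, float]:
    """Equal-tailed central interval, e.g. coverage 0.8 → (p10, p90)."""
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("central_interval requires values")
    lo, hi = np.quantile(arr, [(1 - coverage) / 2, (1 + coverage) / 2],
                         method=QUANTILE_METHOD)
    return float(lo), float(hi)


_TABLE_COLUMNS = ["axis", "level", "n", "mean", "variance", "sd", "minimum",
                  "p10", "lower_quartile", "median", "upper_quartile", "p90",
                  "maximum"]


def category_table(
    records: Sequence[MetricRecord],
    labels: Sequence[CategoryLabels],
    metric: str,
) -> pd.DataFrame:
    """Per-category cohort summaries of one metric field.

    One row per level of every axis plus an "all" row; an entry counts on
    every axis it is classified on, so axis n's sum to the total per axis
    but must never be summed across axes.
    """
    by_id = {l.identifier: l for l in labels}
    if set(by_id) != {r.identifier for r in records}:
        raise ValueError("records and labels are not aligned by identifier")
    values: dict[tuple[str, str], list[float]] = {}
    all_vals: list[float] = []
    for rec in records:
        v = getattr(rec, metric)
        lab = by_id[rec.identifier]
        for axis in AXES:
            key = (axis, lab.axis_value(axis))
            values.setdefault(key, [])
            if v is not None:
                values[key].append(v)
        if v is not None:
            all_vals.append(v)
    rows = []

    def _row(axis, level, vals):
        if vals:
            d = summarize(vals).to_dict()
        else:
            d = {c: float("nan") for c in _TABLE_COLUMNS[3:]}
            d["n"] = 0
        d.update(axis=axis, level=level)
        return d

    rows.append(_row("all", "all", all_vals))
    for axis, levels in AXES.items():
        for level in levels:
            rows.append(_row(axis, level, values.get((axis, level), [])))
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def histogram_counts(
    values: Sequence[float] | np.ndarray, bin_width: float
) -> pd.DataFrame:
    """Fixed-width bin counts anchored at 0, as (bin_left, bin_right, count)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or bin_width <= 0:
        raise ValueError("histogram_counts requires values and a positive width")
    lo = math.floor(arr.min() / bin_width)
    hi = math.floor(arr.max() / bin_width) + 1
    edges = np.arange(lo, hi + 1) * bin_width
    counts, _ = np.histogram(arr, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
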