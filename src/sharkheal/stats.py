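"""Per-injury healing descriptors.

Percent healed at sighting *i* compares the anchor-normalized wound extent
with its day-0 value:

    percent_healed_i = 100 − 100 · (a_i / a_mi) / (a_0 / a_m0)

where a is the wound extent and a_m the anchor extent in the same image. It
is 0 on day 0 by construction, 100 at full closure, and negative if the
wound grew. The inter-sighting healing rate is the first difference of
percent healed over elapsed days,

    y_i = (percent_healed_i − percent_healed_{i−1}) / (t_i − t_{i−1}),

in %/day, defined for consecutive sightings only (no smoothing). Summed
against the elapsed-day gaps the rates telescope back to the final percent
healed exactly.

For severed appendages that fuse rather than close there is no standard
closure endpoint, so reattachment is tracked linearly: the percentage of the
originally severed length that has re-fused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .annotations import HealingSeries
from .errors import DegenerateBaselineError, InsufficientDataError, OrderingError, RangeError

__all__ = [
    "RateObservation",
    "percent_healed",
    "intersighting_rate",
    "logit_proportion",
    "reattachment_percent",
    "rates_frame",
    "LOGIT_EPS",
]

Metric = Literal["area", "perimeter"]

#: Clamp bound for the logit transform; keeps day-0 (p=0) and fully healed
#: (p=1) proportions finite when they survive the exclusion rules.
LOGIT_EPS = 1e-3


@dataclass(frozen=True)
class RateObservation:
    """Percent healed and inter-sighting rate at one sighting (i >= 1)."""

    day_offset: int
    percent_healed: float
    rate: float


def _ratio(series: HealingSeries, i: int, metric: Metric) -> float:
    m = series.measurements[i]
    return m.area_ratio if metric == "area" else m.perimeter_ratio


def percent_healed(series: HealingSeries, i: int, metric: Metric = "area") -> float:
    """Percent of the day-0 extent closed by sighting *i* (negative if grown)."""
    baseline = _ratio(series, 0, metric)
    if baseline <= 0.0:
        raise DegenerateBaselineError(
            f"{series.injury_id}: day-0 {metric} ratio is {baseline}"
        )
    return 100.0 - 100.0 * _ratio(series, i, metric) / baseline


def intersighting_rate(
    series: HealingSeries, metric: Metric = "area"
) -> list[RateObservation]:
    """Rate of change of percent healed between consecutive sightings (%/day)."""
    if len(series) < 2:
        raise InsufficientDataError(
            f"{series.injury_id}: rate needs >=2 sightings, got {len(series)}"
        )
    days = series.day_offsets
    if any(b <= a for a, b in zip(days, days[1:])):
        raise OrderingError(f"{series.injury_id}: day offsets not strictly increasing")
    out = []
    prev = percent_healed(series, 0, metric)
    for i in range(1, len(series)):
        cur = percent_healed(series, i, metric)
        dt = days[i] - days[i - 1]
        out.append(RateObservation(days[i], cur, (cur - prev) / dt))
        prev = cur
    return out


def logit_proportion(p: float, eps: float = LOGIT_EPS) -> float:
    """log-odds of a proportion, clamped into [eps, 1−eps] to stay finite."""
    p = min(max(p, eps), 1.0 - eps)
    return math.log(p / (1.0 - p))


def reattachment_percent(severed_length_0: float, remaining_gap_i: float) -> float:
    """Percent of the originally severed length that has re-fused by day i."""
    if severed_length_0 <= 0:
        raise RangeError("original severed length must be positive")
    if not (0.0 <= remaining_gap_i <= severed_length_0):
        raise RangeError(
            f"remaining gap {remaining_gap_i} outside [0, {severed_length_0}]"
        )
    return 100.0 * (1.0 - remaining_gap_i / severed_length_0)


def rates_frame(
    series_list: Iterable[HealingSeries],
    metrics: tuple[Metric, ...] = ("area", "perimeter"),
) -> pd.DataFrame:
    """Tidy per-sighting table consumed by the trajectory models.

    One row per (injury, sighting, metric) with percent healed and, from the
    second sighting on, the inter-sighting rate; day-0 rows carry rate NaN.
    Label columns present in a series' metadata (type/severity/location) are
    propagated.
    """
    records = []
    for s in series_list:
        for metric in metrics:
            obs = intersighting_rate(s, metric)
            rows = [
                {"day_offset": 0, "percent_healed": percent_healed(s, 0, metric),
                 "rate": float("nan")}
            ] + [
                {"day_offset": o.day_offset, "percent_healed": o.percent_healed,
                 "rate": o.rate}
                for o in obs
            ]
            for row in rows:
                rec = {
                    "injury_id": s.injury_id,
                    "shark_id": s.shark_id,
                    "metric": metric,
                    **row,
                }
                for label in ("type", "severity", "location"):
                    if label in s.metadata:
                        rec[label] = s.metadata[label]
                records.append(rec)
    return pd.DataFrame.from_records(records)
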