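"""Seeded synthetic cohorts of healing whale-shark injuries.

Real photographic records of this kind are opportunistic: sharks are
re-sighted at irregular intervals, every photograph has its own pixel
density, and wound extents are read off hand-traced polygons. The generator
emulates exactly that structure so the full measurement → statistics →
modelling chain can be exercised without any photographs:

* each injury heals along an exponential closure curve with type-dependent
  parameters (lacerations slower than abrasions by default);
* sighting days follow a dispersed (gamma–Poisson, i.e. negative-binomial
  style) gap process with a configurable mean gap over a finite horizon;
* observation noise is additive Gaussian on the percent-healed scale,
  truncated above at full closure;
* each sighting is rendered as pixel-space polygons — wound sections plus a
  square anchor marking — under a per-image multiplicative pixel-density
  jitter, which the anchor normalization must cancel.

Severity and body-location labels are assigned independently of the healing
process, so they are true null factors for the mixed-model screen, while
injury type genuinely drives the healing rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import (
    AnchorScale,
    HealingSeries,
    Polygon,
    WoundAnnotation,
    build_series,
)
from .errors import ConfigError, OrderingError
from .stats import rates_frame

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "simulate_trajectory",
    "render_annotations",
    "generate_cohort",
]

#: Per-type exponential closure parameters (a %, b 1/day) used as generating
#: truth by default: the published pooled surface-area fits per wound type.
DEFAULT_TRUE_PARAMS: dict[str, tuple[float, float]] = {
    "laceration": (98.124, 0.050),
    "abrasion": (94.804, 0.135),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the observed-data regime: 22 usable injury cases across
    18 sharks, opportunistic re-sighting with a mean gap of 15 days over a
    150-day horizon, at least 3 sightings per injury, and 8 percentage
    points of observation noise on the percent-healed scale.
    """

    n_injuries: int = 22
    n_sharks: int = 18
    type_mix: dict = field(
        default_factory=lambda: {"laceration": 0.5, "abrasion": 0.5}
    )
    true_params: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_PARAMS))
    mean_gap_days: float = 15.0
    gap_shape: float = 2.0
    horizon_days: int = 150
    min_sightings: int = 3
    noise_sd: float = 8.0
    pixel_density_range: tuple[float, float] = (0.5, 2.0)
    split_section_prob: float = 0.25
    base_wound_px2: float = 5000.0
    anchor_px2: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_injuries < 1 or self.n_sharks < 1:
            raise ConfigError("need at least one injury and one shark")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("type_mix proportions must sum to 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.min_sightings < 2:
            raise ConfigError("need >=2 sightings per injury")
        if self.mean_gap_days <= 1.0 or self.horizon_days < self.min_sightings:
            raise ConfigError("infeasible sighting process")
        for t in self.type_mix:
            if t not in self.true_params:
                raise ConfigError(f"no true parameters for type {t!r}")


def simulate_trajectory(
    a: float,
    b: float,
    days: Sequence[int],
    noise_sd: float,
    rng: np.random.Generator,
) -> list[float]:
    """Noisy percent-healed values along an exponential closure curve.

    Day 0 is exactly 0 (percent healed is defined relative to the first
    sighting); later values are a(1 − e^(−bx)) plus Gaussian noise,
    truncated above at 100 (full closure).
    """
    if b <= 0:
        raise ConfigError("closure rate b must be positive")
    days = list(days)
    if days != sorted(days) or days[0] != 0:
        raise OrderingError("days must be sorted with day 0 first")
    out = [0.0]
    for x in days[1:]:
        y = a * (1.0 - math.exp(-b * x)) + rng.normal(0.0, noise_sd)
        out.append(min(y, 100.0))
    return out


def _regular_polygon(area: float, n: int, cx: float, cy: float) -> list[tuple[float, float]]:
    # circumradius of a regular n-gon with the requested area
    r = math.sqrt(2.0 * area / (n * math.sin(2.0 * math.pi / n)))
    return [
        (cx + r * math.cos(2.0 * math.pi * k / n),
         cy + r * math.sin(2.0 * math.pi * k / n))
        for k in range(n)
    ]


def render_annotations(
    days: Sequence[int],
    percent_healed: Sequence[float],
    base_wound_px2: float,
    anchor_px2: float,
    pixel_jitter: Sequence[float],
    shark_id: str = "WS-sim",
    injury_id: str = "inj-sim",
    start_date: date = date(2015, 1, 1),
    split_at: int | None = None,
    n_vertices: int = 12,
) -> list[WoundAnnotation]:
    """Render a trajectory as pixel-space polygon annotations.

    Each sighting gets wound polygons with total area proportional to the
    remaining unhealed fraction and a square anchor marking; all coordinates
    of one image are multiplied by that image's pixel-density jitter, so the
    measured ratios must reproduce the trajectory regardless of jitter. The
    sighting at index ``split_at`` (if given) is drawn as two half-area
    sections to exercise the section-summation rule.
    """
    if base_wound_px2 <= 0 or anchor_px2 <= 0:
        raise ConfigError("base areas must be positive")
    annotations = []
    for idx, (d, p, jit) in enumerate(zip(days, percent_healed, pixel_jitter)):
        frac = max(1.0 - p / 100.0, 1e-6)
        s = math.sqrt(jit)  # linear scale; areas pick up the full jitter
        wound_area = base_wound_px2 * frac
        if split_at is not None and idx == split_at:
            half = wound_area / 2.0
            sections = [
                Polygon([(x * s, y * s)
                         for x, y in _regular_polygon(half, n_vertices, 0.0, 0.0)]),
                Polygon([(x * s, y * s)
                         for x, y in _regular_polygon(half, n_vertices, 500.0, 0.0)]),
            ]
        else:
            sections = [
                Polygon([(x * s, y * s)
                         for x, y in _regular_polygon(wound_area, n_vertices, 0.0, 0.0)])
            ]
        side = math.sqrt(anchor_px2)
        anchor_poly = Polygon([
            (1000.0 * s, 1000.0 * s),
            ((1000.0 + side) * s, 1000.0 * s),
            ((1000.0 + side) * s, (1000.0 + side) * s),
            (1000.0 * s, (1000.0 + side) * s),
        ])
        annotations.append(
            WoundAnnotation(
                shark_id=shark_id,
                injury_id=injury_id,
                sighting_date=start_date + timedelta(days=int(d)),
                sections=tuple(sections),
                anchor=AnchorScale(anchor_poly),
                image_id=f"{injury_id}-img{idx}",
            )
        )
    return annotations


def _sighting_days(cfg: CohortConfig, rng: np.random.Generator) -> list[int]:
    """Irregular sighting schedule: day 0 plus dispersed positive gaps."""
    days = [0]
    while days[-1] < cfg.horizon_days:
        lam = rng.gamma(cfg.gap_shape, (cfg.mean_gap_days - 1.0) / cfg.gap_shape)
        gap = 1 + int(rng.poisson(lam))
        days.append(days[-1] + gap)
    days = [d for d in days if d <= cfg.horizon_days]
    while len(days) < cfg.min_sightings:  # guarantee the minimum-sightings rule
        lam = rng.gamma(cfg.gap_shape, (cfg.mean_gap_days - 1.0) / cfg.gap_shape)
        days.append(days[-1] + 1 + int(rng.poisson(lam)))
    return days


@dataclass
class SyntheticCohort:
    """Generated annotations plus the ground truth that produced them."""

    annotations: dict[str, list[WoundAnnotation]]
    labels: dict[str, dict]
    truth: pd.DataFrame
    config: CohortConfig

    def series_list(self) -> list[HealingSeries]:
        return [
            build_series(anns, metadata=self.labels[inj])
            for inj, anns in self.annotations.items()
        ]

    def rates_frame(self) -> pd.DataFrame:
        return rates_frame(self.series_list())

    def to_json(self, path: str | Path) -> None:
        """Serialize in the annotation schema the measurement module reads."""
        docs = []
        for inj, anns in self.annotations.items():
            sightings = []
            for a in anns:
                doc = {
                    "date": a.sighting_date.isoformat(),
                    "image_id": a.image_id,
                    "anchor": [list(v) for v in a.anchor.rectangle.vertices],
                    "sections": [
                        [list(v) for v in s.vertices] for s in a.sections
                    ],
                }
                sightings.append(doc)
            docs.append(
                {
                    "shark_id": anns[0].shark_id,
                    "injury_id": inj,
                    "labels": self.labels[inj],
                    "sightings": sightings,
                }
            )
        Path(path).write_text(json.dumps(docs, indent=1, sort_keys=True))

    def truth_csv(self, path: str | Path) -> None:
        self.truth.to_csv(path, index=False)


def generate_cohort(cfg: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort under *cfg* (seed-deterministic)."""
    cfg = cfg or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    types = list(cfg.type_mix)
    probs = np.array([cfg.type_mix[t] for t in types], dtype=float)
    locations = ["flank", "fin", "peduncle"]

    # Injuries beyond the shark count re-use existing sharks, mimicking
    # individuals that incur several injuries over the study.
    shark_of = [f"WS{i + 1:03d}" for i in range(min(cfg.n_injuries, cfg.n_sharks))]
    while len(shark_of) < cfg.n_injuries:
        shark_of.append(f"WS{int(rng.integers(cfg.n_sharks)) + 1:03d}")

    annotations: dict[str, list[WoundAnnotation]] = {}
    labels: dict[str, dict] = {}
    truth_rows = []
    for j in range(cfg.n_injuries):
        injury_id = f"inj{j + 1:03d}"
        wtype = types[int(rng.choice(len(types), p=probs))]
        a, b = cfg.true_params[wtype]
        severity = "major" if rng.random() < 0.5 else "minor"
        location = locations[int(rng.integers(len(locations)))]
        days = _sighting_days(cfg, rng)
        healed = simulate_trajectory(a, b, days, cfg.noise_sd, rng)
        lo, hi = cfg.pixel_density_range
        jitter = rng.uniform(lo, hi, size=len(days))
        split_at = (
            len(days) // 2 if rng.random() < cfg.split_section_prob else None
        )
        start = date(2015, 1, 1) + timedelta(days=int(rng.integers(365)))
        annotations[injury_id] = render_annotations(
            days,
            healed,
            base_wound_px2=cfg.base_wound_px2 * float(rng.uniform(0.5, 2.0)),
            anchor_px2=cfg.anchor_px2,
            pixel_jitter=jitter,
            shark_id=shark_of[j],
            injury_id=injury_id,
            start_date=start,
            split_at=split_at,
        )
        labels[injury_id] = {
            "type": wtype, "severity": severity, "location": location,
        }
        truth_rows.append(
            {
                "injury_id": injury_id,
                "shark_id": shark_of[j],
                "type": wtype,
                "severity": severity,
                "location": location,
                "a": a,
                "b": b,
                "n_sightings": len(days),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(annotations=annotations, labels=labels, truth=truth, config=cfg)
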