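"""Rule-based injury type/severity/source classification.

Severity (major vs minor) is judged against the first dorsal fin, the
yardstick visible in almost every flank photograph:

* a **laceration** is major when it sits on the main body and the combined
  length of its incisions is at least the fin's vertical height — lacerations
  on appendages are minor (thinner dermal layers there);
* an **abrasion** is major when its area is at least 50% of the fin's area
  *and* its perimeter at least the fin's perimeter, or when its perimeter
  alone is at least 200% of the fin's;
* discoloured (pallid) skin around the site or tissue necrosis promotes
  either type to major regardless of size — a possible sign of infection.

All thresholds are inclusive (greater-than-or-equal). Severity reflects the
likely demand on the animal's resources, not survival prospects, and is
judged on the first sighting of the photographic series.

Quantitative criteria for the six remaining wound types (amputation, bite,
blunt trauma, abnormality, entanglement, nick) ship as an overridable rule
table with implementation-chosen defaults; see DEFAULT_RULES.

Source attribution encodes the observer's visual evidence as flags: a
parallel repeating pattern of clean-cut lacerations indicates a vessel
propeller; a large blunt trauma or large abrasion indicates a vessel hull;
crescent tooth marks a bite; a constriction line an entanglement. With no
notable features the source stays undetermined (typical for minor wounds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

from .errors import ClassificationUnavailableError

log = logging.getLogger(__name__)

__all__ = [
    "WoundType",
    "Severity",
    "Source",
    "InjuryFeatures",
    "DorsalFinReference",
    "InjuryRecord",
    "DEFAULT_RULES",
    "load_rule_table",
    "classify_severity",
    "infer_source",
    "validate_record",
]


class WoundType(str, Enum):
    ABRASION = "abrasion"
    AMPUTATION = "amputation"
    BITE = "bite"
    BLUNT_TRAUMA = "blunt_trauma"
    ABNORMALITY = "abnormality"
    ENTANGLEMENT = "entanglement"
    LACERATION = "laceration"
    NICK = "nick"


class Severity(str, Enum):
    MAJOR = "major"
    MINOR = "minor"


class Source(str, Enum):
    VESSEL_PROPELLER = "vessel_propeller"
    VESSEL_HULL = "vessel_hull"
    BITE = "bite"
    ENTANGLEMENT = "entanglement"
    UNDETERMINED = "undetermined"


# Flags an observer sets from the photographic evidence.
FLAG_PROPELLER = "parallel_repeating_lacerations"
FLAG_HULL = "large_blunt_or_large_abrasion"
FLAG_BITE = "crescent_toothmarks"
FLAG_ENTANGLE = "constriction_line"

_SOURCE_BY_FLAG = {
    FLAG_PROPELLER: Source.VESSEL_PROPELLER,
    FLAG_HULL: Source.VESSEL_HULL,
    FLAG_BITE: Source.BITE,
    FLAG_ENTANGLE: Source.ENTANGLEMENT,
}


@dataclass(frozen=True)
class DorsalFinReference:
    """First-dorsal-fin yardstick, in the same anchor-normalized units as wounds."""

    surface_area: float
    perimeter: float
    vertical_height: float

    def __post_init__(self) -> None:
        if min(self.surface_area, self.perimeter, self.vertical_height) <= 0:
            raise ValueError("dorsal fin reference measurements must be positive")


@dataclass(frozen=True)
class InjuryFeatures:
    """Observer-coded visual and quantitative features of one injury."""

    wound_type: WoundType
    on_main_body: bool = True
    total_incision_length: float = 0.0
    wound_area_ratio_to_fin: float = 0.0
    wound_perimeter_ratio_to_fin: float = 0.0
    discoloration_present: bool = False
    necrosis_present: bool = False
    pattern_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "wound_type", WoundType(self.wound_type))
        object.__setattr__(self, "pattern_flags", frozenset(self.pattern_flags))
        if self.wound_area_ratio_to_fin < 0 or self.wound_perimeter_ratio_to_fin < 0:
            raise ValueError("fin-relative ratios must be >= 0")


@dataclass(frozen=True)
class InjuryRecord:
    injury_id: str
    features: InjuryFeatures
    severity: Severity
    source: Source


# Thresholds verified against the published criteria; per-type defaults for
# the six other types are extrapolated (their published criteria appear only
# in a figure) and overridable via a YAML rule table.
DEFAULT_RULES: dict = {
    "laceration": {"incision_length_vs_fin_height": 1.0},
    "abrasion": {
        "area_vs_fin_area": 0.5,
        "perimeter_vs_fin_perimeter": 1.0,
        "perimeter_alone_vs_fin_perimeter": 2.0,
    },
    # Extrapolated defaults (not from the published criteria text):
    "type_defaults": {
        "amputation": "major",
        "bite": "major",
        "blunt_trauma": "major",
        "abnormality": "minor",
        "entanglement": "major",
        "nick": "minor",
    },
}


def load_rule_table(path: str | Path | None = None) -> dict:
    """Load a severity rule table, merging overrides into DEFAULT_RULES."""
    rules = {
        "laceration": dict(DEFAULT_RULES["laceration"]),
        "abrasion": dict(DEFAULT_RULES["abrasion"]),
        "type_defaults": dict(DEFAULT_RULES["type_defaults"]),
    }
    if path is not None:
        overrides = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in overrides.items():
            if isinstance(val, dict) and key in rules:
                rules[key].update(val)
            else:
                rules[key] = val
    return rules


def _needs_fin(f: InjuryFeatures) -> bool:
    return f.wound_type in (WoundType.LACERATION, WoundType.ABRASION)


def classify_severity(
    f: InjuryFeatures,
    fin: DorsalFinReference | None,
    rules: dict | None = None,
) -> Severity:
    """Apply the severity rule system to one injury's features.

    Raises ClassificationUnavailableError when a quantitative rule is needed
    but no dorsal-fin reference is available.
    """
    rules = rules if rules is not None else DEFAULT_RULES

    if f.wound_type in (WoundType.LACERATION, WoundType.ABRASION):
        # Infection indicators override any size criterion.
        if f.discoloration_present or f.necrosis_present:
            return Severity.MAJOR
        if fin is None:
            raise ClassificationUnavailableError(
                f"{f.wound_type.value} severity needs a dorsal-fin reference"
            )

    if f.wound_type is WoundType.LACERATION:
        thr = rules["laceration"]["incision_length_vs_fin_height"]
        if f.on_main_body and f.total_incision_length >= thr * fin.vertical_height:
            return Severity.MAJOR
        return Severity.MINOR

    if f.wound_type is WoundType.ABRASION:
        r = rules["abrasion"]
        area = f.wound_area_ratio_to_fin * fin.surface_area
        perim = f.wound_perimeter_ratio_to_fin * fin.perimeter
        if (
            area >= r["area_vs_fin_area"] * fin.surface_area
            and perim >= r["perimeter_vs_fin_perimeter"] * fin.perimeter
        ):
            return Severity.MAJOR
        if perim >= r["perimeter_alone_vs_fin_perimeter"] * fin.perimeter:
            return Severity.MAJOR
        return Severity.MINOR

    default = rules["type_defaults"].get(f.wound_type.value, "minor")
    if f.discoloration_present or f.necrosis_present:
        return Severity.MAJOR
    return Severity(default)


def infer_source(f: InjuryFeatures) -> Source:
    """Map pattern flags to an injury source; undetermined without evidence."""
    flags = [fl for fl in f.pattern_flags if fl in _SOURCE_BY_FLAG]
    if not flags:
        return Source.UNDETERMINED
    if len(flags) > 1:
        log.warning(
            "conflicting source flags %s; assigning undetermined", sorted(flags)
        )
        return Source.UNDETERMINED
    return _SOURCE_BY_FLAG[flags[0]]


def validate_record(
    r: InjuryRecord,
    fin: DorsalFinReference | None,
    rules: dict | None = None,
) -> list[dict]:
    """Recompute labels from features and report any disagreement.

    Returns a list of discrepancy entries (empty when consistent); a missing
    fin reference for a quantitative type yields an ``unavailable`` entry.
    """
    report: list[dict] = []
    try:
        sev = classify_severity(r.features, fin, rules)
    except ClassificationUnavailableError as exc:
        report.append(
            {"injury_id": r.injury_id, "field": "severity", "issue": "unavailable",
             "detail": str(exc)}
        )
    else:
        if sev is not r.severity:
            report.append(
                {"injury_id": r.injury_id, "field": "severity",
                 "issue": "mismatch", "stored": r.severity.value,
                 "recomputed": sev.value}
            )
    src = infer_source(r.features)
    if src is not r.source:
        report.append(
            {"injury_id": r.injury_id, "field": "source", "issue": "mismatch",
             "stored": r.source.value, "recomputed": src.value}
        )
    return report
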