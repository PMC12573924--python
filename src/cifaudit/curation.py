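"""Parsing of raw CIF item text and validity filtering.

Raw values are classified as numeric / bounded / missing / malformed, then
numeric values are screened against per-tag open-interval validity rules.
Bounded texts like ``<0.01`` are treated as unreadable and excluded, matching
the survey's curation; tallies satisfy the accounting identity
``numeric + missing + non_numeric == total`` with ``non_numeric =
malformed + bounded`` and ``out_of_range ⊆ numeric``.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cif_io import ABSENT, RawItemSet
from .elements import atomic_number

__all__ = [
    "ParsedValue",
    "ValidityRule",
    "MetricRecord",
    "CurationResult",
    "TAGS",
    "METRIC_TAGS",
    "COUNT_TAGS",
    "DEFAULT_RULES",
    "parse_value",
    "apply_validity",
    "audit_corpus",
    "load_rules",
]

# canonical tags, in survey order
TAG_R = "_refine_ls_r_factor_gt"
TAG_WR = "_refine_ls_wr_factor_ref"
TAG_SHIFT = "_refine_ls_shift/su_max"
TAG_RHO_MAX = "_refine_diff_density_max"
TAG_RHO_MIN = "_refine_diff_density_min"
TAG_GOOF = "_refine_ls_goodness_of_fit_ref"
TAG_THETA = "_diffrn_reflns_theta_max"
TAG_WAVELENGTH = "_diffrn_radiation_wavelength"

METRIC_TAGS = (TAG_R, TAG_WR, TAG_SHIFT, TAG_RHO_MAX, TAG_RHO_MIN, TAG_GOOF, TAG_THETA)
COUNT_TAGS = (
    "_refine_ls_number_parameters",
    "_refine_ls_number_restraints",
    "_refine_ls_number_constraints",
)
TAGS = METRIC_TAGS + (TAG_WAVELENGTH,) + COUNT_TAGS


@dataclass(frozen=True)
class ParsedValue:
    """Classification of one raw item text.

    Exactly one status; ``value``/``su`` only for numeric, ``bound_text``
    only for bounded.
    """

    status: str  # numeric | bounded | missing | malformed
    value: float | None = None
    su: float | None = None
    bound_text: str | None = None

    def __post_init__(self):
        if self.status == "numeric" and (self.value is None or not math.isfinite(self.value)):
            raise ValueError("numeric ParsedValue requires a finite value")
        if self.status == "bounded" and not (
            self.bound_text and self.bound_text[0] in "<>"
        ):
            raise ValueError("bounded ParsedValue requires bound_text starting with < or >")


@dataclass(frozen=True)
class ValidityRule:
    """Open-interval acceptance range for one tag (strict at both ends)."""

    tag: str
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.tag}: lower must be < upper")

    def contains(self, x: float) -> bool:
        return self.lower < x < self.upper


# "Range used in this study" defaults
DEFAULT_RULES: dict[str, ValidityRule] = {
    TAG_R: ValidityRule(TAG_R, 0.0, 1.0),
    TAG_WR: ValidityRule(TAG_WR, 0.0, 1.0),
    TAG_SHIFT: ValidityRule(TAG_SHIFT, 0.0, 15.0),
    TAG_RHO_MAX: ValidityRule(TAG_RHO_MAX, 0.0, 118.0),
    TAG_RHO_MIN: ValidityRule(TAG_RHO_MIN, -118.0, 0.0),
    TAG_GOOF: ValidityRule(TAG_GOOF, 0.0, 20.0),
    TAG_THETA: ValidityRule(TAG_THETA, 0.0, 90.0),
}

_MISSING_TEXTS = frozenset({"?", "."})

# CIF number: optional sign, digits with optional decimal point, optional
# exponent, optional parenthesized su applied to the last digit(s)
_NUM_RE = re.compile(
    r"""^(?P<mantissa>[+-]?(?:\d+\.?\d*|\.\d+))
        (?:[eE](?P<exp>[+-]?\d+))?
        (?:\((?P<su>\d+)\))?$""",
    re.VERBOSE,
)


def parse_value(raw) -> ParsedValue:
    """Classify one raw item text per CIF conventions.

    ``?``, ``.``, empty and absent are missing; ``<x``/``>x`` are bounded;
    a number with a ``(n)`` suffix gets an su on its last digit(s); any
    other text is malformed. Trailing junk is not salvaged.
    """
    if raw is ABSENT or raw is None:
        return ParsedValue(status="missing")
    text = str(raw).strip()
    if text in _MISSING_TEXTS or text == "":
        return ParsedValue(status="missing")
    if text[0] in "<>":
        return ParsedValue(status="bounded", bound_text=text)
    m = _NUM_RE.match(text)
    if m is None:
        return ParsedValue(status="malformed")
    mantissa = m.group("mantissa")
    exp = int(m.group("exp") or 0)
    try:
        value = float(mantissa) * 10.0**exp
    except ValueError:  # pragma: no cover - regex precludes
        return ParsedValue(status="malformed")
    if not math.isfinite(value):
        return ParsedValue(status="malformed")
    su = None
    if m.group("su") is not None:
        frac = mantissa.split(".")[1] if "." in mantissa else ""
        su = int(m.group("su")) * 10.0 ** (-len(frac) + exp)
    return ParsedValue(status="numeric", value=value, su=su)


def apply_validity(
    tag: str, pv: ParsedValue, rules: Mapping[str, ValidityRule] | None = None
) -> tuple[bool, str | None]:
    """Accept/reject a parsed value under the tag's open-interval rule.

    Returns ``(accepted, reason)`` where reason is one of
    ``missing | malformed | bounded-unreadable | out-of-range`` or None.
    """
    rules = DEFAULT_RULES if rules is None else rules
    rule = rules.get(tag.lower())
    if rule is None:
        raise KeyError(f"no validity rule configured for tag {tag!r}")
    if pv.status == "missing":
        return False, "missing"
    if pv.status == "malformed":
        return False, "malformed"
    if pv.status == "bounded":
        return False, "bounded-unreadable"
    if not rule.contains(pv.value):
        return False, "out-of-range"
    return True, None


_REASONS = ("missing", "malformed", "bounded-unreadable", "out-of-range")


@dataclass
class MetricRecord:
    """One entry's curated quality metrics; None means not accepted."""

    identifier: str
    r_factor: float | None = None
    wr_factor: float | None = None
    goof: float | None = None
    shift_su: float | None = None
    rho_max: float | None = None
    rho_min: float | None = None
    theta_max: float | None = None
    wavelength: float | None = None
    n_parameters: int | None = None
    n_restraints: int | None = None
    n_constraints: int | None = None
    z_max: int | None = None
    states: dict[str, str] = field(default_factory=dict)  # tag -> accepted|reason

    _FIELD_BY_TAG = {
        TAG_R: "r_factor",
        TAG_WR: "wr_factor",
        TAG_GOOF: "goof",
        TAG_SHIFT: "shift_su",
        TAG_RHO_MAX: "rho_max",
        TAG_RHO_MIN: "rho_min",
        TAG_THETA: "theta_max",
    }

    def metric(self, tag: str) -> float | None:
        return getattr(self, self._FIELD_BY_TAG[tag.lower()])


@dataclass
class TagTally:
    """Per-tag corpus accounting."""

    total: int = 0
    numeric: int = 0
    missing: int = 0
    malformed: int = 0
    bounded: int = 0
    out_of_range: int = 0
    accepted: int = 0

    @property
    def non_numeric(self) -> int:
        return self.malformed + self.bounded

    @property
    def completeness(self) -> float:
        return self.numeric / self.total if self.total else float("nan")

    def check(self) -> None:
        assert self.numeric + self.missing + self.non_numeric == self.total
        assert self.out_of_range <= self.numeric
        assert self.accepted == self.numeric - self.out_of_range


@dataclass
class CurationResult:
    """Corpus tallies per tag plus the validity rules applied."""

    tallies: dict[str, TagTally]
    rules: Mapping[str, ValidityRule]

    def completeness_percent(self, tag: str) -> float:
        return 100.0 * self.tallies[tag.lower()].completeness

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tag, t in self.tallies.items():
            rule = self.rules.get(tag)
            rows.append(
                {
                    "tag": tag,
                    "total": t.total,
                    "numeric": t.numeric,
                    "missing": t.missing,
                    "malformed": t.malformed,
                    "bounded": t.bounded,
                    "non_numeric": t.non_numeric,
                    "out_of_range": t.out_of_range,
                    "accepted": t.accepted,
                    "completeness_pct": 100.0 * t.completeness,
                    "range": f"{rule.lower} < x < {rule.upper}" if rule else "",
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = self.to_frame().to_dict(orient="records")
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _zmax_of(atom_sites) -> int | None:
    zs = []
    for s in atom_sites:
        try:
            zs.append(atomic_number(s.symbol))
        except KeyError:
            continue
    return max(zs) if zs else None


def audit_corpus(
    entries: Iterable[RawItemSet],
    rules: Mapping[str, ValidityRule] | None = None,
    atom_sites: Mapping[str, Sequence] | None = None,
) -> tuple[CurationResult, list[MetricRecord]]:
    """Curate a corpus of raw item sets.

    ``atom_sites`` optionally maps identifiers to atom-site lists so records
    carry Zmax. Tallies cover exactly the seven survey metric tags.
    """
    rules = DEFAULT_RULES if rules is None else rules
    entries = list(entries)
    if not entries:
        raise ValueError("audit_corpus requires at least one entry")
    tallies = {tag: TagTally() for tag in METRIC_TAGS}
    records: list[MetricRecord] = []
    for raw in entries:
        rec = MetricRecord(identifier=raw.identifier)
        for tag in METRIC_TAGS:
            t = tallies[tag]
            t.total += 1
            pv = parse_value(raw.values.get(tag, ABSENT))
            if pv.status == "numeric":
                t.numeric += 1
            elif pv.status == "missing":
                t.missing += 1
            elif pv.status == "bounded":
                t.bounded += 1
            else:
                t.malformed += 1
            accepted, reason = apply_validity(tag, pv, rules)
            if accepted:
                t.accepted += 1
                rec.states[tag] = "accepted"
                setattr(rec, MetricRecord._FIELD_BY_TAG[tag], pv.value)
            else:
                if reason == "out-of-range":
                    t.out_of_range += 1
                rec.states[tag] = reason
        wl = parse_value(raw.values.get(TAG_WAVELENGTH, ABSENT))
        if wl.status == "numeric" and wl.value > 0:
            rec.wavelength = wl.value
        for tag, attr in zip(COUNT_TAGS, ("n_parameters", "n_restraints", "n_constraints")):
            pv = parse_value(raw.values.get(tag, ABSENT))
            if pv.status == "numeric" and float(pv.value).is_integer():
                setattr(rec, attr, int(pv.value))
        if atom_sites is not None and raw.identifier in atom_sites:
            rec.z_max = _zmax_of(atom_sites[raw.identifier])
        records.append(rec)
    for t in tallies.values():
        t.check()
    return CurationResult(tallies=tallies, rules=rules), records


def load_rules(path: str | Path) -> dict[str, ValidityRule]:
    """Load validity rules from a JSON config: {tag: [lower, upper], ...}.

    Tags absent from the config keep their defaults.
    """
    cfg = json.loads(Path(path).read_text(encoding="utf-8"))
    rules = dict(DEFAULT_RULES)
    for tag, (lo, hi) in cfg.items():
        rules[tag.lower()] = ValidityRule(tag.lower(), float(lo), float(hi))
    return rules
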