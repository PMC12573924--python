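"""Six-axis structure classification.

Chemistry, disorder and radiation are derived from CIF content; pressure
from ``_diffrn_ambient_pressure`` when present; polymeric and refinement
type come from a sidecar label table when supplied, otherwise a flagged
default/heuristic. Every axis records its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .cif_io import CifEntry, normalize_symbol
from .curation import MetricRecord, parse_value
from .elements import atomic_numbers, metal_organic_exclusions

__all__ = [
    "CategoryLabels",
    "ClassificationError",
    "element_set",
    "classify_chemistry",
    "detect_disorder",
    "infer_radiation",
    "assign_categories",
    "load_sidecar",
    "AXES",
]

OCCUPANCY_EPS = 1e-6
ELECTRON_WAVELENGTH_CUTOFF = 0.1  # Å; electron-diffraction λ ≈ 0.02-0.04 Å
PRESSURE_CUTOFF_KPA = 200.0  # 2x atmospheric
ASPHERICAL_KEYWORDS = ("multipole", "hirshfeld atom", "invariom", "aspherical")
DISORDER_KEYWORDS = ("squeeze", "mask")

AXES: dict[str, tuple[str, ...]] = {
    "refinement_type": ("independent_atom", "aspherical"),
    "disordered": ("False", "True"),
    "chemistry": ("organic", "metal_organic"),
    "polymeric": ("False", "True"),
    "pressure": ("ambient", "non_ambient"),
    "radiation": ("xray", "neutron", "electron"),
}


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class CategoryLabels:
    identifier: str
    refinement_type: str = "independent_atom"
    disordered: bool = False
    chemistry: str = "organic"
    polymeric: bool = False
    pressure: str = "ambient"
    radiation: str = "xray"
    provenance: Mapping[str, str] = None  # axis -> derived_from_cif|sidecar|default

    def axis_value(self, axis: str) -> str:
        return str(getattr(self, axis))


def element_set(entry: CifEntry) -> frozenset[str]:
    """Normalized element symbols present in the atom-site loop."""
    table = atomic_numbers()
    out = set()
    for site in entry.atom_sites:
        sym = normalize_symbol(site.symbol)
        if sym not in table:
            raise ClassificationError(f"unrecognized element symbol {site.symbol!r}")
        out.add(sym)
    return frozenset(out)


def classify_chemistry(elements: Iterable[str]) -> str:
    """``organic`` iff no transition metal, lanthanide, actinide or listed
    p-block metal (Al Ga In Tl Ge Sn Pb Sb Bi Po) is present."""
    elements = frozenset(elements)
    if not elements:
        raise ClassificationError("empty element set")
    table = atomic_numbers()
    for sym in elements:
        if sym not in table:
            raise ClassificationError(f"unrecognized element symbol {sym!r}")
    return "organic" if elements.isdisjoint(metal_organic_exclusions()) else "metal_organic"


def detect_disorder(entry: CifEntry) -> bool:
    """True for partial-occupancy non-H sites, populated disorder groups,
    or SQUEEZE/MASK keywords in the special-details text."""
    for site in entry.atom_sites:
        if site.is_hydrogen:
            continue
        if site.disorder_group not in (None, ".", "?", ""):
            return True
        occ = parse_value(site.occupancy_raw)
        if occ.status == "numeric" and occ.value < 1.0 - OCCUPANCY_EPS:
            return True
    details = entry.get("_refine_special_details")
    if details:
        low = str(details).lower()
        if any(k in low for k in DISORDER_KEYWORDS):
            return True
    return False


def infer_radiation(entry: CifEntry) -> tuple[str, str]:
    """Radiation source and its provenance.

    ``_diffrn_radiation_probe`` wins when present; otherwise a wavelength
    cutoff separates electron diffraction from X-rays; otherwise xray by
    default. Neutron cannot be told from X-ray by wavelength alone.
    """
    probe = entry.get("_diffrn_radiation_probe")
    if probe:
        low = str(probe).lower()
        hits = [
            kind
            for kind, keys in (
                ("xray", ("x-ray", "xray", "x_ray")),
                ("neutron", ("neutron",)),
                ("electron", ("electron",)),
            )
            if any(k in low for k in keys)
        ]
        if len(hits) != 1:
            raise ClassificationError(f"contradictory radiation probe {probe!r}")
        return hits[0], "derived_from_cif"
    wl = parse_value(entry.get("_diffrn_radiation_wavelength"))
    if wl.status == "numeric" and wl.value > 0:
        kind = "electron" if wl.value < ELECTRON_WAVELENGTH_CUTOFF else "xray"
        return kind, "derived_from_cif"
    return "xray", "default"


def load_sidecar(path: str | Path) -> pd.DataFrame:
    """Sidecar label table: identifier, polymeric, refinement_type[, pressure]."""
    df = pd.read_csv(path, dtype=str).set_index("identifier")
    return df


def assign_categories(
    entry: CifEntry,
    record: MetricRecord | None = None,
    sidecar: pd.DataFrame | None = None,
) -> CategoryLabels:
    """Compose all six axes for one entry, recording per-axis provenance."""
    prov: dict[str, str] = {}

    try:
        elements = element_set(entry)
    except ClassificationError:
        raise
    if elements:
        chemistry = classify_chemistry(elements)
        prov["chemistry"] = "derived_from_cif"
    else:
        chemistry = "organic"
        prov["chemistry"] = "default"

    if entry.atom_sites or entry.get("_refine_special_details"):
        disordered = detect_disorder(entry)
        prov["disordered"] = "derived_from_cif"
    else:
        disordered = False
        prov["disordered"] = "default"

    radiation, prov["radiation"] = infer_radiation(entry)

    pressure = "ambient"
    prov["pressure"] = "default"
    p = parse_value(entry.get("_diffrn_ambient_pressure"))
    if p.status == "numeric":
        pressure = "non_ambient" if p.value > PRESSURE_CUTOFF_KPA else "ambient"
        prov["pressure"] = "derived_from_cif"

    refinement_type = "independent_atom"
    prov["refinement_type"] = "default"
    details = str(entry.get("_refine_special_details") or "").lower()
    if any(k in details for k in ASPHERICAL_KEYWORDS):
        refinement_type = "aspherical"
        prov["refinement_type"] = "derived_from_cif"

    polymeric = False
    prov["polymeric"] = "default"

    if sidecar is not None:
        if entry.identifier not in sidecar.index:
            raise ClassificationError(f"sidecar has no row for {entry.identifier!r}")
        row = sidecar.loc[entry.identifier]
        if "polymeric" in row.index and pd.notna(row["polymeric"]):
            polymeric = str(row["polymeric"]).strip().lower() in ("true", "1", "yes")
            prov["polymeric"] = "sidecar"
        if "refinement_type" in row.index and pd.notna(row["refinement_type"]):
            refinement_type = str(row["refinement_type"]).strip()
            prov["refinement_type"] = "sidecar"
        if "pressure" in row.index and pd.notna(row["pressure"]):
            pressure = str(row["pressure"]).strip()
            prov["pressure"] = "sidecar"

    return CategoryLabels(
        identifier=entry.identifier,
        refinement_type=refinement_type,
        disordered=disordered,
        chemistry=chemistry,
        polymeric=polymeric,
        pressure=pressure,
        radiation=radiation,
        provenance=prov,
    )
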