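"""Quantities derived from curated items: Bragg resolution, sinθ/λ, DTEST."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cif_io import CifEntry
from .curation import MetricRecord, parse_value
from .elements import atomic_number

__all__ = [
    "ResolutionValue",
    "resolution_from_bragg",
    "resolution_for_record",
    "dtest_threshold",
    "absolute_min_density",
]


@dataclass(frozen=True)
class ResolutionValue:
    """Real-space resolution d (Å) and sinθ/λ (Å⁻¹); d = 1/(2·sinθ/λ)."""

    d: float
    sin_theta_over_lambda: float
    source: str = "computed"  # computed | reported

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("d must be positive")
        if abs(self.sin_theta_over_lambda * 2 * self.d - 1.0) > 1e-9:
            raise ValueError("d and sin(theta)/lambda are inconsistent")


def resolution_from_bragg(wavelength: float, theta_max: float) -> ResolutionValue:
    """d = λ / (2 sin θmax), θmax in degrees.

    Angles are converted to radians internally with math.radians (exact
    multiplication by π/180 in double precision).
    """
    if not 0.0 < theta_max < 90.0:
        raise ValueError(f"theta_max out of domain (0, 90): {theta_max}")
    if wavelength <= 0:
        raise ValueError(f"wavelength must be positive: {wavelength}")
    s = math.sin(math.radians(theta_max))
    d = wavelength / (2.0 * s)
    return ResolutionValue(d=d, sin_theta_over_lambda=s / wavelength, source="computed")


def resolution_for_record(
    record: MetricRecord, entry: CifEntry | None = None
) -> ResolutionValue | None:
    """Resolution for one entry.

    A reported ``_diffrn_reflns_resolution_max`` (sinθ/λ, Å⁻¹; present in
    <0.015% of archive CIFs) is preferred and flagged source=reported;
    otherwise computed from λ and θmax when both were accepted.
    """
    if entry is not None:
        rep = parse_value(entry.get("_diffrn_reflns_resolution_max"))
        if rep.status == "numeric" and rep.value > 0:
            return ResolutionValue(
                d=1.0 / (2.0 * rep.value),
                sin_theta_over_lambda=rep.value,
                source="reported",
            )
    if record.wavelength is not None and record.theta_max is not None:
        return resolution_from_bragg(record.wavelength, record.theta_max)
    return None


def dtest_threshold(z_max: int) -> float:
    """Residual-density reference level: one tenth of Zmax (e Å⁻³)."""
    if z_max < 1:
        raise ValueError(f"z_max must be a positive atomic number: {z_max}")
    return 0.1 * z_max


def absolute_min_density(rho_min: float) -> float:
    """|Δρmin|, for comparison against maximum-density statistics."""
    return abs(rho_min)
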