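"""Element symbol tables shipped as reviewable plain-text package data."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

__all__ = ["atomic_numbers", "metal_organic_exclusions", "atomic_number", "UnknownElementError"]


class UnknownElementError(KeyError):
    """An atom-type symbol not present in the shipped periodic table."""


def _data_text(name: str) -> str:
    return resources.files("cifaudit.data").joinpath(name).read_text(encoding="utf-8")


@lru_cache(maxsize=1)
def atomic_numbers() -> dict[str, int]:
    """Symbol → Z mapping (Z = 1..112, plus D/T → 1)."""
    table = {}
    for line in _data_text("elements.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, z = line.split("\t")
        table[sym] = int(z)
    return table


@lru_cache(maxsize=1)
def metal_organic_exclusions() -> frozenset[str]:
    """Elements whose presence classifies a structure as metal-organic."""
    out = set()
    for line in _data_text("metal_organic_exclusions.txt").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


def atomic_number(symbol: str) -> int:
    try:
        return atomic_numbers()[symbol]
    except KeyError:
        raise UnknownElementError(symbol) from None
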