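"""Minimal CIF 1.1 reading and writing for quality-metric auditing.

Only the features needed to carry refinement-quality items and atom-site
loops are implemented: data blocks, tag-value pairs, ``loop_`` constructs,
single/double-quoted strings, semicolon text fields and comments. Raw value
text is preserved byte-for-byte apart from delimiter stripping, so that
downstream curation sees exactly what the depositor wrote.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

__all__ = [
    "AtomSite",
    "CifEntry",
    "RawItemSet",
    "ABSENT",
    "CifFormatError",
    "read_cif",
    "read_cif_blocks",
    "read_cif_text",
    "extract_items",
    "write_cif_text",
]


class CifFormatError(ValueError):
    """Raised when a file contains no parsable data block."""


class _Absent:
    """Sentinel marking a requested tag that is not present in an entry.

    Distinct from the empty string, which is a legal (if odd) CIF value.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


ABSENT = _Absent()

_HYDROGEN_SYMBOLS = frozenset({"H", "D", "T"})

# element symbol possibly decorated with charge/oxidation suffix, e.g. "Fe3+"
_SYMBOL_RE = re.compile(r"^([A-Za-z]{1,2})")


def normalize_symbol(raw: str) -> str:
    """Strip charge/oxidation decorations from an atom-type symbol.

    >>> normalize_symbol("Fe3+")
    'Fe'
    """
    m = _SYMBOL_RE.match(raw.strip())
    if not m:
        return raw.strip()
    s = m.group(1)
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class AtomSite:
    """One row of an ``_atom_site`` loop, uninterpreted.

    ``occupancy_raw`` keeps the original text (may carry an su suffix or be
    absent → "1"); ``disorder_group`` is the raw ``_atom_site_disorder_group``
    field or ``None`` when the loop has no such column.
    """

    symbol: str
    occupancy_raw: str
    is_hydrogen: bool
    disorder_group: str | None = None


@dataclass
class CifEntry:
    """First-class carrier of one data block's raw items.

    ``items`` maps canonical (lower-cased) tags to raw value text with
    quoting/semicolon delimiters stripped; looped items outside the atom-site
    loop are stored as their first row's value.
    """

    identifier: str
    items: dict[str, str] = field(default_factory=dict)
    atom_sites: list[AtomSite] = field(default_factory=list)
    source: str = ""
    parse_warnings: list[str] = field(default_factory=list)

    def get(self, tag: str):
        return self.items.get(tag.lower(), ABSENT)


@dataclass(frozen=True)
class RawItemSet:
    """Projection of an entry onto a requested tag list."""

    identifier: str
    values: Mapping[str, object]  # tag -> str or ABSENT

    def __getitem__(self, tag: str):
        return self.values[tag.lower()]


# --- tokenizer -------------------------------------------------------------


def _tokenize(text: str) -> Iterator[tuple[str, str]]:
    """Yield (kind, value) tokens: kind in {tag, value, loop, data, stop}."""
    lines = text.splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if line.startswith(";"):
            # semicolon text field: gather until closing ';'
            body = [line[1:]]
            i += 1
            while i < n and not lines[i].startswith(";"):
                body.append(lines[i])
                i += 1
            i += 1  # skip closing ';'
            yield ("value", "\n".join(body).strip())
            continue
        pos = 0
        ln = len(line)
        while pos < ln:
            c = line[pos]
            if c in " \t":
                pos += 1
                continue
            if c == "#":
                break
            if c in "'\"":
                # quoted string: ends at quote followed by whitespace/EOL
                j = pos + 1
                while j < ln:
                    if line[j] == c and (j + 1 == ln or line[j + 1] in " \t"):
                        break
                    j += 1
                yield ("value", line[pos + 1 : j])
                pos = j + 1
                continue
            j = pos
            while j < ln and line[j] not in " \t":
                j += 1
            word = line[pos:j]
            pos = j
            low = word.lower()
            if low.startswith("data_"):
                yield ("data", word[5:])
            elif low == "loop_":
                yield ("loop", "")
            elif low in ("stop_", "global_", "save_") or low.startswith("save_"):
                yield ("stop", word)
            elif word.startswith("_"):
                yield ("tag", low)
            else:
                yield ("value", word)
        i += 1


_ATOM_SYMBOL_TAGS = ("_atom_site_type_symbol", "_atom_site_label")


def _parse_block(identifier: str, tokens: list[tuple[str, str]], source: str) -> CifEntry:
    entry = CifEntry(identifier=identifier, source=source)
    i = 0
    n = len(tokens)
    loops: list[tuple[list[str], list[str]]] = []
    while i < n:
        kind, val = tokens[i]
        if kind == "tag":
            if i + 1 < n and tokens[i + 1][0] == "value":
                if val in entry.items:
                    entry.parse_warnings.append(f"duplicate tag {val}: first occurrence kept")
                else:
                    entry.items[val] = tokens[i + 1][1]
                i += 2
            else:
                entry.parse_warnings.append(f"tag {val} has no value")
                i += 1
        elif kind == "loop":
            i += 1
            header: list[str] = []
            while i < n and tokens[i][0] == "tag":
                header.append(tokens[i][1])
                i += 1
            body: list[str] = []
            while i < n and tokens[i][0] == "value":
                body.append(tokens[i][1])
                i += 1
            if not header:
                entry.parse_warnings.append("loop_ with no tags")
                continue
            if body and len(body) % len(header) != 0:
                entry.parse_warnings.append(
                    f"malformed loop ({header[0]}...): {len(body)} values for {len(header)} tags"
                )
                body = body[: len(body) - len(body) % len(header)]
            loops.append((header, body))
            ncol = len(header)
            for k, tag in enumerate(header):
                if body and tag not in entry.items:
                    entry.items[tag] = body[k]  # first row
        else:  # stray value or stop
            i += 1
    for header, body in loops:
        if any(t.startswith("_atom_site_") for t in header) and any(
            t in header for t in _ATOM_SYMBOL_TAGS
        ):
            entry.atom_sites.extend(_atom_sites_from_loop(header, body))
    return entry


def _atom_sites_from_loop(header: list[str], body: list[str]) -> list[AtomSite]:
    ncol = len(header)
    idx = {t: k for k, t in enumerate(header)}
    sym_col = idx.get("_atom_site_type_symbol", idx.get("_atom_site_label"))
    occ_col = idx.get("_atom_site_occupancy")
    dis_col = idx.get("_atom_site_disorder_group")
    sites = []
    for r in range(0, len(body), ncol):
        row = body[r : r + ncol]
        if len(row) < ncol:
            break
        symbol = normalize_symbol(row[sym_col])
        occ = row[occ_col] if occ_col is not None else "1"
        dis = row[dis_col] if dis_col is not None else None
        sites.append(
            AtomSite(
                symbol=symbol,
                occupancy_raw=occ,
                is_hydrogen=symbol in _HYDROGEN_SYMBOLS,
                disorder_group=dis,
            )
        )
    return sites


# --- public API ------------------------------------------------------------


def read_cif_text(text: str, source: str = "<string>") -> CifEntry:
    """Parse CIF text and return its first data block."""
    return read_cif_blocks_text(text, source)[0]


def read_cif_blocks_text(text: str, source: str = "<string>") -> list[CifEntry]:
    tokens = list(_tokenize(text))
    blocks: list[tuple[str, list[tuple[str, str]]]] = []
    current: list[tuple[str, str]] | None = None
    name = ""
    for kind, val in tokens:
        if kind == "data":
            if current is not None:
                blocks.append((name, current))
            name, current = val, []
        elif current is not None:
            current.append((kind, val))
    if current is not None:
        blocks.append((name, current))
    blocks = [(nm, tk) for nm, tk in blocks if nm]
    if not blocks:
        raise CifFormatError(f"{source}: no data block found")
    return [_parse_block(nm, tk, source) for nm, tk in blocks]


def read_cif(path: str | Path) -> CifEntry:
    """Read the first data block of a CIF file.

    Raises ``OSError`` for unreadable files and :class:`CifFormatError` when
    no data block is present. Malformed loops are salvaged where possible and
    reported via ``entry.parse_warnings``.
    """
    p = Path(path)
    text = p.read_text(encoding="utf-8", errors="replace")
    return read_cif_text(text, source=str(p))


def read_cif_blocks(path: str | Path) -> list[CifEntry]:
    """Read every data block of a (possibly multi-block) CIF file."""
    p = Path(path)
    return read_cif_blocks_text(p.read_text(encoding="utf-8", errors="replace"), str(p))


def extract_items(entry: CifEntry, tags: Sequence[str]) -> RawItemSet:
    """Project an entry onto ``tags``; absence is a value, never an error."""
    if not tags:
        raise ValueError("tags must be non-empty")
    values = {t.lower(): entry.get(t) for t in tags}
    return RawItemSet(identifier=entry.identifier, values=values)


def _format_value(v: str) -> str:
    if v == "":
        return "''"
    if "\n" in v:
        return f"\n;{v}\n;"
    if any(ch in v for ch in " \t'\"") or v.startswith(("_", "#", "$", "[", "]")):
        if "'" not in v:
            return f"'{v}'"
        return f'"{v}"'
    return v


def write_cif_text(entry: CifEntry) -> str:
    """Serialize an entry back to CIF 1.1 text (survey items round-trip)."""
    lines = [f"data_{entry.identifier}"]
    for tag, val in entry.items.items():
        if tag.startswith("_atom_site_") and entry.atom_sites:
            continue
        lines.append(f"{tag} {_format_value(val)}")
    if entry.atom_sites:
        lines.append("loop_")
        lines.append("_atom_site_label")
        lines.append("_atom_site_type_symbol")
        lines.append("_atom_site_occupancy")
        has_dis = any(s.disorder_group is not None for s in entry.atom_sites)
        if has_dis:
            lines.append("_atom_site_disorder_group")
        for k, s in enumerate(entry.atom_sites, 1):
            row = [f"{s.symbol}{k}", s.symbol, s.occupancy_raw]
            if has_dis:
                row.append(s.disorder_group if s.disorder_group is not None else ".")
            lines.append(" ".join(row))
    return "\n".join(lines) + "\n"
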