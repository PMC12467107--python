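"""Curated catalog of neurotransmitter-system genes.

One record per gene: canonical symbol, aliases, the transmitter system it
belongs to (serotonergic, dopaminergic, adrenergic, cholinergic, GABAergic,
histaminergic, glutamatergic) and its functional role (synthesis enzyme,
degradation enzyme, receptor, transporter).

Symbol matching is deliberately forgiving: case, hyphens, spaces and
underscores are ignored and Greek letters are transliterated (α→a, β→b), so
"nAChR α7", "nachr_a7" and "CHRNA7" (via alias) all resolve to the same
record.  The published figures mix these typographic conventions freely.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator

from .io import _data_file

_GREEK = str.maketrans({"α": "a", "β": "b", "γ": "g", "δ": "d", "ε": "e"})


def normalize_symbol(symbol: str) -> str:
    """Canonical lookup form of a gene symbol: lowercase alphanumerics with
    Greek letters transliterated."""
    s = symbol.strip().lower().translate(_GREEK)
    return "".join(ch for ch in s if ch.isalnum())


class System(str, Enum):
    SEROTONERGIC = "serotonergic"
    DOPAMINERGIC = "dopaminergic"
    ADRENERGIC = "adrenergic"
    CHOLINERGIC = "cholinergic"
    GABAERGIC = "GABAergic"
    HISTAMINERGIC = "histaminergic"
    GLUTAMATERGIC = "glutamatergic"


class Role(str, Enum):
    SYNTHESIS_ENZYME = "synthesis_enzyme"
    DEGRADATION_ENZYME = "degradation_enzyme"
    RECEPTOR = "receptor"
    TRANSPORTER = "transporter"


@dataclass(frozen=True)
class GeneCatalogRecord:
    canonical_symbol: str
    aliases: frozenset[str]
    system: System
    role: Role


class GeneCatalog:
    """Indexed collection of :class:`GeneCatalogRecord` with alias lookup."""

    def __init__(self, records: list[GeneCatalogRecord]):
        self._records = list(records)
        self._index: dict[str, GeneCatalogRecord] = {}
        seen_canonical: set[str] = set()
        for rec in self._records:
            canon = normalize_symbol(rec.canonical_symbol)
            if canon in seen_canonical:
                raise ValueError(f"duplicate canonical symbol {rec.canonical_symbol!r}")
            seen_canonical.add(canon)
            for key in {canon, *(normalize_symbol(a) for a in rec.aliases)}:
                owner = self._index.get(key)
                if owner is not None and owner is not rec:
                    raise ValueError(
                        f"symbol {key!r} claimed by both "
                        f"{owner.canonical_symbol!r} and {rec.canonical_symbol!r}"
                    )
                self._index[key] = rec

    def __iter__(self) -> Iterator[GeneCatalogRecord]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self._index

    def lookup(self, symbol: str) -> GeneCatalogRecord:
        try:
            return self._index[normalize_symbol(symbol)]
        except KeyError:
            raise KeyError(f"gene symbol {symbol!r} not in catalog") from None

    def get(self, symbol: str) -> GeneCatalogRecord | None:
        return self._index.get(normalize_symbol(symbol))

    def of_system(self, system: System | str) -> list[GeneCatalogRecord]:
        system = System(system)
        return [r for r in self._records if r.system is system]


def load_builtin_gene_catalog() -> GeneCatalog:
    """The shipped catalog covering all seven transmitter systems."""
    records = [
        GeneCatalogRecord(
            canonical_symbol=entry["canonical_symbol"],
            aliases=frozenset(entry["aliases"]),
            system=System(entry["system"]),
            role=Role(entry["role"]),
        )
        for entry in _data_file("gene_catalog.json")
    ]
    return GeneCatalog(records)
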