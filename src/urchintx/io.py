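"""Reading, writing and validating expression tables and stage maps.

Expression tables are plain TSV/CSV files: the header row carries stage
labels, the first column carries gene symbols, and the body is non-negative
numeric abundance (RPM, FPKM, TPM or raw counts, tagged but not converted).
Blank cells are *missing* values, never zeros — "not detected in the
transcriptome" and "measured at zero" are different statements and the
downstream expression calls keep them apart.

The module also ships the built-in reference fixtures: the per-species
sampling-stage table (native label → unified stage → hours post
fertilization) and the per-stage housekeeping geometric means used as the
normalization denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Unified developmental stages, in temporal order: early cleavage, late
#: cleavage (~60 blastomeres), early blastula, late (hatching/mesenchyme)
#: blastula, early gastrula.
UNIFIED_STAGES: tuple[str, ...] = ("EC", "LC", "EB", "LB", "EG")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(UNIFIED_STAGES)}

#: The four species with built-in reference data.
SPECIES: tuple[str, ...] = (
    "M. franciscanus",
    "P. lividus",
    "L. variegatus",
    "S. purpuratus",
)

_SPECIES_ALIASES = {
    "mfranciscanus": "M. franciscanus",
    "mesocentrotusfranciscanus": "M. franciscanus",
    "plividus": "P. lividus",
    "paracentrotuslividus": "P. lividus",
    "lvariegatus": "L. variegatus",
    "lytechinusvariegatus": "L. variegatus",
    "spurpuratus": "S. purpuratus",
    "strongylocentrotuspurpuratus": "S. purpuratus",
}

_MISSING_TOKENS = {"", "nd", "na", "nan", "n/a"}


class Unit(str, Enum):
    """Abundance unit tag of a source expression table."""

    RPM = "RPM"
    FPKM = "FPKM"
    TPM = "TPM"
    COUNTS = "COUNTS"
    UNKNOWN = "UNKNOWN"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def canonical_species(name: str) -> str:
    """Resolve a species name (full or abbreviated, any casing) to its
    canonical short form, e.g. ``"Mesocentrotus franciscanus"`` →
    ``"M. franciscanus"``."""
    key = "".join(ch for ch in name.lower() if ch.isalnum())
    if key in _SPECIES_ALIASES:
        return _SPECIES_ALIASES[key]
    raise KeyError(
        f"unknown species {name!r}; supported species: {', '.join(SPECIES)}"
    )


@dataclass
class ExpressionTable:
    """Raw gene × native-stage abundance matrix for one species.

    ``values`` is a genes × stages float DataFrame; NaN marks a missing
    measurement.  All defined values must be finite and non-negative, and
    gene symbols and stage labels must be unique.
    """

    species: str
    unit: Unit
    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate stage labels: {dups}")
        arr = v.to_numpy(dtype=float)
        bad = np.where(np.isfinite(arr) & (arr < 0))
        if bad[0].size:
            g, s = v.index[bad[0][0]], v.columns[bad[1][0]]
            raise ValidationError(
                f"negative abundance {arr[bad[0][0], bad[1][0]]!r} "
                f"for gene {g!r} at stage {s!r}"
            )
        if np.isinf(arr).any():
            i, j = np.argwhere(np.isinf(arr))[0]
            raise ValidationError(
                f"non-finite abundance for gene {v.index[i]!r} at stage {v.columns[j]!r}"
            )
        self.values = v.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def native_stages(self) -> list[str]:
        return list(self.values.columns)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_expression_table(
    path: str | Path, species: str, unit: Unit | str = Unit.UNKNOWN
) -> ExpressionTable:
    """Read and validate a gene × stage expression table.

    Input ordering of genes and stages is preserved.  Blank (or ``ND``)
    cells become missing values, not zeros.  A negative value, duplicate
    gene symbol or non-numeric body cell raises :class:`ValidationError`
    naming the offending gene and stage.
    """
    problems = []
    values = _parse_expression_file(Path(path), problems)
    if problems:
        raise ValidationError("; ".join(problems))
    return ExpressionTable(species=species, unit=Unit(unit), values=values)


def _parse_expression_file(path: Path, problems: list[str]) -> pd.DataFrame:
    raw = pd.read_csv(
        path, sep=_sep_for(path), dtype=str, header=0, index_col=0,
        keep_default_na=False, skip_blank_lines=False,
    )
    genes = [str(g).strip() for g in raw.index]
    stages = [str(s).strip() for s in raw.columns]
    seen: dict[str, int] = {}
    for lineno, g in enumerate(genes, start=2):
        if g in seen:
            problems.append(
                f"line {lineno}: duplicate gene symbol {g!r} (first at line {seen[g]})"
            )
        else:
            seen[g] = lineno
    seen_s: set[str] = set()
    for s in stages:
        if s in seen_s:
            problems.append(f"line 1: duplicate stage label {s!r}")
        seen_s.add(s)
    body = np.full(raw.shape, np.nan)
    for i, g in enumerate(genes):
        lineno = i + 2
        for j, s in enumerate(stages):
            cell = str(raw.iat[i, j]).strip()
            if cell.lower() in _MISSING_TOKENS:
                continue
            try:
                x = float(cell)
            except ValueError:
                problems.append(
                    f"line {lineno}: non-numeric value {cell!r} "
                    f"for gene {g!r} at stage {s!r}"
                )
                continue
            if not np.isfinite(x):
                problems.append(
                    f"line {lineno}: non-finite value for gene {g!r} at stage {s!r}"
                )
                continue
            if x < 0:
                problems.append(
                    f"line {lineno}: negative value {x} for gene {g!r} at stage {s!r}"
                )
                continue
            body[i, j] = x
    return pd.DataFrame(body, index=pd.Index(genes, name="gene"), columns=stages)


def validate_expression_file(path: str | Path) -> list[str]:
    """Return a line-addressed list of invariant violations (empty = valid)."""
    problems: list[str] = []
    try:
        _parse_expression_file(Path(path), problems)
    except Exception as exc:  # unreadable / malformed beyond cell level
        problems.append(f"unparseable file: {exc}")
    return problems


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    """Write a table back to TSV/CSV (separator chosen by file extension).

    Values round-trip bit-for-bit: floats are written with Python's
    shortest-exact repr and missing cells as empty fields.
    """
    path = Path(path)
    table.values.to_csv(path, sep=_sep_for(path), na_rep="")


# ---------------------------------------------------------------------------
# Stage maps


@dataclass(frozen=True)
class StageMapEntry:
    native_label: str | None
    unified_stage: str
    hpf: float | None
    available: bool


@dataclass(frozen=True)
class StageMap:
    """Mapping from one species' native stage labels to the unified axis."""

    species: str
    entries: tuple[StageMapEntry, ...]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.unified_stage not in STAGE_INDEX:
                raise ValidationError(f"unknown unified stage {e.unified_stage!r}")
            if e.unified_stage in seen:
                raise ValidationError(
                    f"unified stage {e.unified_stage!r} mapped more than once"
                )
            seen.add(e.unified_stage)

    @classmethod
    def identity(cls, species: str, stages: Iterable[str]) -> "StageMap":
        """A map for tables whose columns already use unified stage names."""
        return cls(
            species=species,
            entries=tuple(
                StageMapEntry(s, s, None, True) for s in stages
            ),
        )

    def native_to_unified(self) -> dict[str, str]:
        return {
            e.native_label: e.unified_stage
            for e in self.entries
            if e.available and e.native_label is not None
        }

    def entry(self, unified_stage: str) -> StageMapEntry | None:
        for e in self.entries:
            if e.unified_stage == unified_stage:
                return e
        return None

    def available_stages(self) -> tuple[str, ...]:
        return tuple(e.unified_stage for e in self.entries if e.available)

    def hpf(self, unified_stage: str) -> float | None:
        e = self.entry(unified_stage)
        return None if e is None else e.hpf


def _data_file(name: str) -> dict | list:
    with resources.files("urchintx").joinpath(f"data/{name}").open("r") as fh:
        return json.load(fh)


def load_builtin_stage_map(species: str) -> StageMap:
    """The built-in sampling-stage table row for one of the four species.

    Stages for which the source dataset has no sample (M. franciscanus early
    blastula, P. lividus late cleavage) come back marked unavailable.
    """
    sp = canonical_species(species)
    row = _data_file("stage_map.json")[sp]
    entries = []
    for stage in UNIFIED_STAGES:
        cell = row[stage]
        if cell is None:
            entries.append(StageMapEntry(None, stage, None, False))
        else:
            entries.append(StageMapEntry(cell["native"], stage, cell["hpf"], True))
    return StageMap(species=sp, entries=tuple(entries))


def load_builtin_ghg_reference() -> dict[str, "GHGProfile"]:
    """Per-species reference housekeeping geometric means (the published
    normalization denominators), keyed by canonical species name.  Stages
    without source data are simply absent from the profile."""
    from .normalization import GHGProfile, HousekeepingSet

    out = {}
    for sp, stages in _data_file("ghg_reference.json").items():
        out[sp] = GHGProfile(
            species=sp,
            values=dict(stages),
            hkg_set=HousekeepingSet(),
            excluded=tuple(
                (s, "no source data") for s in UNIFIED_STAGES if s not in stages
            ),
        )
    return out


def load_printed_nrpm_anchors() -> list[dict]:
    """Published per-gene normalized-expression values (with species and
    stage) used for round-trip fixtures."""
    return list(_data_file("printed_nrpm.json"))
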