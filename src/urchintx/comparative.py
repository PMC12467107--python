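"""Cross-species comparison of expression per transmitter system.

Assembles, for one transmitter system, a genes × species matrix of
presence/pattern summaries; classifies each gene's cross-species
conservation; and renders the machine-readable report plus a stream-style
plot (one colored band per gene per species, band half-width proportional
to NRPM on a scale shared across the system, missing stages gapped).

A gene counts as "ever expressed" in a species if it is called EXPRESSED
at at least one unified stage of the early window (EC–EG); genes switched
on only after gastrulation are, for the early-embryo question, absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from pydantic import BaseModel

from .catalog import GeneCatalog, System, normalize_symbol
from .dynamics import DynamicsCall, Pattern, UnifiedProfile, classify_dynamics
from .io import UNIFIED_STAGES
from .normalization import Call, Thresholds

#: Species with data needed before "conserved in all" is considered
#: informative (configurable in classify_conservation).
MIN_SPECIES_FOR_CONSERVED_ALL = 3


class ConsClass(str, Enum):
    CONSERVED_ALL = "CONSERVED_ALL"
    MAJORITY = "MAJORITY"
    SPECIES_SPECIFIC = "SPECIES_SPECIFIC"
    NOT_DETECTED = "NOT_DETECTED"


@dataclass(frozen=True)
class ConservationClass:
    gene: str
    cls: ConsClass
    n_expressed: int
    n_with_data: int


@dataclass(frozen=True)
class CellSummary:
    """One (gene, species) cell of a comparison matrix."""

    data_present: bool
    ever_expressed: bool | None = None
    pattern: Pattern | None = None
    max_nrpm: float | None = None

    def __post_init__(self) -> None:
        if not self.data_present and (
            self.ever_expressed is not None
            or self.pattern is not None
            or self.max_nrpm is not None
        ):
            raise ValueError("cell without data must have no summary fields")


@dataclass
class ComparisonMatrix:
    system: System
    genes: tuple[str, ...]
    species: tuple[str, ...]
    cells: dict[tuple[str, str], CellSummary]

    def cell(self, gene: str, species: str) -> CellSummary:
        return self.cells[(gene, species)]


def build_comparison(
    profiles_by_species: Mapping[str, Iterable[UnifiedProfile]],
    catalog: GeneCatalog,
    system: System | str,
    fold_threshold: float = 2.0,
    thr: Thresholds | None = None,
) -> ComparisonMatrix:
    """One row per catalog gene of the system, one column per species.

    A species whose table lacks the gene altogether gets an empty cell
    (``data_present=False``) — the transcript was not detected in that
    transcriptome, which is information, not an error.  At least two
    species with data are required.
    """
    system = System(system)
    thr = thr or Thresholds()
    if len(profiles_by_species) < 2:
        raise ValueError("cross-species comparison needs at least 2 species")
    gene_records = catalog.of_system(system)
    genes = tuple(r.canonical_symbol for r in gene_records)
    species = tuple(profiles_by_species)

    cells: dict[tuple[str, str], CellSummary] = {}
    for sp, profiles in profiles_by_species.items():
        indexed: dict[str, UnifiedProfile] = {}
        for p in profiles:
            rec = catalog.get(p.gene)
            key = rec.canonical_symbol if rec is not None else p.gene
            indexed[normalize_symbol(key)] = p
        for rec in gene_records:
            p = indexed.get(normalize_symbol(rec.canonical_symbol))
            if p is None:
                cells[(rec.canonical_symbol, sp)] = CellSummary(data_present=False)
                continue
            call = classify_dynamics(p, fold_threshold=fold_threshold, thr=thr)
            obs = p.observed()
            ever = any(v >= thr.nrpm_threshold for _, v in obs)
            cells[(rec.canonical_symbol, sp)] = CellSummary(
                data_present=True,
                ever_expressed=ever,
                pattern=call.pattern,
                max_nrpm=max(v for _, v in obs),
            )
    return ComparisonMatrix(system=system, genes=genes, species=species, cells=cells)


def classify_conservation(
    n_expressed: int,
    n_with_data: int,
    gene: str = "",
    min_all: int = MIN_SPECIES_FOR_CONSERVED_ALL,
) -> ConservationClass:
    """Pure function of (number of species expressing, number with data).

    NOT_DETECTED if none express; CONSERVED_ALL if every species with data
    expresses and at least ``min_all`` have data; SPECIES_SPECIFIC if
    exactly one expresses; MAJORITY otherwise.
    """
    if n_with_data < 1:
        raise ValueError("need at least one species with data")
    if not 0 <= n_expressed <= n_with_data:
        raise ValueError("n_expressed must lie in [0, n_with_data]")
    if n_expressed == 0:
        cls = ConsClass.NOT_DETECTED
    elif n_expressed == n_with_data and n_with_data >= min_all:
        cls = ConsClass.CONSERVED_ALL
    elif n_expressed == 1:
        cls = ConsClass.SPECIES_SPECIFIC
    else:
        cls = ConsClass.MAJORITY
    return ConservationClass(
        gene=gene, cls=cls, n_expressed=n_expressed, n_with_data=n_with_data
    )


def conservation_of_row(matrix: ComparisonMatrix, gene: str) -> ConservationClass:
    row = [matrix.cell(gene, sp) for sp in matrix.species]
    n_with_data = sum(c.data_present for c in row)
    n_expressed = sum(bool(c.ever_expressed) for c in row if c.data_present)
    if n_with_data == 0:
        # transcript absent from every transcriptome
        return ConservationClass(gene, ConsClass.NOT_DETECTED, 0, 0)
    return classify_conservation(n_expressed, n_with_data, gene=gene)


# ---------------------------------------------------------------------------
# Report schema (pydantic models double as the shipped JSON schema)


class TrajectoryModel(BaseModel):
    stage: str
    nrpm: float | None
    call: str


class SpeciesEntryModel(BaseModel):
    species: str
    data_present: bool
    ever_expressed: bool | None = None
    pattern: str | None = None
    max_nrpm: float | None = None
    trajectory: list[TrajectoryModel] = []


class GeneReportModel(BaseModel):
    gene: str
    conservation_class: str
    n_expressed: int
    n_with_data: int
    species: list[SpeciesEntryModel]


class SystemReportModel(BaseModel):
    system: str
    unit: str = "GHG multiples"
    stages: list[str] = list(UNIFIED_STAGES)
    genes: list[GeneReportModel]


def build_system_report(
    matrix: ComparisonMatrix,
    profiles_by_species: Mapping[str, Iterable[UnifiedProfile]],
    thr: Thresholds | None = None,
) -> SystemReportModel:
    """Machine-readable per-system report: trajectories, patterns and
    conservation class for every catalog gene of the system."""
    thr = thr or Thresholds()
    indexed: dict[str, dict[str, UnifiedProfile]] = {}
    from .catalog import load_builtin_gene_catalog

    catalog = load_builtin_gene_catalog()
    for sp, profiles in profiles_by_species.items():
        indexed[sp] = {}
        for p in profiles:
            rec = catalog.get(p.gene)
            key = rec.canonical_symbol if rec is not None else p.gene
            indexed[sp][normalize_symbol(key)] = p

    gene_reports = []
    for gene in matrix.genes:
        cons = conservation_of_row(matrix, gene)
        entries = []
        for sp in matrix.species:
            cell = matrix.cell(gene, sp)
            traj: list[TrajectoryModel] = []
            if cell.data_present:
                p = indexed[sp][normalize_symbol(gene)]
                for s in UNIFIED_STAGES:
                    v = p.values.get(s)
                    missing = v is None or (isinstance(v, float) and np.isnan(v))
                    traj.append(
                        TrajectoryModel(
                            stage=s,
                            nrpm=None if missing else float(v),
                            call=(
                                Call.MISSING if missing
                                else Call.EXPRESSED if v >= thr.nrpm_threshold
                                else Call.NEGLIGIBLE
                            ).value,
                        )
                    )
            entries.append(
                SpeciesEntryModel(
                    species=sp,
                    data_present=cell.data_present,
                    ever_expressed=cell.ever_expressed,
                    pattern=None if cell.pattern is None else cell.pattern.value,
                    max_nrpm=cell.max_nrpm,
                    trajectory=traj,
                )
            )
        gene_reports.append(
            GeneReportModel(
                gene=gene,
                conservation_class=cons.cls.value,
                n_expressed=cons.n_expressed,
                n_with_data=cons.n_with_data,
                species=entries,
            )
        )
    return SystemReportModel(system=matrix.system.value, genes=gene_reports)


def render_system_report(
    matrix: ComparisonMatrix,
    profiles_by_species: Mapping[str, Iterable[UnifiedProfile]],
    out_json: str | Path | None = None,
    plot_dir: str | Path | None = None,
    scale: str = "linear",
    thr: Thresholds | None = None,
) -> SystemReportModel:
    """Emit the JSON report and the per-system stream plot (SVG + PNG).

    Band half-width is the NRPM value itself (no replicate spread exists in
    the source tables) on a scale shared across the system; ``scale`` may
    be ``"linear"`` or ``"log10"`` (log10(1 + NRPM/threshold), useful since
    NRPM spans several orders of magnitude).  All-negligible genes render
    as zero-width bands flagged in the legend.
    """
    if not matrix.genes:
        raise ValueError("empty comparison matrix")
    if scale not in {"linear", "log10"}:
        raise ValueError(f"unknown scale {scale!r}")
    thr = thr or Thresholds()
    report = build_system_report(matrix, profiles_by_species, thr=thr)

    if out_json is not None:
        Path(out_json).parent.mkdir(parents=True, exist_ok=True)
        Path(out_json).write_text(report.model_dump_json(indent=2))

    if plot_dir is not None:
        plot_dir = Path(plot_dir)
        plot_dir.mkdir(parents=True, exist_ok=True)
        _stream_plot(report, plot_dir, scale=scale, thr=thr)
    return report


def _band_width(nrpm: float, scale: str, thr: Thresholds) -> float:
    if scale == "log10":
        return float(np.log10(1.0 + nrpm / thr.nrpm_threshold))
    return float(nrpm)


def _stream_plot(
    report: SystemReportModel, plot_dir: Path, scale: str, thr: Thresholds
) -> None:
    bands = []  # (label, widths per stage with NaN gaps, flat_negligible)
    for g in report.genes:
        for entry in g.species:
            if not entry.data_present:
                continue
            widths = np.full(len(UNIFIED_STAGES), np.nan)
            for t in entry.trajectory:
                if t.nrpm is not None:
                    widths[UNIFIED_STAGES.index(t.stage)] = _band_width(
                        t.nrpm, scale, thr
                    )
            bands.append((f"{g.gene} ({entry.species})", widths, not entry.ever_expressed))
    if not bands:
        return
    shared_max = max(
        (np.nanmax(w) for _, w, _ in bands if np.isfinite(w).any()), default=1.0
    )
    shared_max = shared_max or 1.0

    fig, ax = plt.subplots(figsize=(8, max(3, 0.45 * len(bands))))
    x = np.arange(len(UNIFIED_STAGES), dtype=float)
    cmap = plt.get_cmap("tab20")
    for i, (label, widths, negligible) in enumerate(bands):
        base = float(len(bands) - 1 - i)
        half = 0.45 * widths / shared_max
        if negligible:
            half = np.where(np.isnan(half), np.nan, 0.0)
            label += " [negligible]"
        mask = np.isfinite(half)
        ax.fill_between(
            x, base - np.where(mask, half, 0), base + np.where(mask, half, 0),
            where=mask, color=cmap(i % 20), alpha=0.8, label=label,
        )
    ax.set_xticks(x)
    ax.set_xticklabels(list(UNIFIED_STAGES))
    ax.set_yticks([])
    ax.set_xlabel("unified developmental stage")
    ax.set_title(f"{report.system} system — band half-width ∝ NRPM ({scale})")
    ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=6)
    fig.tight_layout()
    stem = plot_dir / report.system.replace("/", "_")
    fig.savefig(f"{stem}.svg")
    fig.savefig(f"{stem}.png", dpi=120)
    plt.close(fig)


def report_roundtrip(report: SystemReportModel) -> SystemReportModel:
    """Parse → emit → parse; lossless by construction, used as an oracle."""
    return SystemReportModel.model_validate(json.loads(report.model_dump_json()))
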