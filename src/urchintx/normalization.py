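"""Housekeeping-gene geometric-mean normalization and expression calling.

Each source dataset reports abundance in its own unit (RPM, FPKM, TPM), so
per-gene values are not comparable across datasets.  Dividing every gene's
value at a stage by the geometric mean of three stably expressed
housekeeping genes (GAPDH, ODC, HPRT) at that same stage cancels library
size, sequencing depth and unit conventions: the result, in "GHG multiples"
(NRPM), is invariant to any per-stage rescaling of the whole table.

Expression is then called against a fixed NRPM threshold (default 0.003,
corresponding to roughly 300 transcripts per embryo, ≈ FPKM 5 in the
reference dataset); the boundary is inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .catalog import normalize_symbol
from .io import ExpressionTable, Unit


class Call(str, Enum):
    EXPRESSED = "EXPRESSED"
    NEGLIGIBLE = "NEGLIGIBLE"
    MISSING = "MISSING"


class Scale(str, Enum):
    """Scales on which an expression threshold can be stated."""

    ABS_PER_EMBRYO = "ABS_PER_EMBRYO"
    SOURCE_UNIT = "SOURCE_UNIT"
    NRPM = "NRPM"


@dataclass(frozen=True)
class HousekeepingSet:
    """Reference genes for normalization; at least two required."""

    symbols: tuple[str, ...] = ("GAPDH", "ODC", "HPRT")

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("housekeeping set needs at least 2 genes")


@dataclass(frozen=True)
class Thresholds:
    """Expression-calling thresholds on their three equivalent scales.

    ``nrpm_threshold`` is the operative value; the absolute and
    source-unit forms are the calibration it was derived from and are kept
    for unit conversions, not re-derived.
    """

    abs_transcripts_per_embryo: float = 300.0
    fpkm_equivalent: float = 5.0
    nrpm_threshold: float = 0.003

    def __post_init__(self) -> None:
        if min(
            self.abs_transcripts_per_embryo,
            self.fpkm_equivalent,
            self.nrpm_threshold,
        ) <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass
class GHGProfile:
    """Per-stage geometric mean of the housekeeping genes (the
    normalization denominator), in the unit of the source table.

    Defined only at stages where every housekeeping gene is present and
    strictly positive; other stages are listed in ``excluded`` with a
    reason.
    """

    species: str
    values: dict[str, float]
    hkg_set: HousekeepingSet = field(default_factory=HousekeepingSet)
    excluded: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for stage, v in self.values.items():
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"GHG at stage {stage!r} must be positive, got {v!r}")

    def __getitem__(self, stage: str) -> float:
        return self.values[stage]

    @property
    def stages(self) -> list[str]:
        return list(self.values)


@dataclass
class NormalizedProfile:
    """Gene × stage matrix of NRPM values with per-cell expression calls.

    ``nrpm`` is NaN exactly where the source value or the stage's GHG is
    missing; ``calls`` holds MISSING there and EXPRESSED/NEGLIGIBLE
    elsewhere once :func:`call_expression` has run.
    """

    species: str
    nrpm: pd.DataFrame
    calls: pd.DataFrame
    unit: str = "GHG multiples"
    thresholds: Thresholds | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.nrpm.index)

    @property
    def stages(self) -> list[str]:
        return list(self.nrpm.columns)


def compute_ghg(table: ExpressionTable, hkgs: HousekeepingSet | None = None) -> GHGProfile:
    """Per-stage geometric mean of the housekeeping genes.

    Computed in log space, ``exp(mean(log x))`` — overflow-safe and exact
    for the self-normalization fixed point.  A stage where any housekeeping
    gene is missing or non-positive is excluded (with a warning record),
    mirroring how stages without source data are simply skipped; if no
    stage survives, that is an error.
    """
    hkgs = hkgs or HousekeepingSet()
    by_norm = {normalize_symbol(g): g for g in table.values.index}
    rows = []
    for sym in hkgs.symbols:
        key = normalize_symbol(sym)
        if key not in by_norm:
            raise KeyError(f"housekeeping gene {sym!r} absent from table")
        rows.append(by_norm[key])
    hk = table.values.loc[rows]

    values: dict[str, float] = {}
    excluded: list[tuple[str, str]] = []
    for stage in table.native_stages:
        col = hk[stage].to_numpy(dtype=float)
        if np.isnan(col).any():
            excluded.append((stage, "housekeeping value missing"))
        elif (col <= 0).any():
            excluded.append((stage, "housekeeping value <= 0"))
        else:
            values[stage] = float(np.exp(np.mean(np.log(col))))
    if not values:
        raise ValueError(
            f"no stage has a complete, positive housekeeping set; "
            f"excluded: {excluded}"
        )
    for stage, reason in excluded:
        warnings.warn(f"stage {stage!r} excluded from GHG profile: {reason}")
    return GHGProfile(
        species=table.species, values=values, hkg_set=hkgs, excluded=tuple(excluded)
    )


def normalize_to_nrpm(table: ExpressionTable, ghg: GHGProfile) -> NormalizedProfile:
    """Divide every value by its stage's GHG; output unit is GHG multiples.

    Stages without a GHG value yield all-MISSING columns.
    """
    covered = [s for s in table.native_stages if s in ghg.values]
    if not covered:
        raise ValueError("GHG profile covers no stage of the table")
    nrpm = pd.DataFrame(
        np.nan, index=table.values.index, columns=table.values.columns
    )
    for stage in covered:
        nrpm[stage] = table.values[stage] / ghg[stage]
    calls = pd.DataFrame(
        pd.NA, index=nrpm.index, columns=nrpm.columns, dtype=object
    )
    calls[nrpm.isna()] = Call.MISSING
    return NormalizedProfile(species=table.species, nrpm=nrpm, calls=calls)


def call_expression(
    profile: NormalizedProfile, thr: Thresholds | None = None
) -> NormalizedProfile:
    """Fill the calls matrix: EXPRESSED iff NRPM ≥ threshold (inclusive
    boundary), NEGLIGIBLE below, MISSING preserved.  Idempotent."""
    thr = thr or Thresholds()
    nrpm = profile.nrpm
    calls = pd.DataFrame(Call.NEGLIGIBLE, index=nrpm.index, columns=nrpm.columns, dtype=object)
    calls[nrpm >= thr.nrpm_threshold] = Call.EXPRESSED
    calls[nrpm.isna()] = Call.MISSING
    return NormalizedProfile(
        species=profile.species,
        nrpm=nrpm.copy(),
        calls=calls,
        unit=profile.unit,
        thresholds=thr,
    )


#: Default calibration between absolute transcripts/embryo and source units:
#: 300 transcripts/embryo ↔ FPKM 5 in the reference dataset, i.e. 1/60
#: source-unit per transcript.  Dataset-specific; override per dataset.
DEFAULT_ABS_TO_UNIT_FACTOR = 1.0 / 60.0


def convert_threshold(
    value: float,
    from_scale: Scale | str,
    to_scale: Scale | str,
    ghg_value: float | None = None,
    abs_to_unit_factor: float = DEFAULT_ABS_TO_UNIT_FACTOR,
) -> float:
    """Pure unit conversion of a threshold between its three scales.

    ABS_PER_EMBRYO ↔ SOURCE_UNIT via ``abs_to_unit_factor`` (source-unit
    per transcript-per-embryo); SOURCE_UNIT ↔ NRPM via the stage's GHG.
    The composition is associative and exactly invertible.
    """
    from_scale, to_scale = Scale(from_scale), Scale(to_scale)
    if not (value > 0 and np.isfinite(value)):
        raise ValueError(f"threshold value must be positive, got {value!r}")
    if not (abs_to_unit_factor > 0 and np.isfinite(abs_to_unit_factor)):
        raise ValueError("abs_to_unit_factor must be positive")
    if from_scale is to_scale:
        return value
    needs_ghg = Scale.NRPM in (from_scale, to_scale)
    if needs_ghg:
        if ghg_value is None or not (ghg_value > 0 and np.isfinite(ghg_value)):
            raise ValueError("a positive ghg_value is required for NRPM conversions")

    # route through SOURCE_UNIT as the common scale
    if from_scale is Scale.ABS_PER_EMBRYO:
        in_source = value * abs_to_unit_factor
    elif from_scale is Scale.NRPM:
        in_source = value * ghg_value  # type: ignore[operator]
    else:
        in_source = value

    if to_scale is Scale.ABS_PER_EMBRYO:
        return in_source / abs_to_unit_factor
    if to_scale is Scale.NRPM:
        return in_source / ghg_value  # type: ignore[operator]
    return in_source
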