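"""Stage harmonization and expression-dynamics classification.

After normalization, each gene's trajectory over the unified stage axis
(EC < LC < EB < LB < EG) is summarized as one of a small set of patterns
tied to the maternal-to-zygotic transition (MZT):

* ``ABSENT`` — negligible at every sampled stage;
* ``MATERNAL_DECLINE`` — maternally deposited mRNA decaying after
  fertilization, no substantial recovery;
* ``LATE_ONSET`` — negligible through cleavage, switched on at the
  blastula or later (zygotic transcription);
* ``U_SHAPED`` — maternal decline followed by a zygotic upswing;
* ``PEAK_INTERIOR`` — rising from an expressed baseline (with or without
  a later fall);
* ``FLAT`` — expressed with no fold-change large enough to count.

A "move" between consecutive sampled stages is a fold-change of at least
``fold_threshold`` (default 2, inclusive) in either direction, measured on
values floored at one-tenth of the expression threshold so that zeros do
not produce infinite ratios.  Classification depends only on ratios and
threshold crossings, so it is invariant to rescaling the profile and the
threshold together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .io import STAGE_INDEX, UNIFIED_STAGES, StageMap
from .normalization import Call, NormalizedProfile, Thresholds


class Pattern(str, Enum):
    ABSENT = "ABSENT"
    MATERNAL_DECLINE = "MATERNAL_DECLINE"
    LATE_ONSET = "LATE_ONSET"
    U_SHAPED = "U_SHAPED"
    FLAT = "FLAT"
    PEAK_INTERIOR = "PEAK_INTERIOR"


@dataclass(frozen=True)
class UnifiedProfile:
    """One gene's per-stage NRPM values on the unified stage axis.

    ``values`` maps each of the five unified stages to an NRPM value or
    None (no sample / no GHG).  At least one stage must carry a value.
    """

    species: str
    gene: str
    values: dict[str, float | None]
    calls: dict[str, Call] | None = None

    def __post_init__(self) -> None:
        for s in self.values:
            if s not in STAGE_INDEX:
                raise ValueError(f"unknown unified stage {s!r}")
        if not any(v is not None and not _isnan(v) for v in self.values.values()):
            raise ValueError(f"profile for {self.gene!r} has no defined value")

    def observed(self) -> list[tuple[str, float]]:
        """(stage, value) pairs for non-missing stages, in temporal order."""
        out = []
        for s in UNIFIED_STAGES:
            v = self.values.get(s)
            if v is not None and not _isnan(v):
                out.append((s, float(v)))
        return out


def _isnan(v: float) -> bool:
    return isinstance(v, float) and math.isnan(v)


@dataclass(frozen=True)
class MztUpswing:
    """Whether a blastula-stage upswing (EB or LB rising ≥ fold over the
    minimum of all earlier stages) was found, and at which stage."""

    evaluable: bool
    flagged: bool = False
    stage: str | None = None


@dataclass(frozen=True)
class DynamicsCall:
    gene: str
    species: str
    pattern: Pattern
    mzt: MztUpswing
    max_stage: str | None
    min_stage: str | None
    fold_changes: tuple[float, ...]
    insufficient_stages: bool = False


def harmonize_stages(
    profile: NormalizedProfile, stage_map: StageMap
) -> list[UnifiedProfile]:
    """Re-key a normalized profile's native stages onto the unified axis.

    Pure re-indexing: values are untouched, unified stages without a native
    sample come back as None.  A native stage absent from the map is an
    error naming that stage.
    """
    mapping = stage_map.native_to_unified()
    for native in profile.stages:
        if native not in mapping:
            raise KeyError(
                f"native stage {native!r} not in stage map for {stage_map.species!r}"
            )
    out = []
    have_calls = profile.calls.notna().to_numpy().all()
    for gene in profile.genes:
        values: dict[str, float | None] = {s: None for s in UNIFIED_STAGES}
        calls: dict[str, Call] = {s: Call.MISSING for s in UNIFIED_STAGES}
        for native in profile.stages:
            unified = mapping[native]
            v = profile.nrpm.at[gene, native]
            values[unified] = None if _isnan(float(v)) else float(v)
            c = profile.calls.at[gene, native]
            if isinstance(c, Call):
                calls[unified] = c
        out.append(
            UnifiedProfile(
                species=profile.species,
                gene=gene,
                values=values,
                calls=calls if have_calls else None,
            )
        )
    return out


def _calls_for(
    profile: UnifiedProfile, thr: Thresholds
) -> dict[str, Call]:
    if profile.calls is not None:
        return profile.calls
    calls = {}
    for s in UNIFIED_STAGES:
        v = profile.values.get(s)
        if v is None or _isnan(v):
            calls[s] = Call.MISSING
        elif v >= thr.nrpm_threshold:
            calls[s] = Call.EXPRESSED
        else:
            calls[s] = Call.NEGLIGIBLE
    return calls


def classify_dynamics(
    profile: UnifiedProfile,
    fold_threshold: float = 2.0,
    thr: Thresholds | None = None,
) -> DynamicsCall:
    """Deterministic pattern call for one gene's trajectory.

    Decision sequence on the non-missing stages in temporal order:

    1. every call NEGLIGIBLE → ``ABSENT``;
    2. first EXPRESSED stage is EB or later with all earlier sampled
       stages NEGLIGIBLE → ``LATE_ONSET``;
    3. otherwise from the signs of the qualifying fold-changes ("moves"):
       none → ``FLAT``; all downward → ``MATERNAL_DECLINE``; first move
       down with a later move up → ``U_SHAPED``; first move up →
       ``PEAK_INTERIOR``.

    Fewer than three sampled stages does not raise; the call is made on
    what is available and flagged ``insufficient_stages``.
    """
    thr = thr or Thresholds()
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    obs = profile.observed()
    calls = _calls_for(profile, thr)
    insufficient = len(obs) < 3
    mzt = detect_mzt_upswing(profile, fold_threshold=fold_threshold, thr=thr)

    stages = [s for s, _ in obs]
    floor = thr.nrpm_threshold / 10.0
    vals = np.array([max(v, floor) for _, v in obs])
    ratios = tuple(float(vals[i + 1] / vals[i]) for i in range(len(vals) - 1))
    max_stage = stages[int(np.argmax(vals))] if stages else None
    min_stage = stages[int(np.argmin(vals))] if stages else None

    def result(pattern: Pattern) -> DynamicsCall:
        return DynamicsCall(
            gene=profile.gene,
            species=profile.species,
            pattern=pattern,
            mzt=mzt,
            max_stage=max_stage,
            min_stage=min_stage,
            fold_changes=ratios,
            insufficient_stages=insufficient,
        )

    observed_calls = [calls[s] for s in stages]
    if all(c is Call.NEGLIGIBLE for c in observed_calls):
        return result(Pattern.ABSENT)

    first_expr = next(
        (i for i, c in enumerate(observed_calls) if c is Call.EXPRESSED), None
    )
    if (
        first_expr is not None
        and STAGE_INDEX[stages[first_expr]] >= STAGE_INDEX["EB"]
        and all(c is Call.NEGLIGIBLE for c in observed_calls[:first_expr])
    ):
        return result(Pattern.LATE_ONSET)

    log_cut = math.log2(fold_threshold)
    moves = [
        1 if r >= fold_threshold else -1
        for r in ratios
        if abs(math.log2(r)) >= log_cut
    ]
    if not moves:
        return result(Pattern.FLAT)
    if all(m < 0 for m in moves):
        return result(Pattern.MATERNAL_DECLINE)
    if moves[0] < 0:
        return result(Pattern.U_SHAPED)
    return result(Pattern.PEAK_INTERIOR)


def detect_mzt_upswing(
    profile: UnifiedProfile,
    fold_threshold: float = 2.0,
    thr: Thresholds | None = None,
) -> MztUpswing:
    """Flag a maternal-to-zygotic upswing: NRPM at EB or LB at least
    ``fold_threshold`` times the minimum over all strictly earlier sampled
    stages.  Reports the earliest qualifying stage.  Values are floored at
    one-tenth of the expression threshold so an all-zero prefix does not
    self-trigger.  Without a sampled EB/LB plus at least one earlier stage,
    the result is "not evaluable" rather than an exception.
    """
    thr = thr or Thresholds()
    floor = thr.nrpm_threshold / 10.0
    obs = profile.observed()
    by_stage = {s: max(v, floor) for s, v in obs}
    evaluable = False
    for candidate in ("EB", "LB"):
        if candidate not in by_stage:
            continue
        earlier = [
            by_stage[s]
            for s in by_stage
            if STAGE_INDEX[s] < STAGE_INDEX[candidate]
        ]
        if not earlier:
            continue
        evaluable = True
        if by_stage[candidate] >= fold_threshold * min(earlier):
            return MztUpswing(evaluable=True, flagged=True, stage=candidate)
    return MztUpswing(evaluable=evaluable, flagged=False, stage=None)


def unified_profiles(profile: NormalizedProfile) -> list[UnifiedProfile]:
    """Shortcut for profiles whose columns already use unified stage names."""
    return harmonize_stages(
        profile, StageMap.identity(profile.species, profile.stages)
    )
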