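"""Synthetic expression data with known ground truth.

The bulk generator emulates the statistical structure the downstream
analysis assumes for an early sea urchin embryo time course:

* **maternal** transcripts deposited in the egg and decaying
  exponentially after fertilization, M(t) = M0·exp(−k·t);
* **zygotic** transcripts switched on around the blastula stage by the
  maternal-to-zygotic transition, rising as a delayed saturating
  exponential Z(t) = A·(1 − exp(−r·(t − t_on))) for t ≥ t_on and exactly
  zero before;
* **mixed** transcripts carrying both components (the classic U-shape);
* **absent** transcripts with nothing but the noise floor;
* **housekeeping** genes constant over time, spanning a fixed spread of
  magnitudes whose geometric mean is exactly the per-species reference
  level H0, so that at zero noise the computed normalization denominator
  equals H0 times the per-stage library scale exactly.

Latent trajectories are written on the NRPM scale (multiples of the
housekeeping geometric mean); the observed table multiplies by H0, a
per-stage library-size factor c_s and multiplicative lognormal noise.
The per-stage factor cancels under normalization by construction — that
cancellation is itself a tested invariant.

The onset time for a zygotic onset stage is the midpoint between that
stage's hours-post-fertilization and the previous available stage's, so
the onset-stage sample already carries accumulated zygotic signal while
all strictly earlier samples carry none.

The single-cell generator assigns cells to near-equal clusters and gives
each gene a per-cell detection probability p, inflated by a fold factor
inside a target cluster for enriched genes; counts of expressing cells
are 1 + Poisson so detection probabilities are exact.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionTable, Unit, load_builtin_stage_map
from .single_cell import CellExpressionMatrix, ClusterAssignment

#: Reference housekeeping magnitudes per species, matched in order of
#: magnitude to the published per-stage normalization denominators so that
#: synthetic tables look like the real datasets.  Cosmetic, not inferential.
DEFAULT_H0 = {
    "M. franciscanus": 1500.0,
    "P. lividus": 100.0,
    "L. variegatus": 4500.0,
    "S. purpuratus": 5000.0,
}

DEFAULT_CLASS_COUNTS = {
    "maternal": 165,
    "zygotic": 165,
    "mixed": 110,
    "absent": 55,
    "housekeeping": 5,
}

_HKG_NAMES = ("GAPDH", "ODC", "HPRT")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the bulk generator; defaults are the study conditions.

    ``decay_rate`` is per hour (default 0.15/h, a maternal half-life of
    ~4.6 h); ``rise_rate`` is the zygotic accumulation rate (1/h);
    ``m0_range`` and ``amplitude_range`` are NRPM-scale uniform sampling
    intervals for the maternal baseline and zygotic amplitude; ``noise_cv``
    is the coefficient of variation of the multiplicative lognormal noise.
    ``stage_grid`` overrides the per-species sampling grid as
    (unified_stage, hpf) pairs; None means the species' built-in grid with
    its genuinely missing stages, so generated data exercise gap handling.
    """

    seed: int = 0
    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    stage_grid: tuple[tuple[str, float], ...] | None = None
    decay_rate: float = 0.15
    onset_stage: str = "LB"
    rise_rate: float = 1.0
    m0_range: tuple[float, float] = (0.1, 3.0)
    amplitude_range: tuple[float, float] = (0.3, 3.0)
    h0: float | None = None
    hkg_multipliers: tuple[float, ...] = (0.5, 1.0, 2.0)
    noise_cv: float = 0.1
    stage_scale: Mapping[str, float] | None = None
    noise_floor: float = 0.0
    unit: Unit = Unit.RPM

    def __post_init__(self) -> None:
        for name, n in self.n_per_class.items():
            if name not in DEFAULT_CLASS_COUNTS:
                raise ValueError(f"unknown gene class {name!r}")
            if n < 0:
                raise ValueError(f"negative count for class {name!r}")
        if self.decay_rate <= 0 or self.rise_rate <= 0:
            raise ValueError("rates must be positive")
        if not (0 < self.m0_range[0] <= self.m0_range[1]):
            raise ValueError("invalid m0_range")
        if not (0 < self.amplitude_range[0] <= self.amplitude_range[1]):
            raise ValueError("invalid amplitude_range")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        if self.h0 is not None and self.h0 <= 0:
            raise ValueError("h0 must be positive")
        if any(m <= 0 for m in self.hkg_multipliers):
            raise ValueError("hkg multipliers must be positive")
        if self.stage_scale is not None and any(
            c <= 0 for c in self.stage_scale.values()
        ):
            raise ValueError("stage scale factors must be positive")


@dataclass
class SyntheticTruth:
    """Ground-truth class label and latent parameters per generated gene."""

    params: dict[str, dict]

    def gene_class(self, gene: str) -> str:
        return self.params[gene]["class"]

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, p in self.params.items() if p["class"] == cls]


def _resolve_grid(
    config: GeneratorConfig, species: str
) -> list[tuple[str, float]]:
    if config.stage_grid is not None:
        grid = list(config.stage_grid)
    else:
        sm = load_builtin_stage_map(species)
        grid = [
            (e.unified_stage, float(e.hpf))
            for e in sm.entries
            if e.available and e.hpf is not None
        ]
    if len(grid) < 3:
        raise ValueError("stage grid needs at least 3 stages")
    return grid


def _onset_time(grid: list[tuple[str, float]], onset_stage: str) -> float:
    stages = [s for s, _ in grid]
    if onset_stage not in stages:
        raise ValueError(f"onset stage {onset_stage!r} not in grid {stages}")
    i = stages.index(onset_stage)
    t_on = grid[i][1]
    if i == 0:
        return t_on
    return 0.5 * (grid[i - 1][1] + t_on)


def latent_trajectory(
    cls: str,
    times: np.ndarray,
    m0: float,
    amplitude: float,
    t_onset: float,
    config: GeneratorConfig,
    hk_level: float = 1.0,
) -> np.ndarray:
    """Closed-form noise-free latent NRPM trajectory for one gene."""
    times = np.asarray(times, dtype=float)
    maternal = m0 * np.exp(-config.decay_rate * times)
    zygotic = np.where(
        times >= t_onset,
        amplitude * (1.0 - np.exp(-config.rise_rate * (times - t_onset))),
        0.0,
    )
    if cls == "maternal":
        return maternal
    if cls == "zygotic":
        return zygotic
    if cls == "mixed":
        return maternal + zygotic
    if cls == "absent":
        return np.zeros_like(times)
    if cls == "housekeeping":
        return np.full_like(times, hk_level)
    raise ValueError(f"unknown class {cls!r}")


def generate_bulk_dataset(
    config: GeneratorConfig, species: str
) -> tuple[ExpressionTable, SyntheticTruth]:
    """Gene × stage table for one species plus its ground truth.

    Columns use unified stage names (the species' built-in grid drops its
    genuinely unsampled stages).  Observed value = (latent NRPM +
    noise floor) × H0 × c_s × lognormal multiplicative noise; with
    ``noise_cv`` 0 the table equals the closed-form latent trajectories
    exactly.
    """
    grid = _resolve_grid(config, species)
    try:
        from .io import canonical_species

        sp = canonical_species(species)
    except KeyError:
        sp = species
    h0 = config.h0 if config.h0 is not None else DEFAULT_H0.get(sp, 1000.0)
    t_on = _onset_time(grid, config.onset_stage)
    times = np.array([t for _, t in grid])
    stage_names = [s for s, _ in grid]
    c_s = np.array(
        [
            (config.stage_scale or {}).get(s, 1.0)
            for s in stage_names
        ]
    )
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    rng = np.random.default_rng(config.seed)

    genes: list[str] = []
    latents: list[np.ndarray] = []
    truth: dict[str, dict] = {}
    hk_counter = 0
    for cls in ("maternal", "zygotic", "mixed", "absent", "housekeeping"):
        n = int(config.n_per_class.get(cls, 0))
        for i in range(n):
            if cls == "housekeeping":
                name = (
                    _HKG_NAMES[hk_counter]
                    if hk_counter < len(_HKG_NAMES)
                    else f"HK{hk_counter + 1}"
                )
                hk_level = config.hkg_multipliers[
                    hk_counter % len(config.hkg_multipliers)
                ]
                hk_counter += 1
                m0 = amp = 0.0
            else:
                name = f"{cls}_{i + 1:04d}"
                hk_level = 0.0
                m0 = float(rng.uniform(*config.m0_range))
                amp = float(rng.uniform(*config.amplitude_range))
            genes.append(name)
            latents.append(
                latent_trajectory(cls, times, m0, amp, t_on, config, hk_level)
            )
            truth[name] = {
                "class": cls,
                "m0": m0,
                "amplitude": amp,
                "t_onset": t_on,
                "hk_level": hk_level,
            }
    if not genes:
        raise ValueError("no genes configured")

    latent = np.vstack(latents)  # genes x stages, NRPM scale
    noise = (
        np.exp(rng.normal(0.0, sigma, size=latent.shape))
        if sigma > 0
        else np.ones_like(latent)
    )
    observed = (latent + config.noise_floor) * h0 * c_s[None, :] * noise
    table = ExpressionTable(
        species=sp,
        unit=config.unit,
        values=pd.DataFrame(
            observed, index=pd.Index(genes, name="gene"), columns=stage_names
        ),
    )
    return table, SyntheticTruth(params=truth)


def generate_single_cell_dataset(
    seed: int,
    n_cells: int,
    n_clusters: int,
    enriched: Sequence[tuple[str, int, float]] = (),
    n_uniform_genes: int = 200,
    p_express: float = 0.1,
    count_mean: float = 2.0,
) -> tuple[CellExpressionMatrix, ClusterAssignment, SyntheticTruth]:
    """Cells × genes count matrix with cluster labels and ground truth.

    Uniform genes are detected in each cell with probability ``p_express``
    regardless of cluster; an entry (gene, cluster, fold) makes that
    gene's detection probability ``p_express * fold`` inside the target
    cluster.  Counts for expressing cells are 1 + Poisson(count_mean).
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if n_cells < 10 * n_clusters:
        raise ValueError("need at least 10 cells per cluster on average")
    if not 0 < p_express <= 1:
        raise ValueError("p_express must be in (0, 1]")
    for gene, cluster, fold in enriched:
        if fold <= 0:
            raise ValueError(f"fold for {gene!r} must be positive")
        if not 0 <= cluster < n_clusters:
            raise ValueError(f"cluster {cluster} out of range for {gene!r}")
        if p_express * fold > 1:
            raise ValueError(
                f"p_express*fold = {p_express * fold:.3g} > 1 for {gene!r}"
            )

    rng = np.random.default_rng(seed)
    labels = np.arange(n_cells) % n_clusters
    rng.shuffle(labels)
    clusters = ClusterAssignment(labels=labels, n_clusters=n_clusters)

    gene_specs: list[tuple[str, int | None, float]] = [
        (f"null_{i + 1:04d}", None, 1.0) for i in range(n_uniform_genes)
    ] + [(g, c, f) for g, c, f in enriched]

    counts = np.zeros((n_cells, len(gene_specs)), dtype=int)
    truth: dict[str, dict] = {}
    for j, (gene, cluster, fold) in enumerate(gene_specs):
        p = np.full(n_cells, p_express)
        if cluster is not None:
            p[labels == cluster] = p_express * fold
        expressing = rng.random(n_cells) < p
        counts[expressing, j] = 1 + rng.poisson(count_mean, int(expressing.sum()))
        truth[gene] = {
            "class": "uniform" if cluster is None else "enriched",
            "cluster": cluster,
            "fold": fold,
            "p_express": p_express,
        }
    matrix = CellExpressionMatrix(
        cells=[f"cell_{i + 1:05d}" for i in range(n_cells)],
        genes=[g for g, _, _ in gene_specs],
        counts=counts,
    )
    return matrix, clusters, SyntheticTruth(params=truth)
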