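# Methods

## Normalization model

Each input is a gene × stage abundance table for one species, in whatever
per-sample-scaled unit the source pipeline produced (RPM, FPKM, TPM) or in
raw counts. These units are not comparable across datasets, and even
within one dataset the effective library scale can drift between
developmental time points (total-RNA protocols are known to inflate
apparent post-fertilization abundances). The package therefore normalizes
each stage against an internal reference: the geometric mean of three
housekeeping genes, GAPDH, ODC and HPRT (the set is a parameter,
`HousekeepingSet`, minimum two genes), chosen for being robustly expressed
and annotated in all datasets of interest.

NRPM(g, s) = x(g, s) / GHG(s), GHG(s) = exp(mean(log xᵢ(s))).

The geometric mean is computed in log space — overflow-safe and exact for
the fixed-point property tests. Two algebraic consequences are tested as
invariants rather than examples: the housekeeping genes' own NRPM values
have geometric mean exactly 1 at every stage, and multiplying all genes
at one stage by any positive constant leaves every NRPM at that stage
unchanged. The second property is the entire justification for
cross-dataset comparison.

Stages where any housekeeping gene is missing or non-positive are
excluded from the GHG profile with a warning record instead of failing
the run; real datasets have such stages, and the analysis proceeds on
what is available. Only when no stage survives is it an error.

NRPM is not length-corrected across genes. Comparisons are of a gene with
itself across stages and species, where per-stage scaling cancels;
cross-gene magnitude comparisons (which the stream plots invite) remain
unit-confounded and should be read accordingly.

## Expression threshold

A transcript is EXPRESSED at a stage when NRPM ≥ 0.003 "GHG multiples".
The value corresponds to roughly 300 transcripts per embryo, which is
approximately FPKM 5 in the reference *S. purpuratus* dataset; that single
published equivalence fixes the default absolute↔source-unit calibration
factor of 1/60 in `convert_threshold`, and the factor is dataset-specific
and caller-overridable. The 0.003 figure is taken verbatim rather than
re-derived: it is not exactly 5 divided by any one published per-stage
GHG value, and which denominator produced it is not stated, so re-deriving
it would be false precision. The comparison is inclusive (≥): values *below*
the threshold are excluded, so the boundary itself is kept. Missing
measurements propagate as MISSING calls; they are never imputed as zero,
because "not detected in the transcriptome" and "measured low" are
different observations.

## Stage harmonization

The five unified stages EC < LC < EB < LB < EG cover the window from
first cleavage to early gastrulation — the span of the maternal-to-zygotic
transition (MZT), whose major wave in sea urchins occurs around the
blastula stage. The shipped per-species sampling table (native label,
unified stage, hours post fertilization) has 20 cells, of which two are
genuinely unsampled: *M. franciscanus* EB and *P. lividus* LC. "Egg" and
1 hpf samples both map to EC. Harmonization is pure re-indexing: values
are bit-for-bit unchanged, unsampled unified stages become gaps, and a
native label absent from the map is an error naming the label.

## Dynamics classification

Classification is descriptive, not inferential — the source time courses
have no replicates, so there is nothing to test; the same is true of the
published analyses this workflow supports.

For the non-missing stages in temporal order:

1. all calls NEGLIGIBLE → ABSENT;
2. first EXPRESSED stage at EB or later with every earlier sampled stage
   NEGLIGIBLE → LATE_ONSET (zygotic-only product);
3. otherwise, consecutive ratios rᵢ = vᵢ₊₁/vᵢ are computed on values
   floored at one-tenth of the expression threshold (avoids infinite
   ratios at zero while preserving ordering). A move is |log₂ rᵢ| ≥
   log₂(fold_threshold), ties counting as moves for consistency with the
   inclusive expression threshold. No moves → FLAT; all moves down →
   MATERNAL_DECLINE; first move down with a later move up → U_SHAPED;
   first move up → PEAK_INTERIOR.

The fold threshold defaults to 2.0. Published narrations of these
dynamics speak of "more than threefold", "six-fold", "order of magnitude"
changes without defining a minimal step; 2.0 is the loosest value
consistent with all of them and is an explicit parameter. Grouping a
monotone rise from an expressed baseline into PEAK_INTERIOR (rather than
adding a seventh label) keeps the taxonomy closed; such trajectories are
rises driven by zygotic gain on a maternal baseline, and the separate MZT
flag captures what matters about them. Profiles with fewer than three
sampled stages are classified on what is there and flagged
`insufficient_stages` instead of raising — two of the four reference
species have only four usable stages, and robustness to gaps is a tested
property (deleting the EB column from a declining cohort can coarsen a
MATERNAL_DECLINE to FLAT but never contradict it).

The MZT upswing detector is deliberately simpler than the classifier: the
flag is set when the EB or LB value is at least fold_threshold times the
minimum over all strictly earlier sampled stages (floored values, earliest
qualifying stage reported). Without a sampled EB/LB plus at least one
earlier stage the result is "not evaluable", not an exception.

## Cross-species comparison

Per system, the comparison matrix has one row per catalog gene and one
column per species; a species lacking the gene in its table gets an empty
cell. "Ever expressed" means EXPRESSED at ≥ 1 unified stage within EC–EG:
genes switching on only after gastrulation are absent for the
early-embryo question. Conservation classes are a pure function of
(n_expressed, n_with_data): NOT_DETECTED (0), CONSERVED_ALL (all, with at
least 3 species contributing data — "all of two" is uninformative, and the
minimum is configurable), SPECIES_SPECIFIC (exactly 1), MAJORITY
(otherwise); the implementation is checked exhaustively against a
brute-force truth table.

The stream plots use the NRPM value itself as band half-width: the source
tables carry no replicate spread, so there is no defined range to draw.
The scale is shared across a system's genes, linear by default with a
log10(1 + NRPM/threshold) option, since observed NRPM spans roughly
0.003–5000. Reports are emitted as JSON validated by the shipped pydantic
schema models and round-trip losslessly.

## Single-cell enrichment

Spatial information comes from an external cells × genes count matrix
with precomputed cluster labels (clustering, embedding and QC are out of
scope — labels are inputs). Enrichment is defined on detection, not mean
counts: at the low per-cell abundances of early embryo transcripts,
presence/absence is the robust signal. For each cluster, the expressing
fraction (count > 0), a fold enrichment over the rest with add-one
smoothing on expressing-cell counts, a one-vs-rest hypergeometric
upper-tail p-value on the expressing-cell overlap, and a
Benjamini–Hochberg q-value across the gene's clusters. A cluster is
enriched when fold ≥ 2 and q ≤ 0.05 (both configurable); no cluster
passing → UNIFORM, the maternal-reservoir signature; fewer than 20
expressing cells total → NO_CALL rather than an unstable estimate. The
hypergeometric tail is validated against exact integer enumeration on
small instances, and empirical type-I control is tested on simulated null
genes.

## Synthetic data

The generator encodes the data-generating process the analysis assumes;
its defaults are the study conditions for all recovery tests.

Latent trajectories are written on the NRPM scale:

- maternal: M(t) = M0·exp(−k·t), k = 0.15/h (half-life ≈ 4.6 h),
  M0 ~ U(0.1, 3);
- zygotic: Z(t) = A·(1 − exp(−r·(t − t_on))) for t ≥ t_on, exactly 0
  before; r = 1/h, A ~ U(0.3, 3); the onset stage defaults to LB and t_on
  is the midpoint between the onset stage's hpf and the previous
  available stage's, so the onset-stage sample carries accumulated signal
  while all strictly earlier samples carry none (activation is a process
  "around the blastula stage", not an instant at the sampling time);
- mixed: M(t) + Z(t) — the classic U-shape;
- absent: zero (an optional additive noise floor, default 0, models
  background);
- housekeeping: constant levels 0.5, 1, 2 (cycled), whose geometric mean
  is exactly 1, so at zero noise the computed GHG equals H0·c_s exactly —
  a tested closed form.

Observed value = (latent + floor) × H0 × c_s × lognormal noise, with H0 a
per-species constant matched in magnitude to the published reference
denominators (cosmetic realism only), c_s an arbitrary per-stage library
scale (its cancellation under normalization is a tested invariant), and
lognormal σ = sqrt(log(1 + CV²)), CV defaulting to 10%. Per-species stage
grids copy the shipped sampling table including its genuine gaps, so
synthetic data exercise missing-stage handling. The default cohort is 165
maternal + 165 zygotic + 110 mixed + 55 absent + 5 housekeeping = 500
genes. Everything is a deterministic function of the seed
(`numpy.random.default_rng`).

The functional forms are the generator's own choice — the underlying
biology is described qualitatively in the literature, not modeled — and
were picked for closed-form testability. What the generator does **not**
emulate: count noise at low abundance (noise is purely multiplicative),
transcript-length effects, isoform structure, correlated noise between
stages, or the technical post-fertilization inflation reported for
total-RNA libraries (a documented extension point, off by default).
Passing recovery tests therefore demonstrate correctness of the pipeline
under its own assumptions, not robustness to every artifact of real
libraries.

The single-cell generator assigns cells to K near-equal clusters
(shuffled), gives each gene a per-cell detection probability p (default
0.1), inflated by a fold factor inside the target cluster for enriched
genes (error if p·fold > 1), and draws counts for expressing cells as
1 + Poisson(2), making detection probabilities exact.

## Problem sizes and numerical choices

Recovery experiments use the default 500-gene cohort on the
*S. purpuratus* grid (the reference species, all five stages sampled) and
a 2000-cell × 20-cluster single-cell matrix with 200 null genes — sizes at
which the binomial noise on the reported rates is well below the margins
being checked, while the full test suite and the acceptance script each
run in seconds. Tolerances: fixed-point and scale-invariance checks at
1e-12 (pure float round-off); published-value round-trips at three
decimal places (the printed precision); rate thresholds (95% recovery,
90% flag rates, 5% false positives) with no tuning margin. Ratio
computations floor values at threshold/10; boundary ties count as moves
and as expressed, consistently inclusive.

## Known limitations

- The dynamics taxonomy is a deterministic rule set, not a fitted model;
  trajectories hovering near a fold boundary flip label under small
  perturbations, which is inherent to any thresholded description.
- Conservation classes treat species as exchangeable; no phylogenetic
  weighting is attempted (the published comparison found no clear
  phylogenetic trends at this depth).
- The single-cell statistic conditions on the observed number of
  expressing cells and ignores count depth per cell; it is the minimal
  standard construction, swappable via configuration.
- Cross-gene NRPM magnitudes remain confounded by transcript length and
  annotation quality; only within-gene comparisons are fully supported by
  the normalization algebra.
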