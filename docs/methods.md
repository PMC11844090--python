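# Methods

This note documents the models, parameter choices and numerical
behaviour of `gliamorph`, and what the synthetic-data validation does
and does not establish about real tissue.

## The analysis model

The pipeline treats a 2D multiplexed IHC field as a set of microglial
*territories*. Total microglial signal is the **master mask**: the
pixelwise union of per-marker foregrounds obtained by local-mean
adaptive thresholding (square window, reflected borders, additive
offset). The exact thresholding operator of the commercial software
this workflow descends from is unpublished; local mean + offset is the
simplest operator that is adaptive to uneven illumination, and both the
window (default 20 µm half-width) and offset (default 20 intensity
units) are configuration values. pTDP-43 aggregates are isolated with a
plain clip threshold (default 400), since aggregate signal is bright
and sparse rather than shading-limited.

**Territories.** Somata are detected from the Iba1 channel (local
median background + offset, morphological opening with a disk of the
maximum process half-width to erase processes, minimum-area filter;
fused blobs wider than `max_body_width_um` are split by watershed on
the distance transform). The ROI is then partitioned by a
marker-controlled watershed on the negated Euclidean distance to the
nearest soma pixel. This is a *territory* model — a Voronoi-like
tessellation of soma regions — rather than intensity-basin flooding,
because the single-cell measurements need each cell and its processes
contained within one border; one-pixel watershed lines carry label 0
and are excluded from all measurements. On fixtures with ≥ 20 µm soma
separation the partition agrees with brute-force nearest-seed labeling
on ≥ 99.9% of master-mask pixels (the two differ only at equidistance
ties).

An alternative reading — watershed applied to the master mask itself to
split touching blobs — was considered and rejected: it cannot assign
detached (beaded) process fragments to a parent cell, which the
territory model does naturally. Cells whose soma touches the ROI border
are flagged and excluded from single-cell statistics.

**Morphometry.** Within each domain the process mask is
above-background Iba1 minus the soma, width-limited to
`max_process_width_um`; it is skeletonized by thinning. Terminal twigs
shorter than `spur_prune_um` (default 1.1 µm) hanging off junctions are
pruned as rasterization artefacts; skeleton components shorter than
`min_process_length_um` (default 1.0 µm) are discarded. Features per
cell:

* *cell body area* — soma pixel count × pixel area;
* *process number* — count of surviving skeleton components in the
  domain (rooted or detached). Detached fragments are owned by the
  domain they lie in; no gap-bridging is attempted, since any bridging
  rule would be invented;
* *total outgrowth* — skeleton length with 1/√2 step weights. Diagonal
  steps short-circuited by an orthogonal neighbour are not counted
  (corner double-count guard). The 1/√2 convention makes axis-aligned
  and 45° paths exact and overestimates intermediate orientations by up
  to ~8%; bias-corrected estimators were deliberately not used because
  the 1/√2 weights are the documented contract of the measurement;
* *branch number* — connected clumps of skeleton pixels with ≥ 3
  skeleton neighbours; a clump counts once (a degree-4 node is one
  branch point). "Process number" follows the primary-process
  convention (root-incident components, not all segments); this is the
  main open interpretation in the feature set and is noted as such.

Tissue-wide morphology is the unweighted mean over cells per case.

**Intensities** are raw: no background subtraction, no inter-case
normalisation (a hook exists, default off). Integrated intensity is the
pixel-area-weighted sum over mask ∩ ROI divided by ROI area, so a
uniform intensity c covering area A in ROI R gives c·A/R, independent
of the pixel grid. Per-cell marker means are taken over
(domain ∩ master mask); cells with no master-mask pixel in their domain
are dropped with a log entry.

**Clustering.** Features (four morphology measures + mean Iba1, CD68
and, by default, HLA-DR when present) are transformed x → ln(x+1).
Natural log with pseudocount 1 is used because counts can be zero and
no base is canonical; the log alone provides the "equal weighting" —
no z-scoring is applied by default (a `standardize` flag exists). The
KNN graph uses Euclidean distance, k = ⌊√N⌋ (floor, since no rounding
rule is canonical), symmetrized by union, unweighted; mutual-kNN is
available as config. Distance ties are broken by cell index in the
exact small-N search; the tree-based search at scale resolves ties
arbitrarily, which matters only for exactly duplicated points. Louvain
(igraph `community_multilevel`) optimises modularity at resolution 1.0;
igraph draws randomness from Python's `random`, so a seed makes the
partition deterministic. Clusters are renumbered by decreasing size.
Subsampling before clustering is balanced exactly (default 7,340 cells
per group) and seeded.

*Known behaviour:* modularity optimisation carries a resolution limit —
at resolution 1.0 the favoured community size grows like √m with graph
edges m, so large homogeneous classes are split into class-pure
sub-communities rather than recovered whole. On the default three-class
synthetic cohort at N = 3,000 (k = 54) this yields ~9 communities with
~99.9% class purity but an ARI vs the three coarse classes of ~0.45;
the same scaling at N ≈ 22,000 predicts ~11 communities from three
morphology archetypes. Consumers who need archetype-level recovery
should compare partitions by purity/completeness or merge communities
by phenotype, not expect ARI ≈ 1 against a coarse labelling.

**Statistics.** Mann-Whitney U is two-sided; the exact null is used
when both n ≤ 8 without ties (the n=3+3 exact two-sided p for fully
separated samples is 2/20 = 0.10, verified by enumeration), otherwise
the tie-corrected normal approximation. The BKY two-stage adaptive
step-up is implemented directly (stage 1 at q′ = q/(1+q); m₀ = m − r₁;
stage 2 at q′·m/m₀) and is cross-checked in tests against both a
brute-force transcription and `statsmodels` `fdr_tsbky`; families are
formed per measure panel, recorded in the output. Spearman uses average
ranks with two-sided p; strength classes are strong (|r| ≥ 0.7),
moderate (0.4 ≤ |r| < 0.7), both gated at p ≤ 0.05. The mouse design
uses Type II sums of squares (unequal group sizes, n = 3–6 per cell)
with Tukey HSD on genotype within each timepoint; a constant response
is reported as F = 0 with no significant pairs. Dunn's post-hoc uses
tie-corrected rank-sum z statistics with Bonferroni adjustment (the
convention of the common commercial packages; configurable). SDs are
sample (n−1) throughout, validated against the bundled cohort table's
printed values.

## The synthetic tissue model

Each cell is a soma disk plus a forest of process polylines rooted on
the soma perimeter, grown radially outward with collision checking
(segments keep ≥ 1.6 µm clearance from non-adjacent segments; branch
opening angles 50–80°), so the drawn geometry's topology survives
rasterization and the per-cell truth (exact component count, junction
count, summed drawn length, π r² soma area) equals an independent
re-measurement of the stored geometry. Dystrophic beading inserts
2 µm mid-segment gaps; a triggered gap lengthens a too-short segment to
the minimum fragmentable length, so "every segment carries a gap" holds
at fragmentation probability 1. The truth table stores both the
post-gap component count (`true_process_number`, what a
domain-restricted measurement sees) and the pre-gap primary count
(`true_primary_processes`).

Class defaults — soma radius 3/6/3 µm, 4–6/3–5/2–4 primaries, branch
probability 0.6/0.2/0.2, fragmentation 0/0/0.5 for
ramified/hypertrophic/dystrophic, CD68 means 40/150/125 and Iba1 means
120/210/180 (lognormal, CV 0.25) — encode the qualitative class
descriptions (no quantitative geometric boundary between hypertrophic
and dystrophic exists in the literature; the classes are separated here
by soma size and fragmentation). Segment lengths (≈ 4.5–6 µm) are
scaled to the territory cap: process extent is limited to half the
nearest-neighbour soma distance minus a 2.5 µm margin, so processes
never cross watershed boundaries. Group structure is a class-mixture
shift (control 85/10/5% → stage-4-like 35/35/30%) plus group-conditional
pTDP-43 aggregate density (0 / 60 / 220 mm⁻²).

Rendering: 0.32 µm pixels (typical 20×/0.9 NA sampling) on 800×800
frames, 16–20 cells per frame (≈ 260 cells/mm², cortical-range
density), ≥ 20 µm soma separation, anti-aliasing off. Processes are
one-pixel lines (0.25 µm half-width — fine distal processes); somata
and nuclei are filled disks; CD68 renders as perinuclear puncta plus
diffuse somal signal; pTDP-43 as bright round aggregates. Noise is a
constant background (15) plus Gaussian read noise (sd 12, soma SNR ≈ 10
at the dimmest class) with optional Poisson shot noise; no PSF
simulation. A feature-level sampler (`sample_cell_features`) draws the
same class-conditional features without rasterization for experiments
needing thousands of cells.

**What passing tests show — and don't.** Exact count recovery and
percent-level area/outgrowth agreement on noise-free renders validate
the measurement chain (thresholds → watershed → skeleton → features) as
an algorithm. They do not validate antibody specificity, uneven
illumination beyond the adaptive-threshold model, overlapping cells,
out-of-focus light, 3D structure collapsed into 2D, or rod/amoeboid
morphologies (not modelled). Direction-of-effect checks on noisy
cohorts show the pipeline preserves generative group contrasts at
realistic SNR; effect sizes on real tissue are not predicted by these
numbers.

## Numerical and degenerate-input choices

* Local background for soma/process detection is a tile-median surface
  (window-sized tiles, bilinear upsampling) — robust to bright somata
  and much faster than a sliding median.
* Foreground connectivity is 8-connected everywhere.
* Zero somata in a ROI yields an empty domain map with a warning, not
  an error; an empty case yields missing tissue-morphology values with
  a log entry.
* Single-pixel process specks are removed before thinning; a constant
  image thresholds to empty; clip thresholds are monotone in the
  threshold by construction.
* All randomness flows from explicit integer seeds (cohort seed →
  per-case child seeds via `SeedSequence.spawn`; clustering seed
  default 20250221); identical spec + seed reproduces bit-identical
  images, tables and partitions, and the run manifest records the
  config hash and seeds.
* Problem sizes in the validation suite (18-case noise-free cohorts of
  ~330 cells, 12-case noisy cohorts, N = 3,000 clustering runs) were
  chosen so each check exercises the full pipeline at cohort scale
  while a complete run stays in the minutes range on one CPU.

## Limitations

* The adaptive-threshold and neurite-tracing operators are principled
  reconstructions of unpublished commercial tools, not re-implementations
  of their binaries; parameter values will not transfer verbatim.
* The territory watershed assumes one soma per territory; overlapping
  or touching somata are split by the distance-transform watershed but
  heavily confluent microglia will still merge.
* Chain-code length estimation biases outgrowth by up to +8% for
  orientations near 22.5°; on mixed-orientation cells the mean absolute
  error is ~4%.
* The clustering stage inherits the resolution limit of modularity (see
  above); cluster *count* is a function of N and k, not only of the
  underlying biology.
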