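# gliamorph

Single-cell microglial morphometry and immunophenotyping for multiplexed
fluorescence immunohistochemistry (IHC) of cortex — with a synthetic
tissue simulator so the entire pipeline is testable without any external
image data.

Microglia change both their shape and their protein expression as they
react to neurodegenerative pathology such as the phosphorylated TDP-43
(pTDP-43) aggregates found in ~97% of ALS brains: ramified cells (small
soma, complex processes) give way to hypertrophic (enlarged soma, reduced
process complexity) and dystrophic (small soma, beaded/fragmented
processes) states, with rising CD68 and Iba1. `gliamorph` quantifies this
at the single-cell level from 2D multi-channel images (Hoechst, pTDP-43,
HLA-DR, CD68, Iba1) and is aimed at quantitative neuropathology groups
who want an open, testable equivalent of the classic commercial
image-analysis workflows.

## What the pipeline computes

1. **Segmentation** — per-marker binary masks by local-mean adaptive
   thresholding; their union is the *master mask* of all microglial
   signal (human: HLA-DR ∪ CD68 ∪ Iba1; mouse: Iba1 alone); a clip
   threshold isolates pTDP-43 aggregates; a marker-controlled watershed
   on the distance-to-soma surface partitions the region of interest
   into one *territory (domain)* per cell.
2. **Morphometry** (Iba1 channel) — per cell: cell body area (µm²),
   process number (rooted skeleton components + detached fragments in
   the domain), total outgrowth (summed skeleton length, µm), and branch
   number (skeleton junctions, degree ≥ 3).
3. **Intensity** — tissue-wide integrated intensity of each marker over
   the master mask normalised to ROI area; per-cell mean intensities
   over (domain ∩ master mask).
4. **Phenotype clustering** — cells balanced across groups (default
   7,340 per group), features ln(x+1)-transformed, a union-symmetrized
   k-nearest-neighbour graph with k = ⌊√N⌋, Louvain community detection
   at resolution γ = 1.0; clusters summarised by phenotype means and
   per-case % abundance.
5. **Statistics** — Mann-Whitney U tests with the Benjamini–Krieger–
   Yekutieli two-stage adaptive FDR (q = 0.01); Spearman correlation
   matrices with strength classes (|r| ≥ 0.7 strong, ≥ 0.4 moderate, at
   p ≤ 0.05); two-way genotype × timepoint ANOVA (Type II) with Tukey
   HSD for mouse time-courses; Kruskal–Wallis + Dunn across clusters;
   demographics summaries (mean ± n−1 SD).

The synthetic module renders cohorts of multi-channel cortical fields
with per-cell ground truth (exact soma area, process/branch counts,
outgrowth, marker means), enabling parameter-recovery validation of
every stage.

## Worked example

```python
from gliamorph import pipeline, synthetic as syn
from gliamorph.config import AnalysisConfig

spec = syn.default_human_cohort(seed=2, n_control=1, n_stage4=1, n_stage13=0)
cohort = syn.render_cohort(spec)                       # images + truth
cells, tissue = pipeline.analyze_cohort(cohort, AnalysisConfig())
print(tissue[["case_id", "cd68_intensity", "cell_body_area",
              "total_outgrowth"]].round(2).to_string(index=False))
```

prints (noise-free render of the same seed):

```
      case_id  cd68_intensity  cell_body_area  total_outgrowth
   control_01            0.40           31.38            85.69
ALS_stage4_01            1.67           58.93            60.48
```

i.e. the ALS-like case shows ~4× the CD68 signal per unit tissue area,
~1.9× the mean soma area and ~30% less process outgrowth than the
control case — the hypertrophic/dystrophic shift the pipeline is built
to detect. On noise-free renders the per-cell process and branch counts
match the generator's ground truth exactly (100% of cells), and soma
area / outgrowth agree to within a few percent (rasterization error
only).

The bundled 20-case human cohort metadata reproduces its printed
summary statistics:

```python
from gliamorph import stats, datasets
print(stats.summarize_demographics(datasets.human_cohort_demographics()))
#          n  age_mean  age_sd  pmd_mean  pmd_sd sex_ratio
# control 10     62.60   10.95     24.15   11.06   5 M:5 F
# ALS     10     70.10   11.07     18.20   4.063   6 M:4 F
```

See `examples/` for narrative scripts covering each capability, and the
`gliamorph` CLI (`simulate`, `segment`, `cluster`, `stats`, `run-all`)
for shell-driven runs.

## Layout

```
src/gliamorph/    synthetic, segmentation, morphometry, intensity,
                  clustering, stats, pipeline, config, cli, datasets
tests/            unit + property tests and the validation suite
examples/         one narrative script per capability
docs/methods.md   models, parameters, numerical choices, limitations
```
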