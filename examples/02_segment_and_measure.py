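"""Segment one synthetic case and measure every microglia.

Produces the master mask (union of thresholded HLA-DR/CD68/Iba1), the
watershed domain partition seeded at detected somata, and the four
morphology features plus mean marker intensities per cell, then checks
the counts against the generator's ground truth.
"""

from dataclasses import replace

from gliamorph import pipeline, synthetic as syn
from gliamorph.config import AnalysisConfig

spec = syn.default_human_cohort(seed=2, n_control=1, n_stage13=0, n_stage4=1)
spec = replace(spec, noise=syn.NoiseModel(background=0.0, read_noise_sd=0.0))
cohort = syn.render_cohort(spec)
cfg = AnalysisConfig()

cells, tissue, matched = pipeline.analyze_cohort(cohort, cfg, match_truth=True)

case = cohort.cases[0]
print(f"case {case.case_id}: {len(matched[matched.case_id == case.case_id])} "
      f"cells measured")
cols = ["cell_id", "cell_body_area", "process_number", "total_outgrowth",
        "branch_number", "cd68", "iba1"]
print(cells[cells.case_id == case.case_id][cols].head(6).round(1).to_string(index=False))
print()

pn_exact = (matched["process_number"] == matched["true_process_number"]).mean()
bn_exact = (matched["branch_number"] == matched["true_branch_number"]).mean()
print(f"process count exact vs truth: {pn_exact:.0%}")
print(f"branch  count exact vs truth: {bn_exact:.0%}")
print()
print("tissue-wide measures (integrated intensity / ROI area, feature means):")
print(tissue.round(2).to_string(index=False))
# On noise-free renders the skeleton measurements reproduce the generated
# tree topology exactly; soma areas and outgrowth differ from truth only
# by rasterization (a few percent).
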