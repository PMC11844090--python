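"""End-to-end orchestration: images → masks → cells → clusters → stats.

Stage order is segmentation → morphometry → intensity → clustering →
statistics; every stage's output is persisted (16-bit TIFF label maps,
CSV tables) so stages are independently re-runnable, and a run manifest
records the configuration hash, seeds and file lists. Re-running with
the same inputs and seeds reproduces byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as clu
from . import intensity as inten
from . import morphometry as morph
from . import segmentation as seg
from . import stats as st
from . import synthetic as syn
from .config import AnalysisConfig

log = logging.getLogger("gliamorph")


# --------------------------------------------------------------------------
# per-case analysis


def analyze_case(
    channels: dict[str, np.ndarray],
    roi: np.ndarray,
    cfg: AnalysisConfig,
    case_id: str = "case",
    group: str = "",
):
    """Segment, measure and quantify one case.

    Returns a dict with the master mask, domain map, detected bodies,
    per-cell table (morphology + marker means, border cells flagged) and
    tissue-wide measures (integrated intensities + morphology means).
    """
    cfg.validate()
    px = cfg.pixel_size_um
    images = {
        name: seg.ChannelImage(arr, name, px) for name, arr in channels.items()
    }

    marker_masks = []
    for ch in cfg.master_channels:
        if ch not in images:
            raise ValueError(f"case {case_id!r} lacks channel {ch!r}")
        marker_masks.append(
            seg.adaptive_threshold(
                images[ch], cfg.threshold.adaptive_window_um,
                cfg.threshold.adaptive_offset, roi,
                cfg.threshold.min_object_area_um2)
        )
    master = seg.build_master_mask(marker_masks)

    ptdp_mask = None
    if "ptdp43" in images:
        ptdp_mask = seg.clip_threshold(images["ptdp43"],
                                       cfg.threshold.ptdp43_clip_min, roi)

    bodies = morph.detect_cell_bodies(images["iba1"], cfg.morph, roi)
    domains = seg.partition_domains(bodies.labels, roi)
    border = seg.flag_border_cells(bodies.labels, roi)
    skeletons = morph.trace_processes(images["iba1"], bodies, domains,
                                      cfg.morph, roi)
    cells = morph.measure_all_cells(bodies, skeletons, cfg.morph, px)

    # per-cell marker means within (domain ∩ master)
    means = {}
    for ch in set(cfg.master_channels) | {"iba1", "cd68"}:
        if ch in images:
            means[ch] = inten.per_cell_mean_intensity(images[ch], domains, master)

    rows = []
    for c in cells:
        row = {
            "cell_id": f"{case_id}_m{c.cell_id:03d}",
            "case_id": case_id,
            "group": group,
            "label": c.cell_id,
            "cell_body_area": c.cell_body_area,
            "process_number": c.process_number,
            "total_outgrowth": c.total_outgrowth,
            "branch_number": c.branch_number,
            "border_excluded": c.cell_id in border,
        }
        for ch, series in means.items():
            row[ch] = float(series.get(c.cell_id, np.nan))
        rows.append(row)
    cell_table = pd.DataFrame(rows)
    n_dropped = int(cell_table[[c for c in means]].isna().any(axis=1).sum())
    if n_dropped:
        log.info("%s: %d cells without master-mask signal dropped", case_id, n_dropped)
    cell_table = cell_table.dropna(subset=list(means))

    tissue = {"case_id": case_id, "group": group}
    for ch in cfg.master_channels:
        tissue[f"{ch}_intensity"] = inten.integrated_intensity(
            images[ch], master, roi)
    if ptdp_mask is not None:
        tissue["ptdp43_intensity"] = inten.integrated_intensity(
            images["ptdp43"], ptdp_mask, roi)
    measurable = cells and len(cell_table)
    if measurable:
        kept = [c for c in cells
                if c.cell_id in set(cell_table["label"]) and c.cell_id not in border]
        if kept:
            tissue.update(morph.tissue_wide_morphology(kept))
    log.info("%s: %d somata, %d domains, %d cells measured", case_id,
             bodies.n_cells, domains.n_domains, len(cell_table))

    return {
        "master": master,
        "ptdp43_mask": ptdp_mask,
        "bodies": bodies,
        "domains": domains,
        "cell_table": cell_table,
        "tissue": tissue,
    }


def analyze_cohort(cohort: syn.SyntheticCohort, cfg: AnalysisConfig,
                   match_truth: bool = False):
    """Run the per-case analysis over a rendered synthetic cohort.

    Returns (cell_table, tissue_table) pooled over cases, plus a
    truth-matched table when ``match_truth`` (measured cells joined to
    the generator's ground truth through the rendered soma label map).
    Border-flagged cells are excluded from the pooled single-cell table.
    """
    cell_tables, tissue_rows, matched = [], [], []
    for case in cohort.cases:
        res = analyze_case(case.channels, case.roi, cfg,
                           case_id=case.case_id, group=case.group)
        cell_tables.append(res["cell_table"])
        tissue_rows.append(res["tissue"])
        if match_truth:
            matched.append(
                _match_case(res["cell_table"], res["bodies"], case, cohort))
    cells = pd.concat(cell_tables, ignore_index=True)
    cells = cells[~cells["border_excluded"]].reset_index(drop=True)
    tissue = pd.DataFrame(tissue_rows)
    if match_truth:
        return cells, tissue, pd.concat(matched, ignore_index=True)
    return cells, tissue


def _match_case(cell_table, bodies, case, cohort) -> pd.DataFrame:
    """Join one case's measured cells to ground truth via the rendered
    soma label image at each detected soma centroid."""
    truth = cohort.truth[cohort.truth["case_id"] == case.case_id]
    rows = []
    for _, row in cell_table.iterrows():
        r, c = bodies.centroids[int(row["label"])]
        tl = int(case.soma_labels[int(round(r)), int(round(c))])
        if tl == 0:
            continue
        t = truth[truth["label"] == tl]
        if len(t) != 1:
            continue
        rec = row.to_dict()
        rec.update(t.iloc[0].to_dict())
        rows.append(rec)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# clustering + stats over the pooled cell table


def cluster_cells(cells: pd.DataFrame, cfg: AnalysisConfig,
                  per_group_n: int | None = None) -> clu.ClusterResult:
    """Balanced subsample → log transform → KNN graph → Louvain."""
    p = cfg.cluster
    if per_group_n is None:
        per_group_n = p.per_group_n
    sub = clu.balanced_subsample(cells, per_group_n, seed=p.seed)
    feature_cols = [c for c in clu.DEFAULT_FEATURES if c in sub.columns]
    if p.include_hladr and "hladr" in sub.columns:
        feature_cols.append("hladr")
    fm = clu.FeatureMatrix(values=sub[feature_cols],
                           cells=sub[["cell_id", "case_id", "group"]])
    fm = clu.log_transform(fm, pseudocount=p.pseudocount)
    if p.standardize:
        v = fm.values
        fm = clu.FeatureMatrix(values=(v - v.mean()) / v.std(ddof=0),
                               cells=fm.cells, transformed=True)
    k = None if p.knn_rule == "sqrt_floor" else cfg.cluster.per_group_n
    g = clu.build_knn_graph(fm, k=k, mutual=p.mutual)
    cr = clu.louvain_cluster(g, fm.cells, resolution=p.resolution, seed=p.seed)
    return clu.summarize_clusters(cr, sub[feature_cols])


def tissue_stats(tissue: pd.DataFrame, cfg: AnalysisConfig) -> dict:
    """Group comparisons + correlation matrix on case-level measures."""
    measures = [c for c in tissue.columns if c not in ("case_id", "group")]
    groups = list(tissue["group"].unique())
    comparisons = {}
    for m in measures:
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                x = tissue.loc[tissue["group"] == a, m].dropna()
                y = tissue.loc[tissue["group"] == b, m].dropna()
                if len(x) >= 2 and len(y) >= 2:
                    comparisons[f"{m}: {a} vs {b}"] = (x.to_numpy(), y.to_numpy())
    mw = st.mannwhitney_bky(comparisons, q=cfg.stats.fdr_q) if comparisons else []
    corr = None
    if len(tissue) >= 4 and len(measures) >= 2:
        corr = st.spearman_matrix(tissue[measures],
                                  moderate=cfg.stats.moderate_r,
                                  strong=cfg.stats.strong_r,
                                  alpha=cfg.stats.alpha)
    return {"mannwhitney": mw, "correlation": corr}


# --------------------------------------------------------------------------
# disk-level pipeline


def _stat_results_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": r.comparison, "test": r.test,
                "statistic": r.statistic, "p": r.p_value,
                "discovery": r.discovery, "stars": r.stars,
            }
            for r in results
        ]
    )


def run_pipeline(cfg: AnalysisConfig, out_dir, simulate: syn.CohortSpec | None = None,
                 input_dir=None, per_group_n: int | None = None) -> dict:
    """Run every stage and persist all outputs under ``out_dir``.

    Either ``simulate`` (a CohortSpec) or ``input_dir`` (a directory laid
    out as written by :func:`gliamorph.synthetic.write_cohort`) must be
    given. Returns the manifest dict.
    """
    import tifffile

    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    if simulate is not None:
        cohort = syn.render_cohort(simulate)
        syn.write_cohort(cohort, out / "simulated")
    elif input_dir is not None:
        cohort = load_cohort(input_dir)
    else:
        raise ValueError("provide a CohortSpec to simulate or an input_dir")

    cells, tissue = analyze_cohort(cohort, cfg)
    (out / "tables").mkdir(exist_ok=True)
    cells.to_csv(out / "tables" / "cells.csv", index=False)
    tissue.to_csv(out / "tables" / "tissue.csv", index=False)

    # label maps for the first case as a worked artefact of segmentation
    first = cohort.cases[0]
    res = analyze_case(first.channels, first.roi, cfg, first.case_id, first.group)
    (out / "masks").mkdir(exist_ok=True)
    tifffile.imwrite(out / "masks" / f"{first.case_id}_master.tif",
                     res["master"].pixels.astype(np.uint16) * 65535)
    tifffile.imwrite(out / "masks" / f"{first.case_id}_domains.tif",
                     res["domains"].labels.astype(np.uint16))

    min_group = cells.groupby("group").size().min()
    n_sub = per_group_n if per_group_n is not None else min(
        cfg.cluster.per_group_n, int(min_group))
    cr = cluster_cells(cells, cfg, per_group_n=n_sub)
    assign = cr.cells.copy()
    assign["cluster"] = cr.labels
    assign.to_csv(out / "tables" / "clusters.csv", index=False)
    cr.abundance.to_csv(out / "tables" / "cluster_abundance.csv")
    cr.feature_means.to_csv(out / "tables" / "cluster_phenotypes.csv")

    stats_out = tissue_stats(tissue, cfg)
    _stat_results_frame(stats_out["mannwhitney"]).to_csv(
        out / "tables" / "stats_mannwhitney.csv", index=False)
    if stats_out["correlation"] is not None:
        stats_out["correlation"].to_frame().to_csv(
            out / "tables" / "stats_spearman.csv", index=False)

    manifest = {
        "config_digest": cfg.digest(),
        "config": cfg.to_dict(),
        "seed": simulate.seed if simulate is not None else None,
        "cluster_seed": cfg.cluster.seed,
        "n_cases": len(cohort.cases),
        "n_cells": int(len(cells)),
        "n_clusters": cr.n_clusters,
        "per_group_n": n_sub,
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
        "elapsed_s": round(time.time() - t_start, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_cohort(input_dir) -> syn.SyntheticCohort:
    """Load a cohort from disk (layout of :func:`synthetic.write_cohort`)."""
    import tifffile

    root = Path(input_dir)
    metadata = pd.read_csv(root / "metadata.csv")
    truth_path = root / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    cases = []
    for _, row in metadata.iterrows():
        case_id = row["case_id"]
        with tifffile.TiffFile(root / "images" / f"{case_id}.tif") as tf:
            stack = tf.asarray()
            desc = json.loads(tf.pages[0].description)
        roi = tifffile.imread(root / "images" / f"{case_id}_roi.tif") > 0
        channels = {name: stack[i] for i, name in enumerate(desc["channels"])}
        cases.append(
            syn.SyntheticCase(
                case_id=case_id, group=row["group"], channels=channels,
                roi=roi, soma_centres_px=[],
                soma_labels=np.zeros_like(roi, dtype=np.int32),
                pixel_size_um=desc["pixel_size_um"])
        )
    spec = syn.CohortSpec(groups=(syn.GroupSpec("loaded", len(cases),
                                                {"ramified": 1.0}),))
    return syn.SyntheticCohort(spec=spec, cases=cases, metadata=metadata,
                               truth=truth)
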