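"""Group statistics for tissue-wide and single-cell microglial measures.

The statistical layer mirrors common practice in quantitative
neuropathology: nonparametric two-group comparisons with an adaptive
false-discovery-rate correction, Spearman correlation matrices with
effect-size strength classes, two-way factorial designs for the mouse
time-course, and Kruskal-Wallis/Dunn comparisons across phenotype
clusters.

Conventions
-----------
* Mann-Whitney U tests are two-sided; the exact null distribution is used
  when both samples have n <= 8 and there are no ties, otherwise the
  tie-corrected normal approximation.
* Multiplicity over a family of Mann-Whitney comparisons is controlled
  with the two-stage adaptive step-up FDR procedure of Benjamini, Krieger
  & Yekutieli (BKY) at q = 0.01 by default.
* Spearman correlations use average ranks; a correlation is called
  "strong" when |r| >= 0.7 and p <= 0.05, "moderate" when
  0.4 <= |r| < 0.7 and p <= 0.05, otherwise "none".
* Standard deviations are sample (n-1) SDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


# --------------------------------------------------------------------------
# result containers


@dataclass
class StatResult:
    """One statistical comparison."""

    comparison: str
    test: str
    statistic: float
    p_value: float
    discovery: bool | None = None
    group_ns: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    strength: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per variable pair (upper triangle)."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "strength": self.strength.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Render a p-value with the usual figure-legend star convention."""
    if np.isnan(p):
        return ""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


# --------------------------------------------------------------------------
# Mann-Whitney + BKY


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Returns (U for the first sample, two-sided p). Exact p when both
    n <= 8 and no value is shared between or within samples; normal
    approximation with tie correction and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bky_two_stage(p_values: Sequence[float], q: float = 0.01) -> np.ndarray:
    """Two-stage adaptive step-up FDR (Benjamini-Krieger-Yekutieli).

    Stage 1 runs a linear step-up at q' = q/(1+q); the number of
    non-rejections estimates the number of true nulls m0; stage 2 reruns
    the step-up at q'·m/m0. Returns a boolean discovery vector.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _linear_step_up(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    return _linear_step_up(p, q1 * m / m0)


def _linear_step_up(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up at level q."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1) / m)
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        reject[order[: k + 1]] = True
    return reject


def mannwhitney_bky(
    comparisons: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    q: float = 0.01,
) -> list[StatResult]:
    """Family of two-sided Mann-Whitney tests with BKY FDR control.

    ``comparisons`` maps a label (e.g. ``"CD68: control vs stage4"``) to
    the two group samples. Discovery flags are assigned jointly across the
    whole family at FDR level ``q``.
    """
    labels = list(comparisons)
    results = []
    for label in labels:
        x, y = comparisons[label]
        u, p = mann_whitney(x, y)
        results.append(
            StatResult(
                comparison=label,
                test="mann-whitney",
                statistic=u,
                p_value=p,
                group_ns=(len(x), len(y)),
            )
        )
    discoveries = bky_two_stage([r.p_value for r in results], q=q)
    for r, d in zip(results, discoveries):
        r.discovery = bool(d)
        r.extra["q"] = q
    return results


# --------------------------------------------------------------------------
# Spearman correlation matrix


def classify_correlation(
    r: float,
    p: float,
    moderate: float = 0.4,
    strong: float = 0.7,
    alpha: float = 0.05,
) -> str:
    """Strength class of a correlation: 'strong', 'moderate' or 'none'."""
    if np.isnan(r) or np.isnan(p):
        return "none"
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if p > alpha:
        return "none"
    if abs(r) >= strong:
        return "strong"
    if abs(r) >= moderate:
        return "moderate"
    return "none"


def spearman_matrix(
    measures: pd.DataFrame,
    moderate: float = 0.4,
    strong: float = 0.7,
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """Pairwise Spearman correlations between case-level measures.

    Rows are cases, columns are measures (e.g. pTDP-43 / HLA-DR / CD68 /
    Iba1 integrated intensities and the four morphology means). Each pair
    is correlated on pairwise-complete observations with average-rank
    Spearman r and a two-sided p; constant variables yield NaN.
    """
    cols = list(measures.columns)
    n = len(cols)
    if len(measures) < 4:
        raise ValueError("need at least 4 cases for a correlation matrix")
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    for i in range(n):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, n):
            sub = measures[[cols[i], cols[j]]].dropna()
            a = sub.iloc[:, 0].to_numpy(float)
            b = sub.iloc[:, 1].to_numpy(float)
            if len(sub) < 4 or np.all(a == a[0]) or np.all(b == b[0]):
                continue
            res = sps.spearmanr(a, b)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    strength = np.empty((n, n), dtype=object)
    for i in range(n):
        for j in range(n):
            strength[i, j] = classify_correlation(
                r[i, j], p[i, j], moderate=moderate, strong=strong, alpha=alpha
            )
    idx = pd.Index(cols)
    return CorrelationMatrix(
        variables=cols,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        strength=pd.DataFrame(strength, index=idx, columns=idx),
    )


# --------------------------------------------------------------------------
# two-way ANOVA + Tukey (mouse genotype x timepoint design)


def two_way_anova_tukey(
    data: pd.DataFrame,
    value: str,
    factor_a: str = "genotype",
    factor_b: str = "timepoint",
) -> dict:
    """Two-way ANOVA with interaction plus Tukey HSD within each level of
    ``factor_b``.

    Type II sums of squares are used so unbalanced cells (unequal mouse
    numbers per genotype/timepoint) are handled sensibly. Tukey HSD
    compares the levels of ``factor_a`` separately within each
    ``factor_b`` level, matching a genotype-within-timepoint contrast.

    Returns a dict with ``anova`` (DataFrame of F and p per term) and
    ``tukey`` (list of StatResult, one per pairwise contrast).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    d = data[[value, factor_a, factor_b]].dropna().copy()
    for fac in (factor_a, factor_b):
        levels = d[fac].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {fac!r} needs >= 2 levels")
    counts = d.groupby([factor_a, factor_b], observed=True).size()
    full = len(d[factor_a].unique()) * len(d[factor_b].unique())
    if len(counts) < full or (counts < 1).any():
        raise ValueError("empty factor cell in two-way design")

    d = d.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    if d["_y"].nunique() == 1:
        # constant response: all sums of squares vanish; report F = 0
        idx = ["C(_a)", "C(_b)", "C(_a):C(_b)", "Residual"]
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": [0.0, 0.0, 0.0, np.nan],
             "PR(>F)": [1.0, 1.0, 1.0, np.nan]}, index=idx)
        tukey = [
            StatResult(comparison=f"{a1} vs {a2} @ {factor_b}={lvl}",
                       test="tukey-hsd", statistic=0.0, p_value=1.0,
                       discovery=False)
            for lvl in d["_b"].unique()
            for i, a1 in enumerate(sorted(d["_a"].unique()))
            for a2 in sorted(d["_a"].unique())[i + 1:]
        ]
        return {"anova": anova, "tukey": tukey}
    model = smf.ols("_y ~ C(_a) * C(_b)", data=d).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    tukey_results: list[StatResult] = []
    for level, sub in d.groupby("_b", observed=True):
        if sub["_a"].nunique() < 2:
            continue
        res = pairwise_tukeyhsd(sub["_y"], sub["_a"])
        frame = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
        for _, row in frame.iterrows():
            tukey_results.append(
                StatResult(
                    comparison=f"{row['group1']} vs {row['group2']} @ {factor_b}={level}",
                    test="tukey-hsd",
                    statistic=float(row["meandiff"]),
                    p_value=float(row["p-adj"]),
                    discovery=bool(row["reject"]),
                )
            )
    return {"anova": anova, "tukey": tukey_results}


# --------------------------------------------------------------------------
# Kruskal-Wallis + Dunn (cluster-wise comparisons)


def kruskal_dunn(samples: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis across >= 3 groups, then Dunn's pairwise post-hoc.

    Dunn's test uses rank-sum z statistics with the tie correction and
    Bonferroni-adjusted two-sided p-values (the convention of the common
    commercial statistics packages).
    """
    labels = list(samples)
    arrays = [np.asarray(samples[g], dtype=float) for g in labels]
    if len(arrays) < 3:
        raise ValueError("Kruskal-Wallis/Dunn requires >= 3 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    h, p_kw = sps.kruskal(*arrays)

    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term: sum over tie groups of (t^3 - t)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    splits = np.cumsum([a.size for a in arrays])[:-1]
    rank_groups = np.split(ranks, splits)
    mean_ranks = [rg.mean() for rg in rank_groups]
    sizes = [a.size for a in arrays]

    m = len(labels) * (len(labels) - 1) // 2
    dunn: list[StatResult] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1)))
                * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
            p_adj = min(1.0, p_raw * m)
            dunn.append(
                StatResult(
                    comparison=f"{labels[i]} vs {labels[j]}",
                    test="dunn",
                    statistic=float(z),
                    p_value=float(p_adj),
                    discovery=bool(p_adj <= 0.05),
                    group_ns=(sizes[i], sizes[j]),
                    extra={"p_raw": float(p_raw)},
                )
            )
    return {"h": float(h), "p": float(p_kw), "dunn": dunn}


# --------------------------------------------------------------------------
# demographics


def summarize_demographics(metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean ± sample SD of age and post-mortem delay, sex ratio.

    ``metadata`` needs columns ``group``, ``age``, ``sex`` and ``pmd``.
    Missing numeric values are excluded from the corresponding summary.
    A single-case group has an undefined (NaN) SD.
    """
    required = {"group", "age", "sex", "pmd"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    rows = []
    for group, sub in metadata.groupby("group", sort=False):
        age = sub["age"].dropna().to_numpy(float)
        pmd = sub["pmd"].dropna().to_numpy(float)
        n_m = int((sub["sex"] == "M").sum())
        n_f = int((sub["sex"] == "F").sum())
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "age_mean": age.mean() if age.size else np.nan,
                "age_sd": age.std(ddof=1) if age.size > 1 else np.nan,
                "pmd_mean": pmd.mean() if pmd.size else np.nan,
                "pmd_sd": pmd.std(ddof=1) if pmd.size > 1 else np.nan,
                "sex_ratio": f"{n_m} M:{n_f} F",
            }
        )
    return pd.DataFrame(rows).set_index("group")
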