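"""Perturbation-sensitivity statistics over enhancer-distance gene classes.

Joins gene classifications with differential-expression tables and
computes the comparison statistics of the analysis framework: one-sided
Kolmogorov-Smirnov D values (how strongly a class shifts toward
downregulation relative to a reference class), two-sided Wilcoxon
rank-sum tests, downregulated/unaffected response fractions, feature
quartile stratifications, cross-perturbation overlap tests, and Pearson
correlation clustering of responses across factors.

Conventions: a positive one-sided KS D means the test group's log2 fold
changes are shifted toward LOWER values than the reference (the group is
overrepresented among downregulated genes).  No multiple-testing
correction is applied across category comparisons; p-values are
per-test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .classify import GeneClassification
from .tables_io import CoverageTrack, DeRecord, DeTable

__all__ = [
    "ResponseThresholds",
    "CategoryComparison",
    "ks_d_one_sided",
    "wilcoxon_two_sided",
    "response_class",
    "category_response_fractions",
    "compare_categories",
    "joined_frame",
    "quartile_stratify",
    "QuartileStratification",
    "attach_coverage_feature",
    "overlap_response",
    "multi_factor_set",
    "correlation_cluster",
    "CorrelationClustering",
]


@dataclass(frozen=True)
class ResponseThresholds:
    """Log2FC / FDR cutoffs used by the response-class and set rules.

    ``down_lfc``/``fdr_max`` define "downregulated"; the open interval
    ``(unaffected_low, unaffected_high)`` defines "unaffected" (no FDR
    condition); ``overlap_down_lfc`` is the milder cutoff used when
    intersecting two perturbations; ``mediator_set_lfc`` and
    ``mediator_set_min_hits`` define the multi-factor target set.
    """

    down_lfc: float = -0.8
    unaffected_low: float = -0.2
    unaffected_high: float = 0.2
    fdr_max: float = 0.05
    overlap_down_lfc: float = -0.3
    mediator_set_lfc: float = -0.5
    mediator_set_min_hits: int = 2

    def __post_init__(self) -> None:
        if not self.down_lfc < self.unaffected_low < self.unaffected_high:
            raise ValueError("need down_lfc < unaffected_low < unaffected_high")
        if not 0.0 < self.fdr_max < 1.0:
            raise ValueError("fdr_max must be in (0,1)")


@dataclass
class CategoryComparison:
    """One two-sample comparison between gene groups."""

    statistic_kind: str  # "ks_one_sided" | "wilcoxon_two_sided"
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    direction: str = ""  # "lower" | "higher" | "none"
    degenerate: bool = False


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"empty sample for group '{name}'")
    return arr


def ks_one_sided_d(x: np.ndarray, y: np.ndarray) -> float:
    """D+ = sup_t [F_x(t) - F_y(t)] over the pooled sample points.

    Positive when x is shifted toward lower values than y.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pooled = np.concatenate([x, y])
    fx = np.searchsorted(x, pooled, side="right") / x.size
    fy = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.max(fx - fy))


def ks_d_one_sided(x, y, group_a: str = "x", group_b: str = "y") -> CategoryComparison:
    """One-sided two-sample KS comparison of log2FC samples.

    D = sup_t [F_x(t) - F_y(t)]; p from the asymptotic one-sided tail
    exp(-2 D^2 n_x n_y / (n_x + n_y)), clamped to [0, 1].
    """
    xa = _as_array(x, group_a)
    ya = _as_array(y, group_b)
    d = ks_one_sided_d(xa, ya)
    n_eff = xa.size * ya.size / (xa.size + ya.size)
    p = float(np.clip(np.exp(-2.0 * d * d * n_eff), 0.0, 1.0))
    return CategoryComparison(
        statistic_kind="ks_one_sided",
        group_a=group_a,
        group_b=group_b,
        n_a=int(xa.size),
        n_b=int(ya.size),
        statistic=d,
        p_value=p,
        direction="lower" if d > 0 else "none",
    )


def wilcoxon_two_sided(x, y, group_a: str = "x", group_b: str = "y") -> CategoryComparison:
    """Two-sided Wilcoxon rank-sum test (midranks for ties).

    Exact null distribution when min(n) <= 8 and there are no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.  The reported statistic is the rank sum of x.
    """
    xa = _as_array(x, group_a)
    ya = _as_array(y, group_b)
    has_ties = np.unique(np.concatenate([xa, ya])).size < xa.size + ya.size
    method = "exact" if (min(xa.size, ya.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic) + xa.size * (xa.size + 1) / 2.0
    med_diff = float(np.median(xa) - np.median(ya))
    return CategoryComparison(
        statistic_kind="wilcoxon_two_sided",
        group_a=group_a,
        group_b=group_b,
        n_a=int(xa.size),
        n_b=int(ya.size),
        statistic=w,
        p_value=float(min(res.pvalue, 1.0)),
        direction="lower" if med_diff < 0 else ("higher" if med_diff > 0 else "none"),
    )


def response_class(record: DeRecord, thresholds: ResponseThresholds | None = None) -> str:
    """'downregulated', 'unaffected' or 'neither' for one DE record.

    Downregulated needs log2fc < down_lfc AND fdr < fdr_max (missing FDR
    blocks it); unaffected is the log2FC band alone.
    """
    th = thresholds or ResponseThresholds()
    if record.log2fc < th.down_lfc and record.fdr is not None and record.fdr < th.fdr_max:
        return "downregulated"
    if th.unaffected_low < record.log2fc < th.unaffected_high:
        return "unaffected"
    return "neither"


def joined_frame(
    classifications: list[GeneClassification], de_table: DeTable
) -> pd.DataFrame:
    """Per-gene tidy join of category with log2fc/fdr (genes with a DE record)."""
    left = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in classifications],
            "category": [c.category for c in classifications],
            "inside_ccd": [c.inside_ccd for c in classifications],
        }
    )
    out = left.merge(
        de_table.df[["gene_id", "log2fc", "fdr", "base_mean"]], on="gene_id", how="inner"
    )
    return out[["gene_id", "category", "log2fc", "fdr", "base_mean", "inside_ccd"]]


def category_response_fractions(
    classifications: list[GeneClassification],
    de_table: DeTable,
    thresholds: ResponseThresholds | None = None,
) -> dict[str, dict[str, float | int | None]]:
    """Per category: fraction downregulated, fraction unaffected, denominator."""
    th = thresholds or ResponseThresholds()
    out: dict[str, dict[str, float | int | None]] = {}
    df = joined_frame(classifications, de_table)
    for category, sub in df.groupby("category"):
        n = len(sub)
        fdr_ok = sub["fdr"].notna() & (sub["fdr"] < th.fdr_max)
        down = ((sub["log2fc"] < th.down_lfc) & fdr_ok).sum()
        unaff = (
            (sub["log2fc"] > th.unaffected_low)
            & (sub["log2fc"] < th.unaffected_high)
            & ~((sub["log2fc"] < th.down_lfc) & fdr_ok)
        ).sum()
        out[category] = {
            "fraction_down": down / n,
            "fraction_unaffected": unaff / n,
            "n": n,
        }
    for category in set(c.category for c in classifications) - set(out):
        out[category] = {"fraction_down": None, "fraction_unaffected": None, "n": 0}
    return out


def compare_categories(
    classifications: list[GeneClassification],
    de_table: DeTable,
    pairs: list[tuple[str, str]],
    statistic_kind: str = "ks_one_sided",
) -> tuple[list[CategoryComparison], pd.DataFrame]:
    """Compare log2FC distributions between named category pairs.

    Returns the comparison list plus the per-gene tidy log2FC-by-category
    frame used for cumulative-distribution plotting.
    """
    df = joined_frame(classifications, de_table)
    groups = {cat: sub["log2fc"].to_numpy() for cat, sub in df.groupby("category")}
    comparisons = []
    for a, b in pairs:
        for name in (a, b):
            if name not in groups:
                raise ValueError(f"category '{name}' empty or unknown in joined data")
        if statistic_kind == "ks_one_sided":
            comparisons.append(ks_d_one_sided(groups[a], groups[b], a, b))
        elif statistic_kind == "wilcoxon_two_sided":
            comparisons.append(wilcoxon_two_sided(groups[a], groups[b], a, b))
        else:
            raise ValueError(f"unknown statistic kind '{statistic_kind}'")
    return comparisons, df


@dataclass
class QuartileStratification:
    """Quartile membership over the pooled enhancer set plus comparisons."""

    feature_name: str
    low_gene_ids: list[str]
    high_gene_ids: list[str]
    comparisons: list[CategoryComparison] = field(default_factory=list)
    degenerate: bool = False
    members: pd.DataFrame | None = None


def quartile_stratify(
    classifications: list[GeneClassification],
    de_table: DeTable,
    feature_name: str,
    reference_category: str = "no_enhancer",
) -> QuartileStratification:
    """Stratify enhancer-connected genes by a feature of their enhancer.

    The representative enhancers of ALL short+mid+long genes are pooled and
    ranked on the feature; the bottom and top floor(n/4) enhancers define
    the low/high sets (ties broken deterministically by element
    coordinate).  Per category and quartile group, member genes' log2FC is
    compared to the reference category by two-sided Wilcoxon.
    """
    rows = []
    n_missing = 0
    for cls in classifications:
        if cls.category not in ("short", "mid", "long") or cls.representative_link is None:
            continue
        rep = cls.representative_link
        val = rep.features.get(feature_name)
        if val is None or not np.isfinite(val):
            n_missing += 1
            continue
        rows.append(
            {
                "gene_id": cls.gene_id,
                "category": cls.category,
                "feature": float(val),
                "chrom": rep.element.chrom,
                "start": rep.element.start,
            }
        )
    n_total = len(rows) + n_missing
    if n_total == 0:
        raise ValueError(f"no enhancer-connected genes carry feature '{feature_name}'")
    if n_missing > 0.5 * n_total:
        raise ValueError(
            f"feature '{feature_name}' missing for >50% of enhancers "
            f"({n_missing}/{n_total})"
        )
    pool = pd.DataFrame(rows).sort_values(
        ["feature", "chrom", "start"], kind="mergesort"
    )
    n = len(pool)
    k = n // 4
    degenerate = pool["feature"].nunique() == 1
    pool = pool.assign(quartile_group="")
    pool.iloc[:k, pool.columns.get_loc("quartile_group")] = "low"
    pool.iloc[n - k :, pool.columns.get_loc("quartile_group")] = "high"

    de = de_table.df.set_index("gene_id")["log2fc"]
    ref_lfc = np.array(
        [
            de[c.gene_id]
            for c in classifications
            if c.category == reference_category and c.gene_id in de.index
        ]
    )
    comparisons = []
    if ref_lfc.size:
        for (category, group), sub in pool[pool["quartile_group"] != ""].groupby(
            ["category", "quartile_group"]
        ):
            lfc = np.array([de[g] for g in sub["gene_id"] if g in de.index])
            if lfc.size == 0:
                continue
            cmp = wilcoxon_two_sided(
                lfc, ref_lfc, f"{category}:{group}", reference_category
            )
            cmp.degenerate = degenerate
            comparisons.append(cmp)
    return QuartileStratification(
        feature_name=feature_name,
        low_gene_ids=pool.loc[pool["quartile_group"] == "low", "gene_id"].tolist(),
        high_gene_ids=pool.loc[pool["quartile_group"] == "high", "gene_id"].tolist(),
        comparisons=comparisons,
        degenerate=degenerate,
        members=pool.reset_index(drop=True),
    )


def attach_coverage_feature(
    classifications: list[GeneClassification],
    coverage: CoverageTrack,
    feature_name: str,
) -> list[GeneClassification]:
    """Attach length-weighted mean coverage over each representative element.

    Elements with no overlapping coverage get 0.  Returns the same list
    with each representative link's feature map extended (links are
    frozen, so extended copies are swapped in).
    """
    cache: dict[tuple[str, int, int], float] = {}
    for cls in classifications:
        rep = cls.representative_link
        if rep is None:
            continue
        key = (rep.element.chrom, rep.element.start, rep.element.end)
        if key not in cache:
            cache[key] = coverage.mean_over(*key)
        feats = dict(rep.features)
        feats[feature_name] = cache[key]
        new_rep = dataclasses.replace(rep, features=feats)
        cls.representative_link = new_rep
        cls.qualifying_links = [
            new_rep if l is rep else l for l in cls.qualifying_links
        ]
    return classifications


def overlap_response(
    classifications: list[GeneClassification],
    de_a: DeTable,
    de_b: DeTable,
    thresholds: ResponseThresholds | None = None,
    category: str = "long",
) -> CategoryComparison:
    """Within one category: do genes downregulated under perturbation A
    respond more to perturbation B than A-unaffected genes do?

    Set A = category genes with de_a log2fc < overlap_down_lfc and
    fdr < fdr_max; set U = category genes in the unaffected band of de_a.
    Returns the two-sided Wilcoxon of de_b log2FC between A and U.
    """
    th = thresholds or ResponseThresholds()
    a_ix = de_a.df.set_index("gene_id")
    b_ix = de_b.df.set_index("gene_id")
    lfc_a, lfc_u = [], []
    for cls in classifications:
        g = cls.gene_id
        if cls.category != category or g not in a_ix.index or g not in b_ix.index:
            continue
        rec = a_ix.loc[g]
        fdr_ok = pd.notna(rec["fdr"]) and rec["fdr"] < th.fdr_max
        if rec["log2fc"] < th.overlap_down_lfc and fdr_ok:
            lfc_a.append(float(b_ix.loc[g, "log2fc"]))
        elif th.unaffected_low < rec["log2fc"] < th.unaffected_high:
            lfc_u.append(float(b_ix.loc[g, "log2fc"]))
    if not lfc_a:
        raise ValueError(f"downregulated set empty in category '{category}'")
    if not lfc_u:
        raise ValueError(f"unaffected set empty in category '{category}'")
    return wilcoxon_two_sided(
        lfc_a, lfc_u, f"{category}:down_in_{de_a.name}", f"{category}:unaffected_in_{de_a.name}"
    )


def multi_factor_set(
    de_tables: list[DeTable], thresholds: ResponseThresholds | None = None
) -> set[str]:
    """Genes with log2fc < mediator_set_lfc in >= mediator_set_min_hits tables."""
    th = thresholds or ResponseThresholds()
    if len(de_tables) < th.mediator_set_min_hits:
        raise ValueError(
            f"need >= {th.mediator_set_min_hits} tables, got {len(de_tables)}"
        )
    hits: dict[str, int] = {}
    for table in de_tables:
        down = table.df.loc[table.df["log2fc"] < th.mediator_set_lfc, "gene_id"]
        for g in down:
            hits[g] = hits.get(g, 0) + 1
    return {g for g, k in hits.items() if k >= th.mediator_set_min_hits}


@dataclass
class CorrelationClustering:
    """Pairwise Pearson correlation of responses plus a dendrogram order."""

    correlation: pd.DataFrame
    linkage: np.ndarray | None
    leaf_order: list[str]


def correlation_cluster(
    de_tables: list[DeTable], gene_set: set[str] | list[str]
) -> CorrelationClustering:
    """Correlate and cluster perturbation responses over a gene set.

    Pairwise-complete Pearson r of log2FC vectors over the genes of
    ``gene_set`` present in all tables; average-linkage hierarchical
    clustering on distance 1 - r.  Tables with zero variance get missing
    correlations and are placed last in the leaf order.
    """
    if len(de_tables) < 2:
        raise ValueError("need >= 2 DE tables")
    genes = sorted(set(gene_set))
    mat = pd.DataFrame(
        {t.name: t.log2fc_series().reindex(genes) for t in de_tables}, index=genes
    )
    if mat.dropna(how="all").shape[0] < 3:
        raise ValueError("gene set must have >= 3 genes present in the tables")
    corr = mat.corr(method="pearson", min_periods=2)
    valid = [c for c in corr.columns if corr[c].notna().sum() > 1]
    dropped = [c for c in corr.columns if c not in valid]
    if len(valid) >= 2:
        sub = corr.loc[valid, valid].to_numpy()
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        # guard tiny negative float error in the condensed distance
        from scipy.spatial.distance import squareform

        z = hierarchy.linkage(squareform(np.maximum(dist, 0.0), checks=False), method="average")
        order = [valid[i] for i in hierarchy.leaves_list(z)]
    else:
        z = None
        order = list(valid)
    return CorrelationClustering(
        correlation=corr, linkage=z, leaf_order=order + dropped
    )
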