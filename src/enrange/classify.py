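"""Distance-based gene categorization from element-gene link tables.

Expressed genes are sorted into five mutually exclusive categories from
their predicted enhancer links:

* ``no_enhancer`` — no link beyond 2 kb with a score >= tau_low (0.3):
  promoter-autonomous expression.
* ``short`` — a strong link (score >= tau_high, 0.8) at 2-10 kb and no
  link beyond 10 kb with score >= tau_low.
* ``mid`` — a strong link at 10-40 kb and no link beyond 40 kb with
  score >= tau_low.
* ``long`` — a strong link at 50-500 kb (no proximal-exclusion clause).
* ``ambiguous`` — everything else (e.g. several medium-score links at
  variable distances, or a strong link in the uncovered 40-50 kb gap).

The exclusion clauses make the first four predicates mutually exclusive,
so the label is independent of evaluation order.  Each of short/mid/long
carries a representative link: the qualifying-window link of maximal
score (ties: smaller distance, then leftmost element start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import (
    CcdDomainSet,
    DeTable,
    EnhancerGeneLink,
    GenomicInterval,
    LinkTable,
)

__all__ = [
    "CATEGORIES",
    "ClassifierThresholds",
    "GeneClassification",
    "classify_gene",
    "classify_table",
    "flag_inside_ccd",
    "category_flag_fraction",
    "classifications_to_frame",
]

CATEGORIES = ("no_enhancer", "short", "mid", "long", "ambiguous")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Score cutoffs and distance windows (bp) for the category rules.

    ``tau_low`` is the cutoff above which a link counts as a (blocking)
    enhancer link at all; ``tau_high`` the cutoff for a qualifying link.
    Windows: short (promoter_exclusion_bp, short_max]; mid
    (short_max, mid_max]; long [long_min, long_max].
    """

    tau_low: float = 0.3
    tau_high: float = 0.8
    promoter_exclusion_bp: int = 2_000
    short_max_bp: int = 10_000
    mid_max_bp: int = 40_000
    long_min_bp: int = 50_000
    long_max_bp: int = 500_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau_low <= self.tau_high <= 1.0:
            raise ValueError("need 0 <= tau_low <= tau_high <= 1")
        if not (
            0
            < self.promoter_exclusion_bp
            < self.short_max_bp
            < self.mid_max_bp
            < self.long_min_bp
            < self.long_max_bp
        ):
            raise ValueError("distance windows must be ordered and non-degenerate")


@dataclass
class GeneClassification:
    """A gene's distance category plus its representative qualifying link."""

    gene_id: str
    category: str
    representative_link: EnhancerGeneLink | None = None
    inside_ccd: bool | None = None
    qualifying_links: list[EnhancerGeneLink] = field(default_factory=list)


def _window_mask(d: np.ndarray, s: np.ndarray, th: ClassifierThresholds, category: str):
    if category == "short":
        return (d > th.promoter_exclusion_bp) & (d <= th.short_max_bp) & (s >= th.tau_high)
    if category == "mid":
        return (d > th.short_max_bp) & (d <= th.mid_max_bp) & (s >= th.tau_high)
    if category == "long":
        return (d >= th.long_min_bp) & (d <= th.long_max_bp) & (s >= th.tau_high)
    raise ValueError(category)


def _categorize_arrays(
    d: np.ndarray, s: np.ndarray, th: ClassifierThresholds
) -> tuple[str, np.ndarray]:
    """Category plus boolean mask of qualifying links for one gene."""
    any_enhancer = bool(((d > th.promoter_exclusion_bp) & (s >= th.tau_low)).any())
    if not any_enhancer:
        return "no_enhancer", np.zeros(len(d), dtype=bool)
    short_q = _window_mask(d, s, th, "short")
    if short_q.any() and not ((d > th.short_max_bp) & (s >= th.tau_low)).any():
        return "short", short_q
    mid_q = _window_mask(d, s, th, "mid")
    if mid_q.any() and not ((d > th.mid_max_bp) & (s >= th.tau_low)).any():
        return "mid", mid_q
    long_q = _window_mask(d, s, th, "long")
    if long_q.any():
        return "long", long_q
    return "ambiguous", np.zeros(len(d), dtype=bool)


def _pick_representative(links: list[EnhancerGeneLink]) -> EnhancerGeneLink:
    # max score; ties: smaller distance, then leftmost element start
    return min(links, key=lambda l: (-l.e2g_score, l.distance_bp, l.element.start))


def classify_gene(
    links: list[EnhancerGeneLink],
    thresholds: ClassifierThresholds | None = None,
) -> GeneClassification:
    """Classify one gene from its (possibly empty) list of links."""
    th = thresholds or ClassifierThresholds()
    if not links:
        return GeneClassification(gene_id="", category="no_enhancer")
    gene_ids = {l.gene_id for l in links}
    if len(gene_ids) > 1:
        raise ValueError(f"links span multiple genes: {sorted(gene_ids)}")
    d = np.array([l.distance_bp for l in links], dtype=float)
    s = np.array([l.e2g_score for l in links], dtype=float)
    category, qmask = _categorize_arrays(d, s, th)
    qualifying = [l for l, q in zip(links, qmask) if q]
    rep = _pick_representative(qualifying) if qualifying else None
    return GeneClassification(
        gene_id=links[0].gene_id,
        category=category,
        representative_link=rep,
        qualifying_links=qualifying,
    )


def classify_table(
    link_table: LinkTable,
    de_table: DeTable,
    thresholds: ClassifierThresholds | None = None,
    min_base_mean: float = 50.0,
) -> list[GeneClassification]:
    """Classify every expressed gene in the DE table's universe.

    The gene universe is the set of genes in ``de_table`` with
    ``base_mean >= min_base_mean``; universe genes absent from the link
    table are classified from an empty link list (no_enhancer).
    """
    if min_base_mean < 0:
        raise ValueError("min_base_mean must be >= 0")
    th = thresholds or ClassifierThresholds()
    universe = de_table.df.loc[de_table.df["base_mean"] >= min_base_mean, "gene_id"]
    universe_set = set(universe)

    df = link_table.df
    in_universe = df["gene_id"].isin(universe_set).to_numpy()
    df = df.loc[in_universe]
    d = df["distance_bp"].to_numpy(float)
    s = df["e2g_score"].to_numpy(float)
    codes, gene_ids = pd.factorize(df["gene_id"])

    link_masks = pd.DataFrame(
        {
            "enh": (d > th.promoter_exclusion_bp) & (s >= th.tau_low),
            "short_hi": _window_mask(d, s, th, "short"),
            "beyond_short_lo": (d > th.short_max_bp) & (s >= th.tau_low),
            "mid_hi": _window_mask(d, s, th, "mid"),
            "beyond_mid_lo": (d > th.mid_max_bp) & (s >= th.tau_low),
            "long_hi": _window_mask(d, s, th, "long"),
        }
    )
    agg = link_masks.groupby(codes).any()
    category = np.select(
        [
            ~agg["enh"],
            agg["short_hi"] & ~agg["beyond_short_lo"],
            agg["mid_hi"] & ~agg["beyond_mid_lo"],
            agg["long_hi"],
        ],
        ["no_enhancer", "short", "mid", "long"],
        default="ambiguous",
    )
    cat_by_code = pd.Series(category, index=agg.index)
    link_cat = cat_by_code.reindex(codes).to_numpy()
    qual = (
        ((link_cat == "short") & link_masks["short_hi"].to_numpy())
        | ((link_cat == "mid") & link_masks["mid_hi"].to_numpy())
        | ((link_cat == "long") & link_masks["long_hi"].to_numpy())
    )

    # materialize link objects only for qualifying links
    qual_links: dict[str, list[EnhancerGeneLink]] = {}
    feat_names = link_table.feature_names
    qsub = df.loc[qual]
    has_flag = "ubiquitous" in df.columns
    for row in qsub.itertuples(index=False):
        link = EnhancerGeneLink(
            element=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            gene_id=row.gene_id,
            gene_symbol=row.gene_symbol,
            tss=int(row.tss),
            e2g_score=float(row.e2g_score),
            distance_bp=int(row.distance_bp),
            features={f: float(getattr(row, f)) for f in feat_names},
            ubiquitous_flag=(
                bool(row.ubiquitous)
                if has_flag and row.ubiquitous is not None and pd.notna(row.ubiquitous)
                else None
            ),
        )
        qual_links.setdefault(row.gene_id, []).append(link)

    cat_by_gene = dict(zip(gene_ids, category))
    out = []
    for gene_id in universe:
        cat = cat_by_gene.get(gene_id, "no_enhancer")
        qualifying = qual_links.get(gene_id, [])
        rep = _pick_representative(qualifying) if qualifying else None
        out.append(
            GeneClassification(
                gene_id=gene_id,
                category=cat,
                representative_link=rep,
                qualifying_links=qualifying,
            )
        )
    return out


def flag_inside_ccd(
    classification: GeneClassification, ccds: CcdDomainSet
) -> GeneClassification:
    """Set ``inside_ccd``: true iff some qualifying link has both its element
    and the gene's TSS contained in a single contact-domain interval."""
    if classification.category not in ("short", "mid", "long"):
        raise ValueError(
            f"inside-CCD flag applies to enhancer categories, not "
            f"'{classification.category}'"
        )
    inside = any(
        ccds.contains_pair(l.element.chrom, l.tss, l.element)
        for l in classification.qualifying_links
    )
    classification.inside_ccd = inside
    return classification


def category_flag_fraction(
    classifications: list[GeneClassification],
    flag_name: str = "ubiquitous",
    gene_flags: dict[str, bool] | None = None,
) -> dict[str, float | None]:
    """Per category, the fraction of genes whose flag is true.

    Flags come either from a per-gene mapping (``gene_flags``) or, for
    ``flag_name='ubiquitous'``, from the representative link's flag (genes
    without a representative link need ``gene_flags``).  Empty categories
    yield None, never 0.
    """
    counts: dict[str, list[int]] = {c: [0, 0] for c in CATEGORIES}
    for cls in classifications:
        if gene_flags is not None:
            if cls.gene_id not in gene_flags:
                continue
            flag = gene_flags[cls.gene_id]
        elif flag_name == "ubiquitous":
            if cls.representative_link is None or cls.representative_link.ubiquitous_flag is None:
                continue
            flag = cls.representative_link.ubiquitous_flag
        else:
            raise ValueError(
                f"unknown flag '{flag_name}'; provide gene_flags for custom flags"
            )
        counts[cls.category][0] += int(bool(flag))
        counts[cls.category][1] += 1
    return {
        c: (k / n if n else None) for c, (k, n) in counts.items()
    }


def classifications_to_frame(classifications: list[GeneClassification]) -> pd.DataFrame:
    """Tidy one-row-per-gene export of a classification run."""
    rows = []
    for cls in classifications:
        rep = cls.representative_link
        row = {
            "gene_id": cls.gene_id,
            "category": cls.category,
            "rep_chrom": rep.element.chrom if rep else None,
            "rep_start": rep.element.start if rep else None,
            "rep_end": rep.element.end if rep else None,
            "e2g_score": rep.e2g_score if rep else None,
            "distance_bp": rep.distance_bp if rep else None,
            "inside_ccd": cls.inside_ccd,
        }
        if rep:
            row.update(rep.features)
        rows.append(row)
    return pd.DataFrame(rows)
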