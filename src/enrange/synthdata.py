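"""Seeded generators for every input the pipeline consumes.

The generators plant known structure — category labels, contact-domain
membership, enhancer-feature levels, perturbation effect sizes, screen
hits, 4C spikes — so each analysis stage can be verified end to end
against ground truth.  Category sizes default to the published K562
analysis scale (2,790 promoter-autonomous, 285 short-range, 209
mid-range, 474 long-range expressed genes).

Genes are laid out on one synthetic chromosome at a fixed stride, with a
TSS in the middle of each locus and elements placed up- or downstream at
the planted distances, so loci (and their contact domains) never
overlap.  Each planted short/mid/long gene carries exactly one
qualifying link (score in [0.8, 1] inside its window) plus optional
decoy links (score in [0, 0.3)); ambiguous genes are planted by
violating exactly one clause (a strong link in the uncovered 40-50 kb
gap, or a single medium-score link).  All generators are pure functions
of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables_io import BetaTable, CcdDomainSet, DeTable, LinkTable, _merge_intervals
from .fourc import FragmentProfile

__all__ = ["SimConfig", "gen_links", "gen_de", "gen_screen", "gen_fourc", "PRESETS"]

#: Per-category mean log2FC models.  The long-range effect of the
#: "cohesin" preset is additionally scaled by the enhancer's feature
#: percentile and shrunk (x0.3) outside contact domains; magnitudes are
#: package defaults sized to make the published effect directions
#: detectable at the published group sizes.
PRESETS: dict[str, dict[str, float]] = {
    "cohesin": {"no_enhancer": 0.0, "short": 0.2, "mid": 0.0, "long": -0.5, "ambiguous": 0.0},
    "mediator": {"no_enhancer": 0.0, "short": 0.0, "mid": -0.3, "long": -0.4, "ambiguous": 0.0},
    "null": {"no_enhancer": 0.0, "short": 0.0, "mid": 0.0, "long": 0.0, "ambiguous": 0.0},
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic cohort.

    Distances are in bp.  ``feature_logmu`` gives the location of the
    log-normal enhancer-feature (EP300-like) model per category;
    long-range enhancers are strongest, mirroring the observed ordering.
    ``p_inside_ccd`` is the probability that a planted enhancer gene's
    qualifying link sits inside one contact domain together with its TSS.
    """

    seed: int = 0
    n_no_enhancer: int = 2790
    n_short: int = 285
    n_mid: int = 209
    n_long: int = 474
    n_ambiguous: int = 0
    locus_stride: int = 1_400_000
    element_width: int = 500
    tau_low: float = 0.3
    tau_high: float = 0.8
    promoter_exclusion_bp: int = 2_000
    short_window: tuple[int, int] = (2_001, 10_000)
    mid_window: tuple[int, int] = (10_001, 40_000)
    long_window: tuple[int, int] = (50_000, 500_000)
    max_decoys: int = 3
    feature_name: str = "EP300"
    feature_logmu: dict[str, float] = field(
        default_factory=lambda: {"short": 0.0, "mid": 0.5, "long": 1.0, "decoy": -0.5}
    )
    feature_logsigma: float = 1.0
    p_ubiquitous: dict[str, float] = field(
        default_factory=lambda: {
            "no_enhancer": 0.5,
            "short": 0.35,
            "mid": 0.25,
            "long": 0.15,
            "ambiguous": 0.3,
        }
    )
    p_inside_ccd: float = 0.7
    ccd_margin: int = 1_000
    # effect / DE model
    effect_sd: float = 0.4
    ccd_outside_factor: float = 0.3
    n_eff: float = 4.0
    base_mean_logmu: float = 5.0
    base_mean_logsigma: float = 1.0
    base_mean_floor: float = 50.0
    # screen model
    screen_lines: tuple[str, ...] = ("E0", "E50", "E100", "EC100")
    distal_lines: tuple[str, ...] = ("E50", "E100", "EC100")
    n_targets: int = 3200
    n_nontargeting: int = 624
    anchor_id: str = "HBG_TSS"
    anchor_effect: float = 2.0
    screen_noise_sd: float = 0.05
    # 4C model
    n_fragments: int = 2000
    fourc_alpha: float = 1.0
    fourc_scale: float = 5_000.0
    fourc_baseline: float = 1.0
    fourc_blind_fraction: float = 0.1
    fourc_spike_factor: float = 50.0

    def category_counts(self) -> dict[str, int]:
        return {
            "no_enhancer": self.n_no_enhancer,
            "short": self.n_short,
            "mid": self.n_mid,
            "long": self.n_long,
            "ambiguous": self.n_ambiguous,
        }


def _sample_feature(rng: np.random.Generator, cfg: SimConfig, kind: str, n: int) -> np.ndarray:
    mu = cfg.feature_logmu.get(kind, cfg.feature_logmu["decoy"])
    return np.exp(rng.normal(mu, cfg.feature_logsigma, size=n))


def gen_links(config: SimConfig) -> tuple[LinkTable, pd.DataFrame, CcdDomainSet]:
    """Generate a link table with planted categories and contact domains.

    Returns (link table, truth frame, contact domains).  The truth frame
    has one row per gene: gene_id, category, inside_ccd (None outside the
    enhancer categories), tss, and the qualifying enhancer's feature
    value (NaN for no_enhancer/ambiguous genes).
    """
    rng = np.random.default_rng(config.seed)
    counts = config.category_counts()
    if min(counts.values()) < 0:
        raise ValueError("category counts must be >= 0")
    for lo, hi in (config.short_window, config.mid_window, config.long_window):
        if hi <= lo:
            raise ValueError("infeasible distance window")

    windows = {
        "short": config.short_window,
        "mid": config.mid_window,
        "long": config.long_window,
    }
    categories = [c for c, n in counts.items() for _ in range(n)]
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    ccd_rows: list[tuple[str, int, int]] = []
    chrom = "chrS"
    half = config.locus_stride // 2
    w = config.element_width

    for i, category in enumerate(categories):
        gene_id = f"ENSG{i:08d}"
        symbol = f"G{i}"
        tss = i * config.locus_stride + half
        ubiq = bool(rng.random() < config.p_ubiquitous[category])
        inside_ccd: bool | None = None
        rep_feature = np.nan

        def add_link(distance: float, score: float, feature: float) -> tuple[int, int]:
            side = 1 if rng.random() < 0.5 else -1
            if side > 0:
                start = tss + int(distance)
            else:
                start = tss - int(distance) - w
            rows.append(
                (chrom, start, start + w, gene_id, symbol, tss, score,
                 int(distance), feature, ubiq)
            )
            return start, start + w

        if category in windows:
            lo, hi = windows[category]
            dist = rng.uniform(lo, hi)
            score = rng.uniform(config.tau_high, 1.0)
            rep_feature = float(_sample_feature(rng, config, category, 1)[0])
            elem = add_link(dist, score, rep_feature)
            inside_ccd = bool(rng.random() < config.p_inside_ccd)
            m = config.ccd_margin
            if inside_ccd:
                left = min(tss, elem[0]) - m
                right = max(tss, elem[1]) + m
                ccd_rows.append((chrom, left, right))
            else:
                # domain around the element only, stopping short of the TSS
                gap = max((min(abs(elem[0] - tss), abs(elem[1] - tss))) // 2, 1)
                left = elem[0] - min(m, gap)
                right = elem[1] + min(m, gap)
                if not (left <= tss < right):
                    ccd_rows.append((chrom, left, right))
                    inside_ccd = False
                # else: distance too small to separate; leave no domain
        elif category == "ambiguous":
            if rng.random() < 0.5:
                # strong link in the uncovered gap between mid and long windows
                dist = rng.uniform(config.mid_window[1] + 1, config.long_window[0] - 1)
                score = rng.uniform(config.tau_high, 1.0)
            else:
                # single medium-score link: blocks no_enhancer, qualifies nothing
                dist = rng.uniform(config.promoter_exclusion_bp + 1, config.long_window[1])
                score = rng.uniform(config.tau_low, config.tau_high - 1e-9)
            add_link(dist, score, float(_sample_feature(rng, config, "decoy", 1)[0]))

        n_decoys = int(rng.integers(0, config.max_decoys + 1))
        if category == "no_enhancer" and n_decoys == 0 and rng.random() < 0.5:
            n_decoys = 1  # keep many no-enhancer genes represented in the table
        for _ in range(n_decoys):
            dist = rng.uniform(config.promoter_exclusion_bp + 1, config.long_window[1] + 50_000)
            score = rng.uniform(0.0, config.tau_low - 1e-9)
            add_link(dist, score, float(_sample_feature(rng, config, "decoy", 1)[0]))

        truth_rows.append((gene_id, category, inside_ccd, tss, rep_feature, ubiq))

    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "gene_id", "gene_symbol", "tss",
            "e2g_score", "distance_bp", config.feature_name, "ubiquitous",
        ],
    )
    df[["start", "end", "tss", "distance_bp"]] = df[
        ["start", "end", "tss", "distance_bp"]
    ].astype(np.int64)
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "category", "inside_ccd", "tss", "feature", "ubiquitous"],
    )
    ccds = CcdDomainSet(*_merge_intervals(pd.DataFrame(ccd_rows, columns=["chrom", "start", "end"])))
    table = LinkTable(
        df, feature_names=[config.feature_name], provenance=f"synthetic(seed={config.seed})"
    )
    return table, truth, ccds


def _feature_percentile(truth: pd.DataFrame) -> pd.Series:
    """Percentile (0-1] of each enhancer gene's feature in the pooled
    short+mid+long enhancer set; NaN elsewhere."""
    mask = truth["category"].isin(["short", "mid", "long"])
    pct = pd.Series(np.nan, index=truth.index)
    pct[mask] = truth.loc[mask, "feature"].rank(method="average") / mask.sum()
    return pct


def gen_de(
    link_table: LinkTable,
    truth: pd.DataFrame,
    config: SimConfig,
    preset: str = "cohesin",
    seed: int | None = None,
) -> DeTable:
    """Generate a DE table with planted per-category effects.

    log2fc = mu(category) x modifiers + N(0, effect_sd^2).  Under the
    "cohesin" preset the long-range mean is scaled by the qualifying
    enhancer's pooled feature percentile and multiplied by
    ``ccd_outside_factor`` outside contact domains.  baseMean is
    log-normal above ``base_mean_floor``; FDR comes from the effect
    z-score z = log2fc x sqrt(n_eff) / sd via a two-sided normal p,
    Benjamini-Hochberg adjusted.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset '{preset}' (use {sorted(PRESETS)})")
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    mu_map = PRESETS[preset]
    mu = truth["category"].map(mu_map).to_numpy(float)
    if preset == "cohesin":
        pct = _feature_percentile(truth).to_numpy()
        is_long = (truth["category"] == "long").to_numpy()
        outside = np.array([v is False for v in truth["inside_ccd"]])
        ccd_mult = np.where(outside, config.ccd_outside_factor, 1.0)
        mu = np.where(is_long, mu * pct * ccd_mult, mu)
    n = len(truth)
    log2fc = mu + rng.normal(0.0, config.effect_sd, size=n)
    base_mean = config.base_mean_floor + np.exp(
        rng.normal(config.base_mean_logmu, config.base_mean_logsigma, size=n)
    )
    z = log2fc * np.sqrt(config.n_eff) / config.effect_sd
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {
            "gene_id": truth["gene_id"],
            "base_mean": base_mean,
            "log2fc": log2fc,
            "fdr": fdr,
        }
    )
    return DeTable(name=preset, df=df)


def gen_screen(
    config: SimConfig,
    planted: dict[str, dict[str, float]] | None = None,
    seed: int | None = None,
) -> list[BetaTable]:
    """Generate dual-gate beta tables for each reporter line.

    ``planted`` maps target_id -> {line: effect}; a positive effect means
    the target is required for reporter expression (guides enrich in the
    GFP-low gate).  The anchor gets ``anchor_effect`` in every line;
    non-targeting controls and unplanted targets have effect 0.
    beta_low/high = +-effect/2 + N(0, screen_noise_sd^2).
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    planted = planted or {}
    targets = (
        [config.anchor_id]
        + [f"T{i:05d}" for i in range(config.n_targets)]
        + [f"NT{i:04d}" for i in range(config.n_nontargeting)]
    )
    tables = []
    for line in config.screen_lines:
        effect = np.zeros(len(targets))
        effect[0] = config.anchor_effect
        for t, per_line in planted.items():
            if t in targets:
                effect[targets.index(t)] = per_line.get(line, 0.0)
        noise = rng.normal(0.0, config.screen_noise_sd, size=(len(targets), 2))
        df = pd.DataFrame(
            {
                "target_id": targets,
                "beta_low": effect / 2.0 + noise[:, 0],
                "beta_high": -effect / 2.0 + noise[:, 1],
            }
        )
        tables.append(BetaTable(line, df, anchor_id=config.anchor_id))
    return tables


def gen_fourc(config: SimConfig, seed: int | None = None) -> FragmentProfile:
    """Generate a 4C fragment profile: distance-decay mean with Poisson
    noise, two spike fragments near the viewpoint, ~10% blind fragments."""
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    n = config.n_fragments
    vp = n // 2
    idx = np.arange(n)
    mean = config.fourc_scale / (1.0 + np.abs(idx - vp)) ** config.fourc_alpha
    mean += config.fourc_baseline
    spikes = (vp + 1, vp + 2)
    mean[list(spikes)] *= config.fourc_spike_factor
    counts = rng.poisson(mean).astype(float)
    blind = rng.random(n) < config.fourc_blind_fraction
    frag_w = 1000
    df = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": idx * frag_w,
            "end": (idx + 1) * frag_w,
            "count": counts,
            "blind": blind,
        }
    )
    return FragmentProfile(df, viewpoint=f"frag{vp}")
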