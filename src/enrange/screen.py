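"""Dual-gate CRISPRi screen score arithmetic.

Downstream of per-gate effect estimation (MAGeCK-MLE-style beta scores
for the sorted GFP-low and GFP-high populations), each target's raw
enrichment score is the difference of its two gate betas.  Scores are
normalized per reporter line to the guide targeting the reporter
promoter itself (the anchor), so lines with different dynamic ranges are
comparable.  Distance specificity is scored by subtracting a target's
average score in the distal-enhancer reporter lines from its score in
the enhancer-adjacent line (E0) and ranking on that delta.

Sign convention: with ``score_sign=-1`` (the pipeline default) factors
required for reporter expression get negative normalized scores, so the
distal selection cutoff (<= -0.1) picks activators; ``score_sign=+1``
keeps the plain anchor ratio, under which the anchor itself scores 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import BetaTable

__all__ = [
    "FlowSummary",
    "enrichment_score",
    "normalize_scores",
    "distal_summary",
    "screen_pipeline",
    "single_guide_fc",
]


@dataclass(frozen=True)
class FlowSummary:
    """Median reporter-GFP levels for one single-guide validation."""

    kd_guide: float
    control_guides: tuple[float, float]
    background: float = 0.0

    def __post_init__(self) -> None:
        if min(self.kd_guide, *self.control_guides, self.background) < 0:
            raise ValueError("median GFP levels must be >= 0")


def enrichment_score(beta_low: float, beta_high: float, sign_flip: bool = False) -> float:
    """Raw screen score: GFP-low beta minus GFP-high beta.

    ``sign_flip`` inverts the convention globally.
    """
    if not (math.isfinite(beta_low) and math.isfinite(beta_high)):
        raise ValueError("beta scores must be finite")
    score = beta_low - beta_high
    return -score if sign_flip else score


def normalize_scores(
    beta_table: BetaTable, anchor_id: str | None = None, score_sign: int = 1
) -> pd.DataFrame:
    """Per-target raw and anchor-normalized enrichment scores for one line.

    With ``score_sign=1``: normalized = raw / raw(anchor), so the anchor's
    own normalized score is 1.  With ``score_sign=-1``: normalized =
    -raw / |raw(anchor)|, making activators (anchor-direction effects)
    negative.  Either way the result is invariant to rescaling all of a
    line's raw betas by a nonzero constant.
    """
    anchor_id = anchor_id or beta_table.anchor_id
    df = beta_table.df.copy()
    df["raw_score"] = df["beta_low"] - df["beta_high"]
    anchor_rows = df.loc[df["target_id"] == anchor_id, "raw_score"]
    if anchor_rows.empty:
        raise ValueError(f"anchor '{anchor_id}' absent in line '{beta_table.cell_line}'")
    anchor_raw = float(anchor_rows.iloc[0])
    if anchor_raw == 0.0:
        raise ValueError(
            f"anchor raw score is 0 in line '{beta_table.cell_line}'; cannot normalize"
        )
    if score_sign not in (1, -1):
        raise ValueError("score_sign must be +1 or -1")
    denom = anchor_raw if score_sign == 1 else abs(anchor_raw)
    df["normalized_score"] = score_sign * df["raw_score"] / denom
    df["cell_line"] = beta_table.cell_line
    return df[["target_id", "cell_line", "raw_score", "normalized_score"]]


def distal_summary(
    scores_by_line: pd.DataFrame,
    distal_lines: list[str],
    e0_line: str = "E0",
    selection_cutoff: float = -0.1,
) -> pd.DataFrame:
    """Rank targets on distance specificity of their screen effect.

    ``scores_by_line`` is a long frame (target_id, cell_line,
    normalized_score).  avg_distal is the mean normalized score over the
    distal lines; targets with a normalized score <= ``selection_cutoff``
    in at least one distal line are flagged ``selected``; delta =
    score(E0) - avg_distal; the output is sorted by delta, descending.
    """
    wide = scores_by_line.pivot_table(
        index="target_id", columns="cell_line", values="normalized_score"
    )
    needed = [e0_line] + list(distal_lines)
    missing = [l for l in needed if l not in wide.columns]
    if missing:
        raise ValueError(f"missing cell line(s) in score table: {missing}")
    if wide[needed].isna().any().any():
        raise ValueError("every target needs a score in every named line")
    out = pd.DataFrame(index=wide.index)
    out["score_e0"] = wide[e0_line]
    out["avg_distal"] = wide[list(distal_lines)].mean(axis=1)
    out["selected"] = (wide[list(distal_lines)] <= selection_cutoff).any(axis=1)
    out["delta_e0_minus_distal"] = out["score_e0"] - out["avg_distal"]
    out = out.sort_values("delta_e0_minus_distal", ascending=False)
    out["delta_rank"] = np.arange(1, len(out) + 1)
    return out.reset_index()


def screen_pipeline(
    beta_tables: list[BetaTable],
    distal_lines: list[str],
    e0_line: str = "E0",
    selection_cutoff: float = -0.1,
    score_sign: int = -1,
) -> pd.DataFrame:
    """Normalize every line and compute the distal-specificity ranking."""
    scores = pd.concat(
        [normalize_scores(t, score_sign=score_sign) for t in beta_tables],
        ignore_index=True,
    )
    return distal_summary(scores, distal_lines, e0_line, selection_cutoff)


def single_guide_fc(flow: FlowSummary, anchor_fc: float = 1.0) -> float:
    """Background-subtracted, control- and anchor-normalized reporter FC.

    fc_raw = (kd - background) / mean(control_i - background); the return
    value is fc_raw / anchor_fc, where anchor_fc is the same quantity for
    the promoter-targeting guide.
    """
    denom = float(np.mean([c - flow.background for c in flow.control_guides]))
    if denom <= 0:
        raise ValueError("mean background-subtracted control signal must be > 0")
    if anchor_fc == 0:
        raise ValueError("anchor_fc must be nonzero")
    fc_raw = (flow.kd_guide - flow.background) / denom
    return fc_raw / anchor_fc
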