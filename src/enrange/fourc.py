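"""4C-seq fragment-level coverage normalization and smoothing.

A viewpoint's profile is an ordered vector of per-restriction-fragment
contact counts; "blind" fragments (no secondary restriction site) carry
no usable signal and are excluded from all arithmetic.  Normalization
rescales non-blind counts to one million intra-chromosomal reads after
excluding the two highest-count fragments from the scale factor (they
remain in the output); smoothing is a centered running mean over
fragment order, shrinking to the available fragments at the edges.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FragmentProfile", "normalize_profile", "smooth_profile",
           "read_fragment_profile", "write_fragment_profile"]


class FragmentProfile:
    """Ordered 4C fragments: (interval, count, blind flag) for one viewpoint."""

    def __init__(self, df: pd.DataFrame, viewpoint: str = "") -> None:
        for col in ("chrom", "start", "end", "count", "blind"):
            if col not in df.columns:
                raise ValueError(f"fragment frame missing column {col}")
        if (df["count"] < 0).any():
            raise ValueError("fragment counts must be >= 0")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.viewpoint = viewpoint

    def __len__(self) -> int:
        return len(self.df)

    @property
    def nonblind_counts(self) -> np.ndarray:
        return self.df.loc[~self.df["blind"], "count"].to_numpy(float)


def normalize_profile(profile: FragmentProfile) -> FragmentProfile:
    """Scale non-blind counts to 1e6 reads, excluding the top two from the sum.

    Let S be the sum of non-blind counts minus the two largest non-blind
    counts (ties broken by fragment order); every non-blind count is
    multiplied by 1e6 / S.  Blind fragments pass through untouched.  The
    two top fragments are excluded only from S, not from the output, so
    their scaled values may exceed 1e6.
    """
    nb_mask = ~profile.df["blind"].to_numpy()
    counts = profile.df["count"].to_numpy(float)
    nb_counts = counts[nb_mask]
    if nb_counts.size < 3:
        raise ValueError("need >= 3 non-blind fragments to normalize")
    # two highest by count; stable sort keeps coordinate order among ties
    order = np.argsort(nb_counts, kind="stable")
    top2 = order[-2:]
    s = float(nb_counts.sum() - nb_counts[top2].sum())
    if s == 0:
        raise ValueError("scale denominator is 0 (all signal in the top two fragments)")
    scaled = counts.copy()
    scaled[nb_mask] = nb_counts * (1e6 / s)
    out = profile.df.copy()
    out["count"] = scaled
    return FragmentProfile(out, viewpoint=profile.viewpoint)


def smooth_profile(profile: FragmentProfile, window: int = 21) -> FragmentProfile:
    """Centered running mean over non-blind fragments.

    ``window`` must be odd; at the profile edges the window shrinks to the
    fragments that exist.  Blind fragments are dropped from the output
    (they contribute nothing to the running mean either).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    nb = profile.df.loc[~profile.df["blind"]].reset_index(drop=True)
    smoothed = (
        nb["count"].rolling(window=window, center=True, min_periods=1).mean()
    )
    out = nb.copy()
    out["count"] = smoothed
    return FragmentProfile(out, viewpoint=profile.viewpoint)


def read_fragment_profile(path: str | Path, viewpoint: str = "") -> FragmentProfile:
    df = pd.read_csv(path, sep="\t")
    if "blind" in df.columns:
        df["blind"] = df["blind"].astype(bool)
    return FragmentProfile(df, viewpoint=viewpoint)


def write_fragment_profile(profile: FragmentProfile, path: str | Path) -> None:
    profile.df.to_csv(path, sep="\t", index=False)
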