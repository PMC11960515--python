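"""Readers, writers and validation for the tabular formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention); a TSS is a
single 0-based position.  Element-gene link tables follow the thresholded
ENCODE-rE2G TSV dialect (configurable column map), contact-domain sets are
BED3+, differential-expression tables are the usual DESeq2-style per-gene
output, coverage tracks are bedGraph, and screen beta tables are
MAGeCK-MLE-style gene summaries with one beta column per sorted gate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomicInterval",
    "EnhancerGeneLink",
    "LinkTable",
    "CcdDomainSet",
    "DeRecord",
    "DeTable",
    "CoverageTrack",
    "BetaTable",
    "DEFAULT_LINK_COLUMN_MAP",
    "DEFAULT_DE_COLUMN_MAP",
    "read_link_table",
    "write_link_table",
    "read_ccd_bed",
    "write_ccd_bed",
    "read_de_table",
    "write_de_table",
    "read_coverage_bedgraph",
    "read_beta_table",
    "read_beta_tables",
    "write_beta_table",
]


class FormatError(ValueError):
    """An input file does not conform to its declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class EnhancerGeneLink:
    """One predicted element-to-gene regulatory link.

    ``e2g_score`` is the machine-learned link score in [0, 1];
    ``distance_bp`` the element-TSS separation; ``features`` carries the
    per-link feature columns of the source table (EP300, H3K27ac, DNase,
    promoter activity, ...).
    """

    element: GenomicInterval
    gene_id: str
    gene_symbol: str
    tss: int
    e2g_score: float
    distance_bp: int
    features: Mapping[str, float] = field(default_factory=dict)
    ubiquitous_flag: bool | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.e2g_score <= 1.0:
            raise ValueError(f"e2g_score must be in [0,1], got {self.e2g_score}")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be >= 0")


def element_tss_distance(start: int, end: int, tss: int) -> int:
    """TSS-to-nearest-element-edge distance; 0 when the TSS is inside."""
    if start <= tss < end:
        return 0
    return min(abs(tss - start), abs(tss - end))


#: Column map matching the thresholded ENCODE-rE2G header.
DEFAULT_LINK_COLUMN_MAP: dict[str, str] = {
    "chrom": "chr",
    "start": "start",
    "end": "end",
    "gene_id": "TargetGeneEnsembl_ID",
    "gene_symbol": "TargetGene",
    "tss": "TargetGeneTSS",
    "score": "Score",
    "distance": "distance",
    "ubiquitous": "TargetGeneIsUbiquitouslyExpressed",
}

_LINK_CORE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "gene_id",
    "gene_symbol",
    "tss",
    "e2g_score",
    "distance_bp",
]


class LinkTable:
    """A collection of element-gene links, grouped by target gene.

    Wraps a DataFrame with the canonical columns ``chrom, start, end,
    gene_id, gene_symbol, tss, e2g_score, distance_bp`` plus any feature
    columns and an optional boolean ``ubiquitous`` column.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        feature_names: Sequence[str] = (),
        provenance: str = "",
        n_dropped: int = 0,
    ) -> None:
        missing = [c for c in _LINK_CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"link frame missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.feature_names = list(feature_names)
        self.provenance = provenance
        self.n_dropped = n_dropped

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> list[str]:
        return list(pd.unique(self.df["gene_id"]))

    def links_for_gene(self, gene_id: str) -> list[EnhancerGeneLink]:
        sub = self.df[self.df["gene_id"] == gene_id]
        return [self._row_to_link(row) for _, row in sub.iterrows()]

    def iter_genes(self) -> Iterable[tuple[str, pd.DataFrame]]:
        yield from self.df.groupby("gene_id", sort=False)

    def _row_to_link(self, row: pd.Series) -> EnhancerGeneLink:
        flag = row.get("ubiquitous")
        return EnhancerGeneLink(
            element=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            gene_id=row["gene_id"],
            gene_symbol=row["gene_symbol"],
            tss=int(row["tss"]),
            e2g_score=float(row["e2g_score"]),
            distance_bp=int(row["distance_bp"]),
            features={f: float(row[f]) for f in self.feature_names},
            ubiquitous_flag=None if flag is None or pd.isna(flag) else bool(flag),
        )


def read_link_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    feature_columns: Sequence[str] | None = None,
) -> LinkTable:
    """Read an element-gene link TSV.

    ``column_map`` maps the canonical roles (chrom/start/end/gene_id/
    gene_symbol/tss/score and optionally distance/ubiquitous) to the file's
    header names.  Rows whose score or coordinates fail to parse are dropped
    and counted in ``LinkTable.n_dropped``.  When no distance column is
    mapped, distance is computed as TSS-to-nearest-element-edge.
    """
    cmap = dict(DEFAULT_LINK_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    if raw.empty and raw.columns.size == 0:
        raise FormatError(f"{path}: empty link table")
    required = ["chrom", "start", "end", "gene_id", "gene_symbol", "tss", "score"]
    for role in required:
        if cmap[role] not in raw.columns:
            raise FormatError(f"{path}: missing mapped column '{cmap[role]}' (role {role})")
    if raw.empty:
        raise FormatError(f"{path}: empty link table")

    df = pd.DataFrame(
        {
            "chrom": raw[cmap["chrom"]],
            "gene_id": raw[cmap["gene_id"]],
            "gene_symbol": raw[cmap["gene_symbol"]],
        }
    )
    numeric = {
        "start": raw[cmap["start"]],
        "end": raw[cmap["end"]],
        "tss": raw[cmap["tss"]],
        "e2g_score": raw[cmap["score"]],
    }
    has_distance = "distance" in cmap and cmap["distance"] in raw.columns
    if has_distance:
        numeric["distance_bp"] = raw[cmap["distance"]]
    for name, col in numeric.items():
        df[name] = pd.to_numeric(col, errors="coerce")

    ok = df[list(numeric)].notna().all(axis=1)
    ok &= df["e2g_score"].between(0.0, 1.0)
    ok &= df["start"] >= 0
    ok &= df["end"] > df["start"]
    n_dropped = int((~ok).sum())
    df = df[ok].copy()
    if df.empty:
        raise FormatError(f"{path}: no parseable rows")
    for name in ("start", "end", "tss"):
        df[name] = df[name].astype(np.int64)
    if has_distance:
        df["distance_bp"] = df["distance_bp"].astype(np.int64)
    else:
        df["distance_bp"] = np.minimum(
            np.abs(df["tss"] - df["start"]), np.abs(df["tss"] - df["end"])
        ).astype(np.int64)
        inside = (df["start"] <= df["tss"]) & (df["tss"] < df["end"])
        df.loc[inside, "distance_bp"] = 0

    if "ubiquitous" in cmap and cmap["ubiquitous"] in raw.columns:
        df["ubiquitous"] = (
            raw.loc[df.index, cmap["ubiquitous"]]
            .str.strip()
            .str.lower()
            .map({"true": True, "false": False, "1": True, "0": False})
        )

    mapped = set(cmap.values())
    features = feature_columns
    if features is None:
        features = [c for c in raw.columns if c not in mapped]
    feat_names = []
    for col in features:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing feature column '{col}'")
        df[col] = pd.to_numeric(raw.loc[df.index, col], errors="coerce")
        feat_names.append(col)
    return LinkTable(df, feature_names=feat_names, provenance=str(path), n_dropped=n_dropped)


def write_link_table(table: LinkTable, path: str | Path) -> None:
    """Write a LinkTable in the canonical dialect (round-trips losslessly)."""
    cols = _LINK_CORE_COLUMNS + (["ubiquitous"] if "ubiquitous" in table.df else [])
    cols += table.feature_names
    out = table.df[cols].rename(
        columns={
            "chrom": "chr",
            "gene_id": "TargetGeneEnsembl_ID",
            "gene_symbol": "TargetGene",
            "tss": "TargetGeneTSS",
            "e2g_score": "Score",
            "distance_bp": "distance",
            "ubiquitous": "TargetGeneIsUbiquitouslyExpressed",
        }
    )
    out.to_csv(path, sep="\t", index=False)


class CcdDomainSet:
    """Sorted, merged (non-overlapping) contact-domain intervals."""

    def __init__(self, df: pd.DataFrame, n_merged: int = 0) -> None:
        self.df = df.reset_index(drop=True)
        self.n_merged = n_merged
        self._by_chrom = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in self.df.groupby("chrom", sort=False)
        }

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "CcdDomainSet":
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        return cls(*_merge_intervals(df))

    def containing_interval(self, chrom: str, pos: int) -> tuple[int, int] | None:
        """The (start, end) of the domain containing ``pos``, if any."""
        if chrom not in self._by_chrom:
            return None
        starts, ends = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return int(starts[i]), int(ends[i])
        return None

    def contains_pair(self, chrom: str, pos_a: int, interval: GenomicInterval) -> bool:
        """True iff ``pos_a`` and the whole ``interval`` sit in one domain."""
        dom = self.containing_interval(chrom, pos_a)
        if dom is None or interval.chrom != chrom:
            return False
        return dom[0] <= interval.start and interval.end <= dom[1]


def _merge_intervals(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    if df.empty:
        return df.assign(start=pd.Series(dtype=np.int64), end=pd.Series(dtype=np.int64)), 0
    df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    rows: list[tuple[str, int, int]] = []
    n_merged = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif s <= cur_e:
                cur_e = max(cur_e, int(e))
                n_merged += 1
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return out, n_merged


def read_ccd_bed(path: str | Path) -> CcdDomainSet:
    """Read a BED3+ file of contact domains; sorts and merges overlaps."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            rows.append((parts[0], start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    merged, n_merged = _merge_intervals(df)
    return CcdDomainSet(merged, n_merged=n_merged)


def write_ccd_bed(ccds: CcdDomainSet, path: str | Path) -> None:
    ccds.df.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class DeRecord:
    """One gene's differential-expression result for one perturbation."""

    gene_id: str
    base_mean: float
    log2fc: float
    fdr: float | None = None

    def __post_init__(self) -> None:
        if self.base_mean < 0:
            raise ValueError("base_mean must be >= 0")
        if self.fdr is not None and not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must be in [0,1]")


DEFAULT_DE_COLUMN_MAP: dict[str, str] = {
    "gene_id": "gene_id",
    "base_mean": "baseMean",
    "log2fc": "log2FoldChange",
    "fdr": "padj",
}


class DeTable:
    """Per-gene differential-expression records for one perturbation."""

    def __init__(self, name: str, df: pd.DataFrame, n_duplicates: int = 0) -> None:
        for col in ("gene_id", "base_mean", "log2fc"):
            if col not in df.columns:
                raise ValueError(f"DE frame missing column {col}")
        if "fdr" not in df.columns:
            df = df.assign(fdr=np.nan)
        if df["gene_id"].duplicated().any():
            raise ValueError("gene_id must be unique within a DeTable")
        self.name = name
        self.df = df.reset_index(drop=True)
        self.n_duplicates = n_duplicates
        self._index = self.df.set_index("gene_id")

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index.index

    def record(self, gene_id: str) -> DeRecord:
        row = self._index.loc[gene_id]
        fdr = None if pd.isna(row["fdr"]) else float(row["fdr"])
        return DeRecord(gene_id, float(row["base_mean"]), float(row["log2fc"]), fdr)

    def log2fc_series(self) -> pd.Series:
        return self._index["log2fc"]


def read_de_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    name: str | None = None,
) -> DeTable:
    """Read a DESeq2-style DE table (TSV or CSV, sniffed from the header)."""
    cmap = dict(DEFAULT_DE_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python")
    present = {role: col for role, col in cmap.items() if col in raw.columns}
    if not {"gene_id", "base_mean", "log2fc"} <= set(present):
        raise FormatError(
            f"{path}: required columns not found "
            f"(need {cmap['gene_id']}, {cmap['base_mean']}, {cmap['log2fc']})"
        )
    df = pd.DataFrame(
        {
            "gene_id": raw[cmap["gene_id"]].astype(str),
            "base_mean": pd.to_numeric(raw[cmap["base_mean"]], errors="coerce"),
            "log2fc": pd.to_numeric(raw[cmap["log2fc"]], errors="coerce"),
        }
    )
    if "fdr" in present:
        df["fdr"] = pd.to_numeric(raw[cmap["fdr"]], errors="coerce")
    else:
        df["fdr"] = np.nan
    dup = df["gene_id"].duplicated(keep="first")
    n_dup = int(dup.sum())
    df = df[~dup].reset_index(drop=True)
    return DeTable(name or path.stem, df, n_duplicates=n_dup)


def write_de_table(table: DeTable, path: str | Path) -> None:
    out = table.df.rename(
        columns={"base_mean": "baseMean", "log2fc": "log2FoldChange", "fdr": "padj"}
    )
    out.to_csv(path, sep="\t", index=False)


class CoverageTrack:
    """bedGraph-semantics coverage: sorted non-overlapping scored intervals."""

    def __init__(self, df: pd.DataFrame) -> None:
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping coverage intervals on {chrom}")
        self.df = df
        self._by_chrom = {
            chrom: (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(float),
            )
            for chrom, sub in df.groupby("chrom", sort=False)
        }

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean coverage over [start, end); 0 where uncovered."""
        if chrom not in self._by_chrom or end <= start:
            return 0.0
        starts, ends, values = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        w = np.maximum(e - s, 0)
        return float(np.dot(w, values[lo:hi]) / (end - start))


def read_coverage_bedgraph(path: str | Path) -> CoverageTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
    )
    return CoverageTrack(df)


class BetaTable:
    """Per-target dual-gate beta scores for one reporter cell line."""

    def __init__(self, cell_line: str, df: pd.DataFrame, anchor_id: str) -> None:
        for col in ("target_id", "beta_low", "beta_high"):
            if col not in df.columns:
                raise ValueError(f"beta frame missing column {col}")
        if anchor_id not in set(df["target_id"]):
            raise ValueError(
                f"anchor '{anchor_id}' absent from beta table for line '{cell_line}'"
            )
        if not np.isfinite(df[["beta_low", "beta_high"]].to_numpy()).all():
            raise ValueError(f"non-finite beta in line '{cell_line}'")
        self.cell_line = cell_line
        self.df = df.reset_index(drop=True)
        self.anchor_id = anchor_id

    def __len__(self) -> int:
        return len(self.df)


def read_beta_table(
    path: str | Path,
    cell_line: str,
    anchor_id: str,
    column_map: Mapping[str, str] | None = None,
) -> BetaTable:
    cmap = {"target_id": "target_id", "beta_low": "beta_low", "beta_high": "beta_high"}
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    raw = pd.read_csv(path, sep="\t")
    for role, col in cmap.items():
        if col not in raw.columns:
            raise FormatError(f"{path}: missing mapped column '{col}' (role {role})")
    df = pd.DataFrame({"target_id": raw[cmap["target_id"]].astype(str)})
    for role in ("beta_low", "beta_high"):
        vals = pd.to_numeric(raw[cmap[role]], errors="coerce")
        if vals.isna().any():
            bad = int(vals.index[vals.isna()][0])
            raise FormatError(f"{path}: unparseable {role} at data row {bad}")
        df[role] = vals
    try:
        return BetaTable(cell_line, df, anchor_id)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def read_beta_tables(
    paths_by_line: Mapping[str, str | Path],
    anchor_id: str,
    column_map: Mapping[str, str] | None = None,
) -> list[BetaTable]:
    """Read one beta table per reporter line; anchor must be present in each."""
    return [
        read_beta_table(path, line, anchor_id, column_map)
        for line, path in paths_by_line.items()
    ]


def write_beta_table(table: BetaTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)
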