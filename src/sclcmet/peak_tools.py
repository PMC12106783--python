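"""Interval utilities for ATAC/ChIP peak post-processing.

All coordinates are 0-based half-open (BED convention).  Peaks are
DataFrames with columns chrom, start, end, summit (absolute bp), log2fc,
padj; a ``peak_id`` column or index identifies rows.

Operations: merge peaks whose inter-interval gap is <= 500 bp, build a
summit +/- 250 bp atlas, drop peaks overlapping blacklist regions, assign
peaks to genes (intragenic, else nearest TSS by linear distance from the
peak midpoint), and collapse peak statistics to one signed score per gene
(the peak with the greatest magnitude change) for pre-ranked enrichment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MERGE_GAP = 500
DEFAULT_FLANK = 250


def _validate_peaks(peaks: pd.DataFrame) -> None:
    for i, (_, row) in enumerate(peaks.iterrows()):
        if not (row["start"] < row["end"]):
            raise ValueError(f"malformed interval at line {i}: start >= end")
        if "summit" in peaks.columns and not (row["start"] <= row["summit"] < row["end"]):
            raise ValueError(f"malformed interval at line {i}: summit outside peak")


def merge_peaks(peaks: pd.DataFrame, gap: int = DEFAULT_MERGE_GAP) -> pd.DataFrame:
    """Union peaks on the same chromosome whose gap is <= ``gap`` bp.

    The merged record keeps the summit (and stats) of the member with the
    most extreme |log2fc|, ties broken toward the leftmost member.
    """
    _validate_peaks(peaks)
    df = peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    rows = []
    cur = None
    members: list[int] = []

    def _flush():
        sub = df.loc[members]
        stat = sub["log2fc"].abs().to_numpy() if "log2fc" in sub else np.zeros(len(sub))
        best = sub.index[int(np.argmax(stat))]  # argmax takes first on ties; sorted = leftmost
        rec = {
            "chrom": cur[0],
            "start": cur[1],
            "end": cur[2],
            "summit": sub.loc[best, "summit"] if "summit" in sub else np.nan,
            "log2fc": sub.loc[best, "log2fc"] if "log2fc" in sub else np.nan,
            "padj": sub.loc[best, "padj"] if "padj" in sub else np.nan,
            "n_merged": len(members),
        }
        rows.append(rec)

    for i, row in df.iterrows():
        if cur is not None and row["chrom"] == cur[0] and row["start"] - cur[2] <= gap:
            cur = (cur[0], cur[1], max(cur[2], int(row["end"])))
            members.append(i)
        else:
            if cur is not None:
                _flush()
            cur = (row["chrom"], int(row["start"]), int(row["end"]))
            members = [i]
    if cur is not None:
        _flush()
    out = pd.DataFrame(rows)
    out.index = [f"merged_{i:04d}" for i in range(len(out))]
    return out


def summit_atlas(
    peaks: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Fixed-width atlas entries [summit - flank, summit + flank) per peak.

    Entries are clipped at chromosome bounds; clipping at the upper bound
    requires ``chrom_sizes`` and raises if the chromosome length is missing.
    ``flank=0`` degenerates to a width-1 window on the summit.
    """
    if "summit" not in peaks.columns:
        raise ValueError("summits required to build an atlas")
    rows = []
    for pid, row in peaks.iterrows():
        s = int(row["summit"])
        start, end = s - flank, s + flank
        if flank == 0:
            start, end = s, s + 1
        start = max(start, 0)
        if chrom_sizes is not None:
            if row["chrom"] not in chrom_sizes:
                raise KeyError(
                    f"missing chromosome length for {row['chrom']} while clipping"
                )
            end = min(end, chrom_sizes[row["chrom"]])
        rec = row.to_dict()
        rec.update({"start": start, "end": end})
        rows.append(rec)
    return pd.DataFrame(rows, index=peaks.index)


def filter_blacklist(peaks: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Drop peaks overlapping any blacklist interval by >= 1 bp (no trimming)."""
    if len(blacklist) == 0:
        return peaks.copy()
    keep = np.ones(len(peaks), dtype=bool)
    by_chrom = {c: g for c, g in blacklist.groupby("chrom")}
    for i, (_, row) in enumerate(peaks.iterrows()):
        bl = by_chrom.get(row["chrom"])
        if bl is None:
            continue
        if ((bl["start"] < row["end"]) & (bl["end"] > row["start"])).any():
            keep[i] = False
    return peaks[keep].copy()


def _tss(annotation: pd.DataFrame) -> np.ndarray:
    return np.where(
        annotation["strand"].to_numpy() == "+",
        annotation["start"].to_numpy(),
        annotation["end"].to_numpy() - 1,
    )


def assign_peak_gene(peaks: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Peak-to-gene map: intragenic peaks to the containing gene, else nearest TSS.

    A peak overlapping a gene body is assigned to that gene with distance 0
    (relation 'intragenic'); overlapping several genes, to the one whose TSS
    is nearest the peak midpoint.  Intergenic peaks go to the gene with the
    minimum |midpoint - TSS| on the same chromosome (relation 'nearest_tss').
    Ties break lexicographically by gene id; peaks on chromosomes absent
    from the annotation are flagged 'unassigned'.
    """
    rows = []
    anno_by_chrom = {c: g for c, g in annotation.groupby("chrom")}
    for pid, pk in peaks.iterrows():
        sub = anno_by_chrom.get(pk["chrom"])
        if sub is None or len(sub) == 0:
            rows.append({"peak_id": pid, "gene_id": "", "relation": "unassigned",
                         "distance": -1})
            continue
        mid = (int(pk["start"]) + int(pk["end"])) // 2
        tss = _tss(sub)
        dist = np.abs(tss - mid)
        gene_ids = sub["gene_id"].to_numpy()
        overlap = (sub["start"].to_numpy() < pk["end"]) & (sub["end"].to_numpy() > pk["start"])
        if overlap.any():
            cand = np.flatnonzero(overlap)
            j = cand[np.lexsort((gene_ids[cand], dist[cand]))[0]]
            rows.append({"peak_id": pid, "gene_id": gene_ids[j],
                         "relation": "intragenic", "distance": 0})
        else:
            j = np.lexsort((gene_ids, dist))[0]
            rows.append({"peak_id": pid, "gene_id": gene_ids[j],
                         "relation": "nearest_tss", "distance": int(dist[j])})
    return pd.DataFrame(rows).set_index("peak_id")


def gene_peak_score(peak_gene_map: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """Per-gene signed log2fc of the associated peak with maximal |log2fc|.

    Genes with no assigned peak are omitted.  Among equal-magnitude peaks
    the first in (chrom, start) order wins.  The result is a valid ranking
    input for pre-ranked enrichment.
    """
    merged = peak_gene_map.join(peaks[["chrom", "start", "log2fc"]], how="inner")
    merged = merged[merged["relation"] != "unassigned"]
    merged = merged.sort_values(["chrom", "start"])
    out = {}
    for gene, sub in merged.groupby("gene_id"):
        vals = sub["log2fc"].to_numpy()
        out[gene] = float(vals[int(np.argmax(np.abs(vals)))])
    return pd.Series(out, name="peak_score").sort_index()


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_narrowpeak(path) -> pd.DataFrame:
    """Read the 7-column narrowPeak dialect written by the simulator."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "summit_offset"],
    )
    df["summit"] = df["start"] + df["summit_offset"]
    df["log2fc"] = df["score"]
    return df.set_index("name")


def read_bed(path) -> pd.DataFrame:
    """Read a minimal 3+ column BED file (chrom, start, end, ...)."""
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df[["chrom", "start", "end"]]
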