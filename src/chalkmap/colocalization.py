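"""Projection of QTL clusters to physical coordinates and DEG overlap.

A QTL cluster's confidence region is the genomic interval bound by its
flanking bin markers (left marker start to right marker end, 1-based
inclusive).  Differentially expressed genes are assigned to a cluster when
their gene model overlaps the interval, optionally widened by a flank for
"near the QTL" reporting; inside hits and within-flank hits are reported
distinctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinMarkerMatrix
from .qtl_mapping import QTLCluster


@dataclass
class ColocalizationRecord:
    gene_id: str
    cluster_id: str
    chrom: str
    relationship: str      # "inside" | "within-flank"
    distance_bp: int       # 0 if inside


def qtl_physical_interval(cluster: QTLCluster, bins: BinMarkerMatrix
                          ) -> tuple[str, int, int]:
    """Physical interval of a cluster from its flanking bin markers."""
    li = bins.marker_index(cluster.left_marker)
    ri = bins.marker_index(cluster.right_marker)
    start = int(bins.start[li])
    end = int(bins.end[ri])
    if start > end:
        raise ValueError(
            f"{cluster.cluster_id}: flanking markers out of order "
            f"({cluster.left_marker} starts after {cluster.right_marker})")
    return str(bins.chroms[li]), start, end


def colocate(genes: pd.DataFrame, intervals: dict[str, tuple[str, int, int]],
             de_results: pd.DataFrame | None = None,
             flank_bp: int = 0, degs_only: bool = True) -> pd.DataFrame:
    """Assign genes to QTL intervals by physical overlap.

    ``genes`` needs gene_id/chrom/start/end columns; ``intervals`` maps a
    cluster id to (chrom, start, end).  When DE results are given, only
    significant genes are assigned (unless ``degs_only`` is False) and the
    DE columns are carried along.  One row per (gene, cluster) pair.
    """
    chroms_known = set(genes["chrom"])
    if de_results is not None:
        known = set(genes["gene_id"])
        missing = [g for g in de_results.index if g not in known]
        if missing and len(missing) == len(de_results):
            raise ValueError("DE gene ids do not match the annotation")
        if degs_only:
            keep = de_results[de_results["significant"]].index
            genes = genes[genes["gene_id"].isin(keep)]
    rows = []
    for cid, (chrom, lo, hi) in intervals.items():
        if chrom not in chroms_known:
            raise ValueError(f"{cid}: chromosome {chrom} absent from the "
                             "gene annotation")
        sub = genes[genes["chrom"] == chrom]
        g_start = sub["start"].to_numpy()
        g_end = sub["end"].to_numpy()
        hit = (g_end >= lo - flank_bp) & (g_start <= hi + flank_bp)
        for gid, s, e in zip(sub["gene_id"].to_numpy()[hit],
                             g_start[hit], g_end[hit]):
            inside = e >= lo and s <= hi
            dist = 0 if inside else int(max(lo - e, s - hi))
            rows.append({
                "gene_id": gid, "cluster": cid, "chrom": chrom,
                "relationship": "inside" if inside else "within-flank",
                "distance_bp": dist,
            })
    out = pd.DataFrame(rows, columns=["gene_id", "cluster", "chrom",
                                      "relationship", "distance_bp"])
    if de_results is not None and len(out):
        cols = [c for c in ("fold_change", "direction", "log2fc", "p",
                            "fdr", "significant") if c in de_results.columns]
        out = out.join(de_results[cols], on="gene_id")
    return out


def per_cluster_counts(coloc: pd.DataFrame) -> pd.Series:
    if coloc.empty:
        return pd.Series(dtype=int)
    return coloc.groupby("cluster")["gene_id"].nunique()
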