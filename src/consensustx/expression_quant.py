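"""Cluster-level expression via the contig-to-cluster map, and qPCR concordance.

Per-contig abundance (counts or FPKM from an external quantifier, or from the
synthetic generator) is attributed to clusters the way a transcript-to-gene
map attributes transcript abundance to genes: the cluster's FPKM in a sample
is the sum over its member contigs.  Reads that match a cultivar-specific
allele contig thereby still count toward the cluster of the representative
sequence, which is the point of quantifying on the contig-to-cluster map.

Expression is optionally normalized to a reference (housekeeping) cluster,
and agreement with an independent measurement (qPCR copy numbers) is scored
as the adjusted r-squared of a simple linear model on log2 values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import AbundanceTable

logger = logging.getLogger(__name__)


def fpkm(fragments: float, effective_length: float, total_mapped: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if effective_length <= 0:
        raise ValueError("effective_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return fragments * 1e9 / (effective_length * total_mapped)


def counts_to_fpkm(table: AbundanceTable, total_mapped: pd.Series | None = None) -> AbundanceTable:
    """Convert a counts-mode table to FPKM using per-contig lengths.

    ``total_mapped`` defaults to the per-sample column sums of the table
    itself (i.e. all counted fragments are treated as mapped).
    """
    if table.mode != "counts":
        raise ValueError("table is not in counts mode")
    if table.lengths is None:
        raise ValueError("counts_to_fpkm requires per-contig lengths")
    lengths = table.lengths.reindex(table.data.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for contig {missing!r}")
    totals = table.data.sum(axis=0) if total_mapped is None else total_mapped
    if (totals <= 0).any():
        raise ValueError("zero library size in at least one sample")
    out = table.data.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return AbundanceTable(data=out, mode="fpkm", lengths=table.lengths)


@dataclass
class ClusterExpression:
    """Cluster x sample FPKM matrix plus the map that produced it."""

    values: pd.DataFrame
    contig_to_cluster: dict[str, int]
    n_unmapped_contigs: int = 0


def aggregate_to_clusters(
    contig_fpkm: AbundanceTable,
    contig_to_cluster: dict[str, int],
    known_clusters: set[int] | None = None,
) -> ClusterExpression:
    """Sum member-contig FPKM into cluster FPKM per sample.

    Contigs absent from the map are dropped (logged); per-sample totals over
    the mapped contigs are conserved exactly.  With ``known_clusters`` given,
    a map entry pointing at an unknown cluster id raises.
    """
    if known_clusters is not None:
        bad = set(contig_to_cluster.values()) - known_clusters
        if bad:
            raise ValueError(f"contig mapped to unknown cluster(s): {sorted(bad)[:5]}")
    data = contig_fpkm.data
    mapped_mask = data.index.isin(contig_to_cluster)
    n_unmapped = int((~mapped_mask).sum())
    if n_unmapped:
        logger.warning("%d contig(s) not in the contig-to-cluster map; dropped", n_unmapped)
    mapped = data.loc[mapped_mask]
    groups = pd.Series(
        [contig_to_cluster[c] for c in mapped.index], index=mapped.index, name="cluster_id"
    )
    values = mapped.groupby(groups).sum()
    values.index.name = "cluster_id"
    return ClusterExpression(
        values=values,
        contig_to_cluster=dict(contig_to_cluster),
        n_unmapped_contigs=n_unmapped,
    )


def normalize_to_reference(
    cluster_expr: pd.DataFrame, reference_cluster_id
) -> pd.DataFrame:
    """Divide every cluster's value by the reference cluster's, per sample."""
    if reference_cluster_id not in cluster_expr.index:
        raise KeyError(f"reference cluster {reference_cluster_id!r} not present")
    ref = cluster_expr.loc[reference_cluster_id]
    zero = ref[ref == 0]
    if len(zero):
        raise ValueError(f"reference FPKM is zero in {zero.index[0]!r}")
    return cluster_expr.div(ref, axis=1)


@dataclass
class ConcordanceResult:
    """Fit of log2 RNA-seq expression on log2 qPCR copy number."""

    slope: float
    intercept: float
    r2_adjusted: float
    n_points: int
    excluded_zero_pairs: int


def concordance(
    qpcr: pd.DataFrame,
    rnaseq: pd.DataFrame,
    log_floor: float = 0.0,
) -> ConcordanceResult:
    """Adjusted r-squared of log2(rnaseq) regressed on log2(qpcr).

    The two matrices are matched on their shared (gene, sample) cells.  Pairs
    where either value is zero are excluded (and counted) unless a positive
    ``log_floor`` is configured, in which case the floor is added to both
    sides before taking logs.  Requires at least 3 usable pairs.  Adjusted
    r2 = 1 - (1 - r2) * (n - 1) / (n - 2) for the single-predictor model.
    """
    genes = qpcr.index.intersection(rnaseq.index)
    samples = qpcr.columns.intersection(rnaseq.columns)
    x = qpcr.loc[genes, samples].to_numpy(dtype=float).ravel()
    y = rnaseq.loc[genes, samples].to_numpy(dtype=float).ravel()
    if log_floor > 0:
        x = x + log_floor
        y = y + log_floor
        excluded = 0
        keep = np.ones(len(x), dtype=bool)
    else:
        keep = (x > 0) & (y > 0)
        excluded = int((~keep).sum())
    x, y = np.log2(x[keep]), np.log2(y[keep])
    n = len(x)
    if n < 3:
        raise ValueError(f"fewer than 3 usable (gene, sample) pairs ({n})")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return ConcordanceResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2_adjusted=float(r2_adj),
        n_points=n,
        excluded_zero_pairs=excluded,
    )
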