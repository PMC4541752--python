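"""Per-cluster metrics, the 2-of-3 retention rule, and composition analysis.

After clustering, every putative cluster is scored on three criteria —
representative length, number of member contigs, and summed FPKM over all
members and samples — and discarded only when it fails **at least two** of
the three.  Tolerating one failure protects short genes and weakly expressed
rare isoforms that a conjunction of hard thresholds would throw away.

Boundary semantics follow the thresholds as stated: length >= 500 passes,
contig count must be strictly greater than 10, summed FPKM strictly greater
than 50.  All three cut-offs and the failure budget are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .merge_cluster import ClusterSet
from .seq_io import AbundanceTable

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["length", "n_contigs", "sum_fpkm", "n_sources"]


@dataclass
class FilterConfig:
    """Thresholds of the three cluster criteria and the failure budget.

    A cluster passes the length criterion when representative length
    >= ``min_length``; the contig criterion when n_contigs > ``min_contigs``;
    the expression criterion when summed FPKM > ``min_sum_fpkm`` (the latter
    two exclusive).  It is discarded when the number of failed criteria
    exceeds ``max_failures`` (default 1, i.e. discard on >= 2 failures).
    """

    min_length: int = 500
    min_contigs: int = 10
    min_sum_fpkm: float = 50.0
    max_failures: int = 1

    def __post_init__(self) -> None:
        if min(self.min_length, self.min_contigs, self.min_sum_fpkm, self.max_failures) < 0:
            raise ValueError("filter thresholds must be non-negative")


def compute_metrics(
    cluster_set: ClusterSet, abundance: AbundanceTable | None = None
) -> pd.DataFrame:
    """Length, contig count, summed FPKM and source breadth per cluster.

    ``sum_fpkm`` sums the FPKM of every member contig over every sample;
    contigs absent from the abundance table contribute 0 (a warning reports
    how many).  Without an abundance table ``sum_fpkm`` is NaN and the filter
    degrades to the two structural criteria.
    """
    contig_sum: dict[str, float] | None = None
    if abundance is not None:
        if abundance.mode != "fpkm":
            raise ValueError("compute_metrics expects an FPKM-mode abundance table")
        contig_sum = abundance.data.sum(axis=1).to_dict()

    rows = []
    n_missing = 0
    for cluster in cluster_set.clusters:
        if contig_sum is None:
            fpkm = np.nan
        else:
            fpkm = 0.0
            for m in cluster.members:
                if m.contig_id in contig_sum:
                    fpkm += contig_sum[m.contig_id]
                else:
                    n_missing += 1
        rows.append(
            {
                "cluster_id": cluster.cluster_id,
                "length": cluster.representative_length,
                "n_contigs": cluster.size,
                "sum_fpkm": fpkm,
                "n_sources": cluster.source_breadth,
            }
        )
    if n_missing:
        logger.warning(
            "%d cluster member contig(s) absent from the abundance table; "
            "they contribute 0 FPKM",
            n_missing,
        )
    return pd.DataFrame(rows, columns=["cluster_id"] + METRIC_COLUMNS).set_index(
        "cluster_id"
    )


def apply_filter(metrics: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Apply the 2-of-3 rule; returns metrics plus per-criterion flags.

    Output columns: ``pass_length``, ``pass_contigs``, ``pass_fpkm`` (the
    per-cluster boolean triple), ``n_failed`` and ``retained``.  When
    ``sum_fpkm`` is entirely NaN (no abundance supplied) the expression
    criterion is left out of the failure count and a warning is emitted.
    """
    config = config or FilterConfig()
    out = metrics.copy()
    out["pass_length"] = out["length"] >= config.min_length
    out["pass_contigs"] = out["n_contigs"] > config.min_contigs
    fpkm = out["sum_fpkm"]
    fpkm_known = fpkm.notna()
    if not fpkm_known.any():
        logger.warning(
            "no FPKM available: filtering on length and contig count only "
            "(2-criteria mode)"
        )
        out["pass_fpkm"] = pd.NA
        out["n_failed"] = (~out["pass_length"]).astype(int) + (
            ~out["pass_contigs"]
        ).astype(int)
    else:
        out["pass_fpkm"] = fpkm > config.min_sum_fpkm
        out["n_failed"] = (
            (~out["pass_length"]).astype(int)
            + (~out["pass_contigs"]).astype(int)
            + (~out["pass_fpkm"].astype(bool)).astype(int)
        )
    out["retained"] = out["n_failed"] <= config.max_failures
    return out


def filter_threshold_scan(
    metrics: pd.DataFrame,
    contig_thresholds: Sequence[float],
    fpkm_thresholds: Sequence[float],
    length_thresholds: Sequence[float],
) -> pd.DataFrame:
    """Clusters strictly below each candidate threshold, per metric.

    The long-form table (columns ``metric``, ``threshold``, ``n_below``) is
    the basis for choosing filter cut-offs by inspection: counts are
    non-decreasing in the candidate value.
    """
    scans = {
        "n_contigs": contig_thresholds,
        "sum_fpkm": fpkm_thresholds,
        "length": length_thresholds,
    }
    rows = []
    for metric, thresholds in scans.items():
        if len(thresholds) == 0:
            raise ValueError(f"empty threshold list for {metric}")
        values = metrics[metric]
        for t in thresholds:
            rows.append(
                {"metric": metric, "threshold": t, "n_below": int((values < t).sum())}
            )
    return pd.DataFrame(rows, columns=["metric", "threshold", "n_below"])


def participation_matrix(cluster_set: ClusterSet) -> pd.DataFrame:
    """Cluster x source-tag matrix of member counts (row sums = cluster sizes)."""
    tags = sorted({t for c in cluster_set.clusters for t in c.source_tags})
    data = np.zeros((len(cluster_set.clusters), len(tags)), dtype=int)
    tag_idx = {t: j for j, t in enumerate(tags)}
    for i, cluster in enumerate(cluster_set.clusters):
        for m in cluster.members:
            data[i, tag_idx[m.contig_id.split("|", 1)[0]]] += 1
    return pd.DataFrame(
        data, index=[c.cluster_id for c in cluster_set.clusters], columns=tags
    )


def assembly_correlation(
    participation: pd.DataFrame, cluster_set: ClusterSet | None = None,
    true_clusters_only: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of assemblies over their cluster-participation vectors.

    Two assemblies correlate strongly when their contigs land in the same
    clusters.  By default the correlation is computed over true clusters
    (size >= 2) only, since singletons carry no co-occurrence signal; pass
    ``true_clusters_only=False`` to use all clusters.  Requires at least two
    clusters in the domain; a zero-variance participation vector yields NaN
    for its assembly.
    """
    part = participation
    if true_clusters_only and cluster_set is not None:
        true_ids = [c.cluster_id for c in cluster_set.clusters if c.size >= 2]
        part = part.loc[part.index.intersection(true_ids)]
    if len(part) < 2:
        raise ValueError("need at least 2 clusters to correlate assemblies")
    return part.corr(method="pearson")


def breadth_histogram(
    cluster_set: ClusterSet, breadth_cutoff: int = 10
) -> tuple[pd.Series, list[int]]:
    """Histogram of clusters by source breadth, plus the core-set cluster ids.

    The core set holds clusters whose members come from more than
    ``breadth_cutoff`` distinct single assemblies — the broadly supported
    part of the consensus.
    """
    breadths = pd.Series(
        {c.cluster_id: c.source_breadth for c in cluster_set.clusters}, dtype=int
    )
    hist = breadths.value_counts().sort_index()
    hist.index.name = "n_sources"
    core = sorted(breadths.index[breadths > breadth_cutoff].tolist())
    return hist, core
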