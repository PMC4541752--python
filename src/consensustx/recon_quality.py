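"""Reference-gene reconstruction quality by self-normalized bitscore ratio.

How well does an assembly reconstruct a known gene?  Align the reference
coding sequence locally (Smith–Waterman, both strands) against every contig,
convert the best raw score to bits with the Karlin–Altschul transform

    bits = (lambda * S - ln K) / ln 2,

and divide by the bits of the reference aligned to itself.  A verbatim copy
scores ratio 1.0; a missing gene scores ~0; an exact half-length fragment of
a kb-scale gene scores close to 0.5.  Because the ratio is self-normalized it
is largely insensitive to the exact scoring scheme or aligner constants.

The same machinery predicts isoforms: counting the contigs whose individual
ratio exceeds a threshold (default 0.8) flags genes represented by more than
one high-quality, distinct sequence — the signature of a near-identical
isoform pair surviving clustering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from skbio.alignment import pair_align

from .merge_cluster import revcomp
from .seq_io import AssemblyCollection, SequenceRecord

logger = logging.getLogger(__name__)

# (match, mismatch, gap_open, gap_extend) -> (lambda [nats/score unit], K).
# Standard nucleotide Karlin-Altschul parameters for the default scheme.
KARLIN_ALTSCHUL: dict[tuple[float, float, float, float], tuple[float, float]] = {
    (1.0, -2.0, 5.0, 2.0): (1.28, 0.46),
}


def ungapped_lambda(match: float, mismatch: float, p_match: float = 0.25) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for the ungapped lambda.

    Assumes uniform base composition; useful when adopting a scoring scheme
    absent from the built-in table (K must then be supplied by the caller).
    """
    f = lambda lam: p_match * math.exp(lam * match) + (1 - p_match) * math.exp(
        lam * mismatch
    ) - 1.0
    return brentq(f, 1e-6, 10.0)


@dataclass
class ScoringScheme:
    """Local-alignment scoring and the statistics converting scores to bits.

    ``gap_open`` and ``gap_extend`` are positive costs: a gap of length k is
    penalized ``gap_open + k * gap_extend``.  ``lam`` (nats per score unit)
    and ``K`` come from the standard Karlin–Altschul parameter table for the
    chosen rewards; the default (+1/-2, 5/2 gaps) uses lambda = 1.28,
    K = 0.46.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    lam: float | None = None
    K: float | None = None

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.lam is None or self.K is None:
            key = (self.match, self.mismatch, self.gap_open, self.gap_extend)
            if key not in KARLIN_ALTSCHUL:
                raise ValueError(
                    "no tabulated Karlin-Altschul parameters for this scheme; "
                    "pass lam and K explicitly (see ungapped_lambda)"
                )
            self.lam, self.K = KARLIN_ALTSCHUL[key]
        if self.lam <= 0 or not 0 < self.K < 1:
            raise ValueError("need lambda > 0 and 0 < K < 1")


def bitscore(raw_score: float, scheme: ScoringScheme) -> float:
    """Karlin–Altschul bit score of a raw local-alignment score."""
    return (scheme.lam * raw_score - math.log(scheme.K)) / math.log(2.0)


@dataclass
class ReferenceGene:
    """A reference coding sequence with its precomputed self-alignment bits."""

    gene_id: str
    residues: str
    self_bits: float

    @classmethod
    def from_sequence(cls, record: SequenceRecord, scheme: ScoringScheme) -> "ReferenceGene":
        # The optimal self local alignment is the full-length exact match.
        self_raw = scheme.match * len(record.residues)
        return cls(record.id, record.residues, bitscore(self_raw, scheme))


@dataclass
class QualityCell:
    """Reconstruction of one gene in one assembly."""

    gene_id: str
    assembly_id: str
    best_contig_id: str | None
    ratio: float
    n_hits_above: int


def local_score(a: str, b: str, scheme: ScoringScheme) -> float:
    """Optimal Smith–Waterman score of ``a`` vs ``b`` (single strand)."""
    if not a or not b:
        return 0.0
    res = pair_align(
        a,
        b,
        mode="local",
        sub_score=(scheme.match, scheme.mismatch),
        gap_cost=(scheme.gap_open, scheme.gap_extend),
        max_paths=0,
    )
    return float(res.score)


def _shares_seed(gene: str, contig: str, w: int = 11) -> bool:
    """Exact-word prescreen: does any length-w word of the gene occur in the
    contig on either strand?  Contigs sharing no seed cannot produce a
    meaningful local alignment and are skipped (score 0)."""
    words = {gene[i : i + w] for i in range(0, len(gene) - w + 1)}
    for hay in (contig, revcomp(contig)):
        for i in range(0, len(hay) - w + 1):
            if hay[i : i + w] in words:
                return True
    return False


def best_local_hits(
    gene: ReferenceGene,
    contigs: list[SequenceRecord],
    scheme: ScoringScheme,
    prescreen: bool = True,
) -> list[tuple[str, float, float]]:
    """Per-contig best local score over both strands, sorted descending.

    Returns (contig_id, raw_score, bits) triples for contigs with a positive
    score.  ``prescreen=False`` disables the exact-seed skip and aligns every
    contig (the slow exhaustive route).
    """
    hits: list[tuple[str, float, float]] = []
    for rec in contigs:
        if prescreen and not _shares_seed(gene.residues, rec.residues):
            continue
        raw = max(
            local_score(gene.residues, rec.residues, scheme),
            local_score(gene.residues, revcomp(rec.residues), scheme),
        )
        if raw > 0:
            hits.append((rec.id, raw, bitscore(raw, scheme)))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def reconstruction_ratio(
    gene: ReferenceGene,
    contigs: list[SequenceRecord],
    scheme: ScoringScheme,
    assembly_id: str = "",
    hit_threshold: float = 0.8,
) -> QualityCell:
    """Best-hit bits over self bits, clamped to [0, 1], plus the hit count.

    No positive-scoring contig means ratio 0 with no best contig.  The local
    alignment of the gene against anything cannot out-score the gene against
    itself under positive-match scoring, so the clamp only absorbs float
    round-off.
    """
    hits = best_local_hits(gene, contigs, scheme)
    if not hits:
        return QualityCell(gene.gene_id, assembly_id, None, 0.0, 0)
    best_id, _, best_bits = hits[0]
    ratio = min(1.0, max(0.0, best_bits / gene.self_bits))
    n_above = sum(1 for _, _, b in hits if b / gene.self_bits > hit_threshold)
    return QualityCell(gene.gene_id, assembly_id, best_id, ratio, n_above)


def isoform_hit_count(
    gene: ReferenceGene,
    contigs: list[SequenceRecord],
    scheme: ScoringScheme,
    hit_threshold: float = 0.8,
) -> int:
    """Distinct contigs whose individual bitscore ratio exceeds the threshold.

    A count of 2 for a gene whose assembly holds both the gene and a ~97%
    identical partner is the isoform-prediction signal.
    """
    cell = reconstruction_ratio(gene, contigs, scheme, hit_threshold=hit_threshold)
    return cell.n_hits_above


@dataclass
class QualityMatrix:
    """Gene x assembly reconstruction-quality matrix."""

    ratio: pd.DataFrame
    n_hits: pd.DataFrame
    best_contig: pd.DataFrame
    cells: dict[tuple[str, str], QualityCell] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Per-assembly minimum and mean ratio."""
        return pd.DataFrame(
            {"min_ratio": self.ratio.min(axis=0), "mean_ratio": self.ratio.mean(axis=0)}
        )


def quality_matrix(
    genes: list[ReferenceGene],
    assemblies: AssemblyCollection,
    scheme: ScoringScheme,
    hit_threshold: float = 0.8,
) -> QualityMatrix:
    """Score every reference gene against every assembly."""
    if not genes:
        raise ValueError("empty reference gene panel")
    tags = assemblies.source_tags
    gene_ids = [g.gene_id for g in genes]
    ratio = pd.DataFrame(0.0, index=gene_ids, columns=tags)
    n_hits = pd.DataFrame(0, index=gene_ids, columns=tags)
    best = pd.DataFrame("", index=gene_ids, columns=tags, dtype=object)
    cells: dict[tuple[str, str], QualityCell] = {}
    for tag in tags:
        contigs = assemblies.assemblies[tag]
        for gene in genes:
            cell = reconstruction_ratio(
                gene, contigs, scheme, assembly_id=tag, hit_threshold=hit_threshold
            )
            ratio.loc[gene.gene_id, tag] = cell.ratio
            n_hits.loc[gene.gene_id, tag] = cell.n_hits_above
            best.loc[gene.gene_id, tag] = cell.best_contig_id or ""
            cells[(gene.gene_id, tag)] = cell
    return QualityMatrix(ratio=ratio, n_hits=n_hits, best_contig=best, cells=cells)


def hit_coverage_table(
    hits: pd.DataFrame,
    target_lengths: dict[str, int],
    coverage_thresholds: tuple[int, ...] = (100, 90, 80, 70, 60, 50, 40, 30, 20, 10),
    evalue_cutoff: float = 1e-20,
) -> pd.Series:
    """Cumulative count of targets matched at each percent-coverage threshold.

    Hits above the e-value cutoff are dropped; each target's best coverage is
    the maximal aligned target span over its remaining hits, as a percent of
    target length.  The returned series counts targets with best coverage >=
    each threshold — non-decreasing as the threshold decreases, the shape of
    a full-length-reconstruction table.
    """
    unknown = set(hits["subject_id"]) - set(target_lengths)
    if unknown:
        raise KeyError(f"hits reference unknown target(s): {sorted(unknown)[:5]}")
    kept = hits[hits["e_value"] <= evalue_cutoff].copy()
    counts = {}
    if kept.empty:
        best_cov = pd.Series(dtype=float)
    else:
        span = (kept["s_end"] - kept["s_start"]).abs() + 1
        lengths = kept["subject_id"].map(target_lengths)
        kept["coverage"] = span / lengths * 100.0
        best_cov = kept.groupby("subject_id")["coverage"].max()
    for t in coverage_thresholds:
        counts[t] = int((best_cov >= t).sum())
    out = pd.Series(counts, name="n_targets")
    out.index.name = "pct_coverage"
    return out
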