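"""Pooling and greedy identity clustering of multi-assembly contig sets.

Contigs from all single assemblies are pooled and clustered incrementally at
a nucleotide-identity threshold ``c`` (default 0.97): contigs are scanned in
order of decreasing length, and each one either joins the first existing
cluster whose representative it matches at identity >= c, or founds a new
cluster with itself as representative.  Because the scan is length-descending,
every representative is at least as long as every member of its cluster, so
fragments are credited as contained matches.

Identity between two sequences is the number of identical aligned bases
divided by the length of the *shorter* sequence, under an alignment in which
the overhangs of the longer sequence are free (end-gap-free / containment
semantics).  This is the convention of greedy clustering tools used for
transcriptome redundancy removal: a perfect fragment of a longer contig has
identity 1.0 and collapses into it, while two diverged isoforms of similar
length (e.g. ~96%) stay apart at c = 0.97.

A conservative shared-word prescreen (default word length 9) prunes candidate
representatives that provably cannot reach the threshold, without ever
changing the result (see :func:`word_filter_pass`).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .seq_io import SequenceRecord

_REVCOMP = str.maketrans("ACGTN", "TGCAN")

IDENTITY_EPS = 1e-9  # guard against float representation of exact thresholds


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass
class ClusterParams:
    """Knobs of the greedy clustering stage.

    identity_threshold
        Minimum fraction of identical bases (over the shorter sequence) for a
        contig to join a cluster.  0.97 merges cultivar alleles differing by
        a few SNPs while keeping ~96%-identical isoform pairs apart.
    word_length
        Word size of the conservative prescreen (the ``n`` of word counting).
    both_strands
        Compare contigs on both strands (assemblers emit arbitrary strands).
    assign_mode
        ``first_match`` joins the first qualifying representative (classic
        greedy behaviour); ``best_match`` scans all and joins the best.
    """

    identity_threshold: float = 0.97
    word_length: int = 9
    both_strands: bool = True
    assign_mode: str = "first_match"

    def __post_init__(self) -> None:
        if not 0.90 <= self.identity_threshold <= 1.00:
            raise ValueError("identity_threshold must be in [0.90, 1.00]")
        if not 4 <= self.word_length <= 12:
            raise ValueError("word_length must be in [4, 12]")
        if self.assign_mode not in ("first_match", "best_match"):
            raise ValueError(f"unknown assign_mode {self.assign_mode!r}")


@dataclass
class ClusterMember:
    contig_id: str
    length: int
    identity: float  # fraction of identical bases to the representative
    strand: str  # '+' or '-'


@dataclass
class Cluster:
    cluster_id: int
    representative_id: str
    members: list[ClusterMember]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def representative_length(self) -> int:
        for m in self.members:
            if m.contig_id == self.representative_id:
                return m.length
        raise ValueError(f"representative {self.representative_id!r} not among members")

    @property
    def source_tags(self) -> set[str]:
        return {m.contig_id.split("|", 1)[0] for m in self.members}

    @property
    def source_breadth(self) -> int:
        return len(self.source_tags)


@dataclass
class ClusterSet:
    """A partition of the pooled contig set into clusters."""

    clusters: list[Cluster]
    params: ClusterParams
    contig_to_cluster: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_contigs(self) -> int:
        return sum(c.size for c in self.clusters)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.clusters if c.size == 1)

    @property
    def n_true_clusters(self) -> int:
        """Clusters holding at least two contigs."""
        return sum(1 for c in self.clusters if c.size >= 2)

    def validate(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            for m in c.members:
                if m.contig_id in seen:
                    raise ValueError(f"contig {m.contig_id!r} appears in two clusters")
                seen.add(m.contig_id)
                if self.contig_to_cluster.get(m.contig_id) != c.cluster_id:
                    raise ValueError(f"contig_to_cluster inconsistent for {m.contig_id!r}")
        if len(seen) != len(self.contig_to_cluster):
            raise ValueError("contig_to_cluster does not cover the member set")


def _hw_matches(query: str, target: str) -> int:
    """Identical aligned bases of the best end-gap-free (infix) alignment.

    ``query`` must be the shorter sequence; overhangs of ``target`` are free.
    N positions never count as matches even when they align to an N.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    cigar = res["cigar"]
    if cigar is None:  # pragma: no cover - edlib always returns a path here
        return 0
    matches = 0
    qi = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch == "=":
            segment = query[qi : qi + ln]
            matches += ln - segment.count("N")
            qi += ln
        elif ch in ("X", "I"):  # I consumes query
            qi += ln
        # 'D' consumes target only
    return matches


def pair_identity(a: str, b: str, both_strands: bool = True) -> tuple[float, str]:
    """Fraction of identical bases over the shorter sequence, and its strand.

    The alignment is end-gap-free: the shorter sequence is aligned inside the
    longer one with the longer sequence's overhangs unpenalized, so exact
    containment saturates at identity 1.0.  With ``both_strands`` the reverse
    complement of the shorter sequence is also tried and the better strand is
    reported ('+' wins ties).
    """
    if not a or not b:
        raise ValueError("pair_identity requires non-empty sequences")
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    ls = len(query)
    ident_fwd = _hw_matches(query, target) / ls
    if not both_strands:
        return ident_fwd, "+"
    ident_rev = _hw_matches(revcomp(query), target) / ls
    if ident_rev > ident_fwd:
        return ident_rev, "-"
    return ident_fwd, "+"


def _word_counter(seq: str, n: int) -> Counter:
    return Counter(seq[i : i + n] for i in range(len(seq) - n + 1))


def _shared_words(wa: Counter, wb: Counter) -> int:
    if len(wa) > len(wb):
        wa, wb = wb, wa
    return sum(min(cnt, wb[w]) for w, cnt in wa.items() if w in wb)


def word_filter_pass(
    a: str,
    b: str,
    c: float,
    n: int = 9,
    both_strands: bool = True,
    words_a: tuple[Counter, Counter] | None = None,
    words_b: Counter | None = None,
) -> bool:
    """Conservative prescreen: can identity(a, b) possibly reach ``c``?

    Two sequences at identity >= c over shorter length ``Ls`` have at most
    ``ceil((1-c)*Ls)`` non-matching columns on the shorter sequence, and each
    such column destroys at most ``n`` of its ``Ls - n + 1`` length-``n``
    windows; the aligned sequences therefore share at least
    ``Ls - n + 1 - n*ceil((1-c)*Ls)`` words (counted with multiplicity).
    Returns False only when the shared-word count on both strands falls below
    that bound — i.e. it never rejects a pair the aligner would accept.

    ``words_a`` (forward and reverse-complement counters of the shorter
    sequence) and ``words_b`` (forward counter of the longer) may be supplied
    to amortize word counting across many comparisons.
    """
    query, target = (a, b) if len(a) <= len(b) else (b, a)
    ls = len(query)
    if ls < n:
        return True  # too short for the bound to apply
    bound = (ls - n + 1) - n * math.ceil((1.0 - c) * ls)
    if bound <= 0:
        return True
    if words_a is None:
        words_a = (_word_counter(query, n), _word_counter(revcomp(query), n))
    if words_b is None:
        words_b = _word_counter(target, n)
    if _shared_words(words_a[0], words_b) >= bound:
        return True
    if both_strands and _shared_words(words_a[1], words_b) >= bound:
        return True
    return False


def greedy_cluster(
    contigs: list[SequenceRecord],
    params: ClusterParams | None = None,
    use_word_filter: bool = True,
) -> ClusterSet:
    """Incremental greedy clustering of pooled contigs.

    Contigs are processed longest-first (ties broken by input order).  Each
    contig joins the first (``first_match``) or best (``best_match``) existing
    representative it matches at identity >= the threshold; otherwise it
    founds a new cluster.  ``use_word_filter=False`` disables the prescreen
    and aligns against every candidate; the result is identical because the
    prescreen is conservative.
    """
    params = params or ClusterParams()
    c = params.identity_threshold
    n = params.word_length

    ids = [r.id for r in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("pooled contigs must have unique ids")

    order = sorted(range(len(contigs)), key=lambda i: (-len(contigs[i].residues), i))

    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_words: list[Counter] = []
    contig_to_cluster: dict[str, int] = {}

    for idx in order:
        rec = contigs[idx]
        seq = rec.residues
        q_words = (_word_counter(seq, n), _word_counter(revcomp(seq), n))

        best: tuple[float, str, int] | None = None  # (identity, strand, cluster idx)
        for k, rep_seq in enumerate(rep_seqs):
            if use_word_filter and not word_filter_pass(
                seq,
                rep_seq,
                c,
                n,
                both_strands=params.both_strands,
                words_a=q_words,
                words_b=rep_words[k],
            ):
                continue
            ident, strand = pair_identity(seq, rep_seq, params.both_strands)
            if ident + IDENTITY_EPS >= c:
                if params.assign_mode == "first_match":
                    best = (ident, strand, k)
                    break
                if best is None or ident > best[0]:
                    best = (ident, strand, k)

        if best is not None:
            ident, strand, k = best
            clusters[k].members.append(ClusterMember(rec.id, len(seq), ident, strand))
            contig_to_cluster[rec.id] = clusters[k].cluster_id
        else:
            cid = len(clusters)
            clusters.append(
                Cluster(cid, rec.id, [ClusterMember(rec.id, len(seq), 1.0, "+")])
            )
            rep_seqs.append(seq)
            rep_words.append(_word_counter(seq, n))
            contig_to_cluster[rec.id] = cid

    return ClusterSet(clusters=clusters, params=params, contig_to_cluster=contig_to_cluster)


def cluster_threshold_scan(
    contigs: list[SequenceRecord],
    thresholds: list[float],
    params: ClusterParams | None = None,
) -> pd.DataFrame:
    """Re-cluster the pooled set at each identity threshold.

    Returns a DataFrame with one row per threshold and columns
    ``n_clusters``, ``n_singletons``, ``n_true_clusters`` — the shape of a
    threshold-scan table used to pick the clustering identity.
    """
    base = params or ClusterParams()
    rows = []
    for t in thresholds:
        if not 0.90 <= t <= 1.00:
            raise ValueError(f"threshold {t} outside [0.90, 1.00]")
        p = ClusterParams(
            identity_threshold=t,
            word_length=base.word_length,
            both_strands=base.both_strands,
            assign_mode=base.assign_mode,
        )
        cs = greedy_cluster(contigs, p)
        rows.append(
            {
                "threshold": t,
                "n_clusters": cs.n_clusters,
                "n_singletons": cs.n_singletons,
                "n_true_clusters": cs.n_true_clusters,
            }
        )
    return pd.DataFrame(rows).set_index("threshold")


def representatives(cluster_set: ClusterSet, contigs: list[SequenceRecord]) -> list[SequenceRecord]:
    """Representative sequences of each cluster, in cluster order."""
    by_id = {r.id: r for r in contigs}
    return [by_id[c.representative_id] for c in cluster_set.clusters]


def contig_to_cluster_frame(cluster_set: ClusterSet) -> pd.DataFrame:
    """The contig-to-cluster map as a two-column DataFrame (TSV-ready)."""
    rows = [
        {"contig_id": m.contig_id, "cluster_id": c.cluster_id}
        for c in cluster_set.clusters
        for m in c.members
    ]
    return pd.DataFrame(rows, columns=["contig_id", "cluster_id"])
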