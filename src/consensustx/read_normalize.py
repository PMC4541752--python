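"""Streaming digital normalization of sequencing reads by median k-mer coverage.

Over-represented transcripts flood de novo assemblers with redundant reads.
This stage walks the read stream once, in input order, and keeps a read only
if its median k-mer coverage — computed against the k-mers of the reads
*already retained* — is below a cap (default k = 25, cap 30).  The k-mers of
every retained read are then added to the counter, so the m-th identical copy
of a read is admitted iff m - 1 < cap: a read duplicated a thousand times
survives with exactly ``max_cov`` copies while unique reads pass untouched.

K-mers are strand-folded (a k-mer and its reverse complement count as one),
because reads come from both strands.  The output is always a subsequence of
the input, and re-running the normalizer on its own output changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_REVCOMP)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class NormalizeConfig:
    """k-mer size, coverage cap, and paired-end behaviour.

    ``pair_aware`` treats stream items as (read1, read2) tuples and admits or
    rejects the pair jointly, so mates are never orphaned.
    """

    k: int = 25
    max_cov: int = 30
    pair_aware: bool = False

    def __post_init__(self) -> None:
        if not 11 <= self.k <= 31:
            raise ValueError("k must be in [11, 31]")
        if self.max_cov < 1:
            raise ValueError("max_cov must be >= 1")


class KmerCounter:
    """Counts of canonical k-mers; k-mers containing N are skipped."""

    def __init__(self, k: int) -> None:
        self.k = k
        self.counts: dict[str, int] = {}

    def add_sequence(self, seq: str) -> None:
        k = self.k
        counts = self.counts
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            ckmer = _canonical(kmer)
            counts[ckmer] = counts.get(ckmer, 0) + 1

    def coverages(self, seq: str) -> list[int]:
        k = self.k
        counts = self.counts
        return [
            counts.get(_canonical(seq[i : i + k]), 0)
            for i in range(len(seq) - k + 1)
            if "N" not in seq[i : i + k]
        ]


def _read_seq(read) -> str:
    # Accept plain strings or Biopython SeqRecords.
    return str(getattr(read, "seq", read)).upper()


def median_coverage(read, counter: KmerCounter, k: int | None = None) -> float:
    """Median count of the read's canonical k-mers (absent k-mers count 0)."""
    seq = _read_seq(read)
    k = counter.k if k is None else k
    if k != counter.k:
        raise ValueError("k does not match the counter's k")
    if len(seq) < k:
        raise ValueError(f"read shorter than k ({len(seq)} < {k})")
    covs = counter.coverages(seq)
    if not covs:  # all windows contained N
        return 0.0
    return float(median(covs))


def normalize_stream(reads: Iterable, config: NormalizeConfig | None = None) -> list:
    """Single-pass streaming normalization; returns the retained subsequence.

    A read (or, pair-aware, a read pair judged by the mean of the two median
    coverages) is retained iff its admission-time median coverage is strictly
    below ``max_cov``; its k-mers are then committed to the counter.
    """
    config = config or NormalizeConfig()
    counter = KmerCounter(config.k)
    retained = []
    for item in reads:
        if config.pair_aware:
            r1, r2 = item
            cov = 0.5 * (
                median_coverage(r1, counter) + median_coverage(r2, counter)
            )
            if cov < config.max_cov:
                retained.append(item)
                counter.add_sequence(_read_seq(r1))
                counter.add_sequence(_read_seq(r2))
        else:
            if median_coverage(item, counter) < config.max_cov:
                retained.append(item)
                counter.add_sequence(_read_seq(item))
    return retained


def normalize_fastq(
    in_path, out_path, config: NormalizeConfig | None = None
) -> tuple[int, int]:
    """File-level wrapper: FASTQ in, retained FASTQ out; returns (n_in, n_out)."""
    from .seq_io import read_fastq, write_fastq

    reads = read_fastq(in_path)
    kept = normalize_stream(reads, config)
    write_fastq(kept, out_path)
    return len(reads), len(kept)
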