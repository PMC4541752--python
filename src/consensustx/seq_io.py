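"""Readers and writers for the plain-text formats used throughout the pipeline.

The formats are deliberately boring: multi-FASTA for contigs and cluster
representatives, CD-HIT-style ``.clstr`` files for cluster composition,
12-column tabular hit files (BLAST ``outfmt 6``), TSV abundance tables and
FASTQ for the optional read-normalization stage.  Everything round-trips
losslessly so that each pipeline stage can be run, inspected and resumed from
disk.

Contig identifiers are made globally unique across assemblies by prefixing
them with a per-assembly source tag separated by ``|`` (``SRR648707|TR19558``
style).  The prefix is how provenance survives pooling; downstream modules
recover the source of any contig by splitting on the first ``|``.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

_VALID_RESIDUES = frozenset("ACGTN")

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bitscore",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class SequenceRecord:
    """A contig or reference sequence.

    ``id`` is unique within one file; after source-tag prefixing it is unique
    across the whole pooled contig set.  Residues are uppercase DNA over
    ``{A, C, G, T, N}``.
    """

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def source_tag(self) -> str:
        """Source-assembly tag encoded in the id (text before the first ``|``)."""
        return self.id.split("|", 1)[0]


@dataclass
class AssemblyCollection:
    """Ordered map from source tag to the contigs of that single assembly."""

    assemblies: dict[str, list[SequenceRecord]] = field(default_factory=dict)

    def add(self, source_tag: str, records: list[SequenceRecord]) -> None:
        if source_tag in self.assemblies:
            raise ValueError(f"duplicate source tag {source_tag!r}")
        seen: set[str] = set()
        for rec in records:
            if rec.id in seen:
                raise ValueError(
                    f"duplicate contig id {rec.id!r} within assembly {source_tag!r}"
                )
            seen.add(rec.id)
        self.assemblies[source_tag] = records

    @property
    def source_tags(self) -> list[str]:
        return list(self.assemblies)

    def n_contigs(self) -> int:
        return sum(len(v) for v in self.assemblies.values())

    def pooled(self) -> list[SequenceRecord]:
        """All contigs with globally unique ``source_tag|id`` identifiers."""
        out: list[SequenceRecord] = []
        for tag, records in self.assemblies.items():
            for rec in records:
                rid = rec.id if rec.id.startswith(tag + "|") else f"{tag}|{rec.id}"
                out.append(SequenceRecord(rid, rec.residues, rec.description))
        ids = [r.id for r in out]
        if len(set(ids)) != len(ids):
            raise ValueError("pooled contig ids collide after source-tag prefixing")
        return out


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, source_tag: str | None = None) -> list[SequenceRecord]:
    """Read a multi-FASTA file, optionally prefixing ids with ``source_tag|``.

    The parser is strict: every record needs a non-empty header and at least
    one residue, and residues must be DNA over ``{A,C,G,T,N}`` (case folded
    to uppercase).  Violations raise :class:`ParseError` naming the line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has no residues")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ParseError(
                f"{path}:{header_line}: record {header!r} contains illegal "
                f"residue(s) {sorted(bad)}"
            )
        name, _, desc = header.partition(" ")
        if source_tag is not None:
            name = f"{source_tag}|{name}"
        records.append(SequenceRecord(name, seq, desc))
        header, chunks = None, []

    with _open_text(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{line_no}: empty FASTA header")
                header_line = line_no
            else:
                if header is None:
                    raise ParseError(
                        f"{path}:{line_no}: sequence data before first header"
                    )
                chunks.append(line.strip())
        _flush(line_no + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CD-HIT style .clstr files
# ---------------------------------------------------------------------------

_CLSTR_HEADER = re.compile(r"^>Cluster\s+(\d+)\s*$")
_CLSTR_MEMBER = re.compile(
    r"^(\d+)\t(\d+)nt, >(.*?)\.\.\. (?:\*|at ([+-])/([0-9.]+)%)\s*$"
)


def write_clstr(cluster_set, path: str | Path) -> None:
    """Write cluster composition in the widely used ``.clstr`` dialect.

    One block per cluster; the representative line ends with ``*`` and member
    lines carry strand and percent identity to the representative, e.g.::

        >Cluster 0
        0\t1200nt, >asm01|G0001.c0... *
        1\t1200nt, >asm02|G0001.c0... at +/99.75%
    """
    with _open_text(path, "wt") as fh:
        for k, cluster in enumerate(cluster_set.clusters):
            fh.write(f">Cluster {k}\n")
            for i, m in enumerate(cluster.members):
                if m.contig_id == cluster.representative_id:
                    fh.write(f"{i}\t{m.length}nt, >{m.contig_id}... *\n")
                else:
                    fh.write(
                        f"{i}\t{m.length}nt, >{m.contig_id}... at "
                        f"{m.strand}/{m.identity * 100:.2f}%\n"
                    )


def read_clstr(path: str | Path, params=None):
    """Parse a ``.clstr`` file back into a ClusterSet (inverse of write_clstr)."""
    from .merge_cluster import Cluster, ClusterMember, ClusterParams, ClusterSet

    clusters: list[Cluster] = []
    members: list[ClusterMember] = []
    rep_id: str | None = None
    cluster_idx: int | None = None

    def _flush(line_no: int) -> None:
        nonlocal members, rep_id
        if cluster_idx is None:
            return
        if rep_id is None:
            raise ParseError(f"{path}:{line_no}: cluster {cluster_idx} has no representative")
        clusters.append(Cluster(cluster_idx, rep_id, members))
        members, rep_id = [], None

    with _open_text(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            m = _CLSTR_HEADER.match(line)
            if m:
                _flush(line_no)
                cluster_idx = int(m.group(1))
                continue
            m = _CLSTR_MEMBER.match(line)
            if not m:
                raise ParseError(f"{path}:{line_no}: unparseable .clstr line: {line!r}")
            _, length, contig_id, strand, pct = m.groups()
            if strand is None:  # representative line
                rep_id = contig_id
                members.append(ClusterMember(contig_id, int(length), 1.0, "+"))
            else:
                members.append(
                    ClusterMember(contig_id, int(length), float(pct) / 100.0, strand)
                )
        _flush(line_no + 1)

    contig_to_cluster = {
        m.contig_id: c.cluster_id for c in clusters for m in c.members
    }
    return ClusterSet(
        clusters=clusters,
        params=params if params is not None else ClusterParams(),
        contig_to_cluster=contig_to_cluster,
    )


# ---------------------------------------------------------------------------
# Tabular hit files (BLAST outfmt 6)
# ---------------------------------------------------------------------------


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular hit file into a DataFrame (columns HIT_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    if df["pct_identity"].lt(0).any() or df["pct_identity"].gt(100).any():
        raise ParseError(f"{path}: percent identity outside [0, 100]")
    if (df["q_start"] > df["q_end"]).any():
        raise ParseError(f"{path}: q_start > q_end")
    if df["bitscore"].lt(0).any():
        raise ParseError(f"{path}: negative bitscore")
    return df


def write_hits(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=HIT_COLUMNS)


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Per-contig, per-sample fragment counts or FPKM.

    ``data`` is a DataFrame indexed by contig id with one column per sample;
    ``mode`` is ``"counts"`` or ``"fpkm"``; ``lengths`` optionally records
    per-contig length in bases (needed to convert counts to FPKM).
    """

    data: pd.DataFrame
    mode: str = "fpkm"
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "fpkm"):
            raise ValueError(f"unknown abundance mode {self.mode!r}")
        if (self.data.values < 0).any():
            raise ValueError("abundance table contains negative cells")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate contig id {dup!r} in abundance table")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def read_abundance(path: str | Path) -> AbundanceTable:
    """Read a TSV abundance table.

    Layout: optional ``# mode=counts|fpkm`` comment line, then a header whose
    first column is ``contig_id``, an optional ``length`` column, and one
    column per sample.  Without the mode line, all-integral values are taken
    as counts, anything else as FPKM.  Missing cells count as zero.
    """
    mode = None
    with _open_text(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"mode\s*=\s*(\w+)", first)
            if m:
                mode = m.group(1)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate contig_id row {dup!r}")
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length").astype(int)
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="raise")
    df = df.fillna(0.0)
    if mode is None:
        vals = df.to_numpy()
        mode = "counts" if (vals == vals.round()).all() else "fpkm"
    return AbundanceTable(data=df.astype(float), mode=mode, lengths=lengths)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"# mode={table.mode}\n")
        df = table.data.copy()
        if table.lengths is not None:
            df.insert(0, "length", table.lengths)
        df.index.name = "contig_id"
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# FASTQ (read-normalization stage)
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> list[BioSeqRecord]:
    with _open_text(path) as fh:
        return list(SeqIO.parse(fh, "fastq"))


def write_fastq(records: Iterable[BioSeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def make_fastq_record(read_id: str, sequence: str, quality: int = 40) -> BioSeqRecord:
    rec = BioSeqRecord(Seq(sequence), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = [quality] * len(sequence)
    return rec
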