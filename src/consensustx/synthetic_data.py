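"""Ground-truth generators for testing the consensus-transcriptome pipeline.

The generator emulates the statistical structure the clustering and filtering
procedure has to cope with when many per-cultivar single assemblies are
pooled:

* **allele groups** — the same gene reconstructed in different assemblies with
  a handful of SNP-level substitutions (pairwise identity >= 99%), which the
  clustering should merge;
* **isoform pairs** — two distinct genes at ~96–97% nucleotide identity (the
  SLS1/SLS2, T16H1/T16H2 situation), which the clustering must keep apart;
* **fragmentation** — partial reconstructions (1–3 fragments of >= 100 nt)
  standing in for incompletely assembled transcripts;
* **uneven expression** — log-normal gene-level FPKM with a constant
  housekeeping reference gene, split over a gene's contigs so that the
  contig-to-cluster aggregation can be checked against gene-level truth.

All generators are deterministic for a fixed seed; a single top-level seed is
fanned out to per-stage child seeds by fixed arithmetic so each stage is
individually reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seq_io import AbundanceTable, AssemblyCollection, SequenceRecord, make_fastq_record

_BASES = np.array(list("ACGT"))


def child_seed(seed: int, tag: str) -> int:
    """Derive a stable per-stage seed from the top-level seed."""
    return (seed * 7919 + zlib.crc32(tag.encode())) % (2**31)


@dataclass
class GeneModel:
    """A ground-truth transcript sequence."""

    gene_id: str
    residues: str
    role: str = "ordinary"  # ordinary | isoform_member | reference_marker
    family_id: str | None = None  # shared by the two members of an isoform pair

    def __post_init__(self) -> None:
        if len(self.residues) < 300:
            raise ValueError("gene models must be at least 300 nt")
        if set(self.residues) - set("ACGT"):
            raise ValueError("gene models are over {A,C,G,T}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TruthSet:
    """Everything the tests need to score the pipeline against the truth."""

    genes: list[GeneModel]
    isoform_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    # (source_tag, gene_id) -> substitution positions applied to that allele
    allele_map: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    # (source_tag, gene_id) -> list of kept (start, end) half-open slices
    fragmentation_plan: dict[tuple[str, str], list[tuple[int, int]]] = field(
        default_factory=dict
    )
    contig_to_gene: dict[str, str] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)
    expression: pd.DataFrame | None = None  # gene x sample true FPKM
    seed: int = 0

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def reference_gene_id(self) -> str | None:
        for g in self.genes:
            if g.role == "reference_marker":
                return g.gene_id
        return None


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_to_identity(residues: str, target_identity: float, seed: int) -> str:
    """Substitute exactly round((1 - target) * L) distinct positions.

    Substitution-only (no indels), so the realized end-gap-free identity to
    the input is exactly the target up to the rounding of the substitution
    count.  ``target_identity = 1.0`` returns the input unchanged.
    """
    if not 0.5 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0.5, 1.0]")
    n_sub = round((1.0 - target_identity) * len(residues))
    if n_sub == 0:
        return residues
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(residues), size=n_sub, replace=False)
    out = list(residues)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def generate_gene_set(
    n_genes: int,
    n_isoform_pairs: int,
    length_range: tuple[int, int] = (900, 1500),
    isoform_identity: float = 0.96,
    seed: int = 0,
) -> list[GeneModel]:
    """Random gene panel with ``n_isoform_pairs`` near-identical pairs.

    Each isoform pair is a base gene plus a partner produced by
    :func:`mutate_to_identity` at ``isoform_identity`` (default 0.96, the
    identity regime of real isoform pairs that clustering must not merge).
    The first non-isoform gene is tagged ``reference_marker`` and plays the
    housekeeping role in expression simulations.  Deterministic per seed.
    """
    if n_genes < 2 * n_isoform_pairs:
        raise ValueError("need n_genes >= 2 * n_isoform_pairs")
    if not 0.90 <= isoform_identity <= 0.99:
        raise ValueError("isoform_identity must be in [0.90, 0.99]")
    rng = np.random.default_rng(child_seed(seed, "gene_set"))
    genes: list[GeneModel] = []
    n_base = n_genes - n_isoform_pairs
    for i in range(n_base):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gid = f"G{i + 1:04d}"
        genes.append(GeneModel(gid, random_sequence(length, rng)))
    for p in range(n_isoform_pairs):
        base = genes[p]
        fam = f"F{p + 1:02d}"
        base.role = "isoform_member"
        base.family_id = fam
        partner_id = f"G{n_base + p + 1:04d}"
        partner_seq = mutate_to_identity(
            base.residues, isoform_identity, child_seed(seed, f"isoform:{partner_id}")
        )
        genes.append(GeneModel(partner_id, partner_seq, "isoform_member", fam))
    for g in genes:
        if g.role == "ordinary":
            g.role = "reference_marker"
            break
    return genes


def _fragment_slices(
    length: int, n_parts: int, rng: np.random.Generator, min_len: int = 100
) -> list[tuple[int, int]]:
    """Split [0, length) into n_parts contiguous slices, each >= min_len."""
    extra = length - n_parts * min_len
    if extra < 0:
        return [(0, length)]
    cuts = np.sort(rng.integers(0, extra + 1, size=n_parts - 1))
    bounds = [0]
    acc = 0
    for i in range(n_parts - 1):
        acc = min_len * (i + 1) + int(cuts[i])
        bounds.append(acc)
    bounds.append(length)
    return [(bounds[i], bounds[i + 1]) for i in range(n_parts)]


def generate_assemblies(
    truth: TruthSet,
    n_assemblies: int = 19,
    fragmentation_prob: float = 0.3,
    dropout_prob: float = 0.1,
    allele_rate: float = 2.0,
    seed: int | None = None,
    keep_fragment_prob: float = 0.8,
) -> AssemblyCollection:
    """Derive per-cultivar single assemblies from the truth gene set.

    Each assembly carries, for every non-dropped gene, either a full-length
    allele or 1–3 fragments of >= 100 nt of that allele.  ``allele_rate`` is
    the per-allele *cap* on cultivar substitutions, in substitutions per kb:
    each allele draws uniformly between 0 and ``floor(rate * L / 1000)``
    substitutions (also capped at 1% of gene length), so two alleles of the
    same gene diverge at most ``2 * rate / 1000`` — pairwise identity is
    guaranteed >= 0.99 whenever the rate is <= 5/kb.  Every emitted contig is
    recorded in ``truth.contig_to_gene`` under its pooled ``tag|id``
    identifier.
    """
    for p, name in ((fragmentation_prob, "fragmentation_prob"), (dropout_prob, "dropout_prob")):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(child_seed(seed, "assemblies"))
    collection = AssemblyCollection()
    for a in range(1, n_assemblies + 1):
        tag = f"asm{a:02d}"
        records: list[SequenceRecord] = []
        for gene in truth.genes:
            if rng.random() < dropout_prob:
                continue
            length = len(gene)
            max_sub = min(int(allele_rate * length / 1000.0), int(0.01 * length))
            n_sub = int(rng.integers(0, max_sub + 1)) if max_sub > 0 else 0
            positions = sorted(
                int(x) for x in rng.choice(length, size=n_sub, replace=False)
            )
            allele = list(gene.residues)
            for pos in positions:
                alternatives = [b for b in "ACGT" if b != allele[pos]]
                allele[pos] = alternatives[rng.integers(0, 3)]
            allele_seq = "".join(allele)
            truth.allele_map[(tag, gene.gene_id)] = positions

            if rng.random() < fragmentation_prob and length >= 200:
                n_parts = int(rng.integers(2, 4))
                slices = _fragment_slices(length, n_parts, rng)
                kept = [s for s in slices if rng.random() < keep_fragment_prob]
                if not kept:
                    kept = [slices[int(rng.integers(0, len(slices)))]]
            else:
                kept = [(0, length)]
            truth.fragmentation_plan[(tag, gene.gene_id)] = kept

            for j, (start, end) in enumerate(kept):
                cid = f"{gene.gene_id}.c{j}"
                records.append(SequenceRecord(cid, allele_seq[start:end]))
                pooled_id = f"{tag}|{cid}"
                truth.contig_to_gene[pooled_id] = gene.gene_id
                truth.contig_lengths[pooled_id] = end - start
        collection.add(tag, records)
    return collection


def generate_expression(
    truth: TruthSet,
    n_samples: int = 42,
    lognormal_mu: float = 3.0,
    lognormal_sigma: float = 1.0,
    reference_gene_id: str | None = None,
    seed: int | None = None,
) -> AbundanceTable:
    """Gene-level log-normal FPKM, split over each gene's contigs.

    The reference (housekeeping) gene is held constant at ``exp(mu)`` across
    samples; every other gene draws an independent log-normal value per
    sample.  A gene's per-sample FPKM is apportioned to its contigs
    proportionally to contig length, so contig values sum exactly back to the
    gene value.  Requires :func:`generate_assemblies` to have been run so the
    contig inventory exists.
    """
    if not truth.contig_to_gene:
        raise ValueError("generate_assemblies must be run before generate_expression")
    reference_gene_id = reference_gene_id or truth.reference_gene_id
    gene_ids = [g.gene_id for g in truth.genes]
    if reference_gene_id is not None and reference_gene_id not in gene_ids:
        raise ValueError(f"reference gene {reference_gene_id!r} not in truth")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(child_seed(seed, "expression"))
    samples = [f"sample{i + 1:02d}" for i in range(n_samples)]
    values = rng.lognormal(lognormal_mu, lognormal_sigma, size=(len(gene_ids), n_samples))
    expr = pd.DataFrame(values, index=gene_ids, columns=samples)
    if reference_gene_id is not None:
        expr.loc[reference_gene_id] = float(np.exp(lognormal_mu))
    truth.expression = expr

    by_gene: dict[str, list[str]] = {}
    for contig_id, gene_id in truth.contig_to_gene.items():
        by_gene.setdefault(gene_id, []).append(contig_id)

    rows: dict[str, np.ndarray] = {}
    for gene_id, contig_ids in by_gene.items():
        lengths = np.array([truth.contig_lengths[c] for c in contig_ids], dtype=float)
        weights = lengths / lengths.sum()
        gene_vals = expr.loc[gene_id].to_numpy()
        for contig_id, w in zip(contig_ids, weights):
            rows[contig_id] = gene_vals * w
    data = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    lengths = pd.Series(
        {c: truth.contig_lengths[c] for c in data.index}, name="length"
    ).astype(int)
    return AbundanceTable(data=data, mode="fpkm", lengths=lengths)


def generate_reads(
    truth: TruthSet,
    coverage_profile: dict[str, int] | int = 2,
    duplication_factor: dict[str, int] | int = 1,
    read_length: int = 100,
    seed: int | None = None,
):
    """Uniform tiling reads per gene, with per-gene duplication.

    ``coverage_profile`` sets the approximate fold coverage of the tiling
    (tile step = read_length // coverage); ``duplication_factor`` repeats
    every read of a gene verbatim, emulating the over-represented reads that
    digital normalization is meant to cap.  Read order is deterministic:
    genes in panel order, positions left to right, duplicates consecutive.
    """
    min_len = min(len(g) for g in truth.genes)
    if read_length > min_len:
        raise ValueError("read_length exceeds the shortest gene")
    reads = []
    for gene in truth.genes:
        cov = coverage_profile if isinstance(coverage_profile, int) else coverage_profile.get(
            gene.gene_id, 2
        )
        dup = duplication_factor if isinstance(duplication_factor, int) else duplication_factor.get(
            gene.gene_id, 1
        )
        step = max(1, read_length // max(1, cov))
        for start in range(0, len(gene) - read_length + 1, step):
            seq = gene.residues[start : start + read_length]
            for d in range(dup):
                reads.append(
                    make_fastq_record(f"{gene.gene_id}_p{start}_d{d}", seq)
                )
    return reads


def make_truth(
    n_genes: int = 12,
    n_isoform_pairs: int = 2,
    length_range: tuple[int, int] = (900, 1500),
    isoform_identity: float = 0.96,
    seed: int = 0,
) -> TruthSet:
    """Convenience constructor: gene set wrapped in a TruthSet."""
    genes = generate_gene_set(n_genes, n_isoform_pairs, length_range, isoform_identity, seed)
    pairs = []
    by_family: dict[str, list[str]] = {}
    for g in genes:
        if g.family_id:
            by_family.setdefault(g.family_id, []).append(g.gene_id)
    for fam, ids in sorted(by_family.items()):
        pairs.append((ids[0], ids[1], isoform_identity))
    return TruthSet(genes=genes, isoform_pairs=pairs, seed=seed)
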