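"""End-to-end orchestration: simulate -> [normalize] -> cluster -> filter ->
quality -> quantify -> report.

Each stage reads and writes plain files (FASTA / TSV / ``.clstr`` / FASTQ) in
the run directory, so any stage can be re-run or inspected in isolation, and
a machine-readable ``summary.json`` accumulates the headline numbers (cluster
counts, filter accounting, quality summary, concordance).  A single top-level
seed is fanned out to the stages; re-running with the same config and seed
reproduces the outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cluster_filter, expression_quant, merge_cluster, recon_quality, seq_io
from . import read_normalize, synthetic_data
from .cluster_filter import FilterConfig
from .merge_cluster import ClusterParams
from .read_normalize import NormalizeConfig
from .recon_quality import ReferenceGene, ScoringScheme

logger = logging.getLogger(__name__)

CANONICAL_STAGES = [
    "simulate",
    "normalize",
    "merge-cluster",
    "filter",
    "quality",
    "quantify",
    "report",
]

DEFAULT_STAGES = [
    "simulate",
    "merge-cluster",
    "filter",
    "quality",
    "quantify",
    "report",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names it.  Partial outputs are preserved."""


@dataclass
class SyntheticConfig:
    """Shape of the simulated study: a multi-cultivar, multi-sample corpus.

    Defaults mirror the real study design the pipeline targets: 19 per-sample
    assemblies pooled, 42 expression samples, a small panel of kb-scale genes
    including two ~96%-identity isoform pairs, SNP-level cultivar alleles and
    a third of genes fragmented per assembly.
    """

    n_genes: int = 12
    n_isoform_pairs: int = 2
    length_range: tuple[int, int] = (900, 1500)
    isoform_identity: float = 0.96
    n_assemblies: int = 19
    fragmentation_prob: float = 0.3
    dropout_prob: float = 0.1
    allele_rate: float = 2.0
    n_samples: int = 42
    lognormal_mu: float = 3.0
    lognormal_sigma: float = 1.0
    read_length: int = 100


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    normalize: NormalizeConfig = field(default_factory=NormalizeConfig)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    hit_threshold: float = 0.8
    breadth_cutoff: int = 10
    scan_thresholds: list[float] | None = None

    def __post_init__(self) -> None:
        order = [CANONICAL_STAGES.index(s) for s in self.stages]
        if sorted(order) != order or len(set(order)) != len(order):
            raise ValueError(
                f"stages must be a subset of {CANONICAL_STAGES} in canonical order"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("synthetic", SyntheticConfig),
            ("cluster", ClusterParams),
            ("filter", FilterConfig),
            ("normalize", NormalizeConfig),
            ("scheme", ScoringScheme),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "synthetic" in kwargs and isinstance(kwargs["synthetic"].length_range, list):
            kwargs["synthetic"].length_range = tuple(kwargs["synthetic"].length_range)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages in order; returns the summary dict.

    Every stage's outputs are written before the next stage starts; a stage
    failure raises :class:`PipelineError` naming the stage, leaving earlier
    outputs on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}

    stage_fns = {
        "simulate": _stage_simulate,
        "normalize": _stage_normalize,
        "merge-cluster": _stage_merge_cluster,
        "filter": _stage_filter,
        "quality": _stage_quality,
        "quantify": _stage_quantify,
        "report": _stage_report,
    }
    for stage in config.stages:
        logger.info("stage %s starting", stage)
        try:
            stage_fns[stage](config, outdir, state, summary)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done", stage)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _stage_simulate(config: PipelineConfig, outdir: Path, state: dict, summary: dict) -> None:
    sc = config.synthetic
    truth = synthetic_data.make_truth(
        n_genes=sc.n_genes,
        n_isoform_pairs=sc.n_isoform_pairs,
        length_range=sc.length_range,
        isoform_identity=sc.isoform_identity,
        seed=config.seed,
    )
    assemblies = synthetic_data.generate_assemblies(
        truth,
        n_assemblies=sc.n_assemblies,
        fragmentation_prob=sc.fragmentation_prob,
        dropout_prob=sc.dropout_prob,
        allele_rate=sc.allele_rate,
    )
    abundance = None
    if sc.n_samples > 0:
        abundance = synthetic_data.generate_expression(
            truth,
            n_samples=sc.n_samples,
            lognormal_mu=sc.lognormal_mu,
            lognormal_sigma=sc.lognormal_sigma,
        )
    asm_dir = outdir / "assemblies"
    asm_dir.mkdir(exist_ok=True)
    for tag, records in assemblies.assemblies.items():
        seq_io.write_fasta(records, asm_dir / f"{tag}.fasta")
    seq_io.write_fasta(
        [seq_io.SequenceRecord(g.gene_id, g.residues) for g in truth.genes],
        outdir / "reference_genes.fasta",
    )
    manifest = pd.DataFrame(
        sorted(truth.contig_to_gene.items()), columns=["contig_id", "gene_id"]
    ).set_index("contig_id")
    _write_tsv(manifest, outdir / "truth_contig_to_gene.tsv")
    if abundance is not None:
        seq_io.write_abundance(abundance, outdir / "abundance.tsv")
    if "normalize" in config.stages:
        reads = synthetic_data.generate_reads(
            truth, read_length=sc.read_length, seed=config.seed
        )
        seq_io.write_fastq(reads, outdir / "reads.fastq")
        state["reads_path"] = outdir / "reads.fastq"
    state.update(truth=truth, assemblies=assemblies)
    if abundance is not None:
        state["abundance"] = abundance
    summary["simulate"] = {
        "n_genes": len(truth.genes),
        "n_assemblies": len(assemblies.assemblies),
        "n_contigs": assemblies.n_contigs(),
        "n_samples": 0 if abundance is None else len(abundance.samples),
    }


def _stage_normalize(config: PipelineConfig, outdir: Path, state: dict, summary: dict) -> None:
    reads_path = state.get("reads_path", outdir / "reads.fastq")
    n_in, n_out = read_normalize.normalize_fastq(
        reads_path, outdir / "reads.normalized.fastq", config.normalize
    )
    summary["normalize"] = {"reads_in": n_in, "reads_retained": n_out}


def _require(state: dict, key: str, needed_by: str):
    if key not in state:
        raise PipelineError(f"stage {needed_by!r} needs {key!r} from an earlier stage")
    return state[key]


def _stage_merge_cluster(config: PipelineConfig, outdir: Path, state: dict, summary: dict) -> None:
    assemblies: seq_io.AssemblyCollection = _require(state, "assemblies", "merge-cluster")
    pooled = assemblies.pooled()
    cs = merge_cluster.greedy_cluster(pooled, config.cluster)
    state["pooled"] = pooled
    state["cluster_set"] = cs
    seq_io.write_fasta(
        merge_cluster.representatives(cs, pooled), outdir / "representatives.fasta"
    )
    seq_io.write_clstr(cs, outdir / "clusters.clstr")
    merge_cluster.contig_to_cluster_frame(cs).to_csv(
        outdir / "contig_to_cluster.tsv", sep="\t", index=False
    )
    if config.scan_thresholds:
        scan = merge_cluster.cluster_threshold_scan(
            pooled, config.scan_thresholds, config.cluster
        )
        _write_tsv(scan, outdir / "threshold_scan.tsv")
    summary["merge_cluster"] = {
        "n_pooled_contigs": len(pooled),
        "n_clusters": cs.n_clusters,
        "n_singletons": cs.n_singletons,
        "n_true_clusters": cs.n_true_clusters,
        "identity_threshold": config.cluster.identity_threshold,
    }


def _stage_filter(config: PipelineConfig, outdir: Path, state: dict, summary: dict) -> None:
    cs = _require(state, "cluster_set", "filter")
    abundance = state.get("abundance")
    if abundance is None:
        logger.warning("no abundance table available; filter runs in 2-criteria mode")
    metrics = cluster_filter.compute_metrics(cs, abundance)
    report = cluster_filter.apply_filter(metrics, config.filter)
    _write_tsv(metrics, outdir / "cluster_metrics.tsv")
    _write_tsv(report, outdir / "filter_report.tsv")
    pooled = state.get("pooled", [])
    retained_ids = set(report.index[report["retained"]])
    reps = [
        r
        for c, r in zip(cs.clusters, merge_cluster.representatives(cs, pooled))
        if c.cluster_id in retained_ids
    ]
    seq_io.write_fasta(reps, outdir / "retained_representatives.fasta")

    part = cluster_filter.participation_matrix(cs)
    _write_tsv(part, outdir / "participation.tsv")
    hist, core = cluster_filter.breadth_histogram(cs, config.breadth_cutoff)
    _write_tsv(hist.to_frame("n_clusters"), outdir / "breadth_histogram.tsv")
    if cs.n_true_clusters >= 2:
        corr = cluster_filter.assembly_correlation(part, cs, true_clusters_only=True)
        _write_tsv(corr, outdir / "assembly_correlation.tsv")
    scan = cluster_filter.filter_threshold_scan(
        metrics,
        contig_thresholds=[2, 3, 5, 10, 20],
        fpkm_thresholds=[5, 10, 50, 100],
        length_thresholds=[200, 500, 1000],
    )
    scan.to_csv(outdir / "filter_threshold_scan.tsv", sep="\t", index=False)
    state["filter_report"] = report
    n_ret = int(report["retained"].sum())
    summary["filter"] = {
        "n_clusters": len(report),
        "n_retained": n_ret,
        "n_discarded": len(report) - n_ret,
        "core_clusters": len(core),
    }


def _stage_quality(config: PipelineConfig, outdir: Path, state: dict, summary: dict) -> None:
    truth = _require(state, "truth", "quality")
    assemblies = _require(state, "assemblies", "quality")
    panel = [
        ReferenceGene.from_sequence(
            seq_io.SequenceRecord(g.gene_id, g.residues), config.scheme
        )
        for g in truth.genes
    ]
    qm = recon_quality.quality_matrix(
        panel, assemblies, config.scheme, config.hit_threshold
    )
    _write_tsv(qm.ratio, outdir / "quality_ratio.tsv")
    _write_tsv(qm.n_hits, outdir / "quality_hits.tsv")
    _write_tsv(qm.best_contig, outdir / "quality_best_contig.tsv")
    state["quality"] = qm
    summary["quality"] = {
        "n_genes": len(panel),
        "n_assemblies": len(assemblies.assemblies),
        "min_ratio": float(qm.ratio.values.min()),
        "mean_ratio": float(qm.ratio.values.mean()),
    }


def _stage_quantify(config: PipelineConfig, outdir: Path, state: dict, summary: dict) -> None:
    truth = _require(state, "truth", "quantify")
    abundance = _require(state, "abundance", "quantify")
    cs = _require(state, "cluster_set", "quantify")
    expr = expression_quant.aggregate_to_clusters(abundance, cs.contig_to_cluster)
    _write_tsv(expr.values, outdir / "cluster_expression.tsv")

    ref_gene = truth.reference_gene_id
    concord = None
    if ref_gene is not None and truth.expression is not None:
        # Majority cluster of each gene's contigs stands for that gene.
        gene_cluster: dict[str, int] = {}
        for g in truth.genes:
            counts: dict[int, int] = {}
            for contig_id, gid in truth.contig_to_gene.items():
                if gid == g.gene_id and contig_id in cs.contig_to_cluster:
                    cid = cs.contig_to_cluster[contig_id]
                    counts[cid] = counts.get(cid, 0) + 1
            if counts:
                gene_cluster[g.gene_id] = max(counts, key=lambda c: (counts[c], -c))
        if ref_gene in gene_cluster:
            ref_cluster = gene_cluster[ref_gene]
            norm = expression_quant.normalize_to_reference(expr.values, ref_cluster)
            _write_tsv(norm, outdir / "cluster_expression_normalized.tsv")
            rnaseq = pd.DataFrame(
                {g: norm.loc[c] for g, c in gene_cluster.items()}
            ).T
            qpcr = expression_quant.normalize_to_reference(truth.expression, ref_gene)
            result = expression_quant.concordance(qpcr, rnaseq)
            concord = dataclasses.asdict(result)
    summary["quantify"] = {
        "n_clusters_expressed": int(len(expr.values)),
        "n_unmapped_contigs": expr.n_unmapped_contigs,
        "concordance": concord,
    }


def _stage_report(config: PipelineConfig, outdir: Path, state: dict, summary: dict) -> None:
    """Human-readable recap of the tables the run produced."""
    lines = ["consensustx run report", "=" * 22, ""]
    tables = [
        ("threshold scan", "threshold_scan.tsv"),
        ("filter threshold scan", "filter_threshold_scan.tsv"),
        ("quality matrix (ratios)", "quality_ratio.tsv"),
        ("quality matrix (hits > threshold)", "quality_hits.tsv"),
        ("source-breadth histogram", "breadth_histogram.tsv"),
        ("filter report", "filter_report.tsv"),
    ]
    for title, name in tables:
        path = outdir / name
        if path.exists():
            lines.append(f"## {title} ({name})")
            lines.append(path.read_text().rstrip())
        else:
            lines.append(f"## {title}: absent")
        lines.append("")
    if "filter" in summary:
        f = summary["filter"]
        assert f["n_retained"] + f["n_discarded"] == f["n_clusters"]
        lines.append(
            f"filter accounting: {f['n_retained']} retained + "
            f"{f['n_discarded']} discarded = {f['n_clusters']} clusters"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    summary["report"] = {"path": "report.txt"}
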