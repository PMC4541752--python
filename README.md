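# consensustx

Tools for building and quality-controlling a **consensus de novo
transcriptome** from many per-sample assemblies.

When a non-model organism is studied through multiple independent RNA-seq
experiments — different tissues, treatments and cultivars — each sample can
be assembled on its own, and the union of those single assemblies usually
reconstructs more genes, and reconstructs them better, than any one assembly.
The price is massive redundancy: the same transcript appears once per sample,
with SNP-level cultivar differences, and often in fragments.  The scientific
difficulty is that redundancy removal must merge **alleles** of one gene
(~99%+ identity) without collapsing **isoform pairs** — distinct genes at
~96–97% nucleotide identity, such as the two secologanin synthase (SLS1/SLS2)
or tabersonine 16-hydroxylase (T16H1/T16H2) genes of *Catharanthus roseus* —
into a single sequence.

`consensustx` implements the whole desk-side workflow:

1. **Pooling & greedy clustering** (`merge_cluster`) — contigs from all
   assemblies, scanned longest-first, join the first representative they
   match at identity ≥ *c* (default 0.97).  Identity is *identical bases /
   length of the shorter sequence* under an end-gap-free alignment, so
   fragments collapse into full-length contigs.  A conservative shared-word
   prescreen (word length 9) prunes hopeless comparisons without ever
   changing the result.
2. **Cluster filtering** (`cluster_filter`) — each cluster is scored on
   representative length (≥ 500 nt), member count (> 10) and summed FPKM over
   all samples (> 50), and discarded only when **at least two of the three**
   criteria fail, protecting short or weakly expressed genes.
3. **Reconstruction quality** (`recon_quality`) — a reference gene's best
   local-alignment bitscore against an assembly, divided by the gene's
   self-alignment bitscore (`bits = (λ·S − ln K)/ln 2`), gives a
   scale-free **bitscore ratio** in [0, 1]; counting contigs with ratio > 0.8
   flags candidate isoforms.
4. **Cluster-level expression** (`expression_quant`) — contig abundance is
   attributed to clusters through the contig-to-cluster map (the
   transcript-to-gene idea), normalized to a housekeeping cluster, and
   checked against qPCR as the adjusted r² of a log2–log2 linear model.
5. **Digital normalization** (`read_normalize`, optional) — a single pass
   over the read stream retains a read only while its median canonical
   k-mer coverage (k = 25) is below a cap (default 30).
6. **Synthetic truth** (`synthetic_data`) — generators for gene panels with
   isoform pairs, cultivar alleles, fragmentation and log-normal expression,
   so every claim above is testable without any sequencing download.

## Worked example

```python
from consensustx import *
from consensustx import synthetic_data as sd

truth = sd.make_truth(n_genes=8, n_isoform_pairs=2, isoform_identity=0.96, seed=42)
assemblies = sd.generate_assemblies(truth, n_assemblies=6, fragmentation_prob=0.3,
                                    dropout_prob=0.1, allele_rate=2.0)
abundance = sd.generate_expression(truth, n_samples=10)

pooled = assemblies.pooled()
clusters = greedy_cluster(pooled, ClusterParams(identity_threshold=0.97))
print(f"{len(pooled)} contigs -> {clusters.n_clusters} clusters "
      f"({clusters.n_singletons} singletons)")

report = apply_filter(compute_metrics(clusters, abundance), FilterConfig())
print(f"retained {int(report['retained'].sum())}/{len(report)} clusters")

scheme = ScoringScheme()
gene = ReferenceGene.from_sequence(
    SequenceRecord(truth.genes[0].gene_id, truth.genes[0].residues), scheme)
cell = reconstruction_ratio(gene, assemblies.assemblies["asm01"], scheme)
print(f"{gene.gene_id} in asm01: ratio {cell.ratio:.3f}, "
      f"hits > 0.8: {cell.n_hits_above}")
```

prints

```
61 contigs -> 8 clusters (0 singletons)
retained 8/8 clusters
G0001 in asm01: ratio 0.876, hits > 0.8: 1
```

Sixty-one pooled contigs (alleles and fragments of 8 genes from 6 simulated
cultivar assemblies) collapse to exactly one cluster per gene: alleles merged,
both 96%-identity isoform pairs kept apart.  All 8 clusters pass the 2-of-3
filter.  Gene `G0001` happens to be fragmented in assembly `asm01`, so its
best contig reaches only 87.6% of the self-alignment bitscore.

The same workflow is available from the shell:

```bash
consensustx simulate --n-genes 8 --n-assemblies 6 --seed 42 --outdir run/
consensustx merge-cluster run/assemblies/*.fasta --identity 0.97 --outdir run/
consensustx filter run/clusters.clstr --abundance run/abundance.tsv --outdir run/
consensustx run-all --seed 42 --outdir run_all/   # everything, one command
```

## Layout

```
src/consensustx/
  seq_io.py           FASTA / .clstr / hit-table / abundance / FASTQ I/O
  synthetic_data.py   ground-truth generators (genes, assemblies, expression, reads)
  read_normalize.py   streaming median-k-mer-coverage normalization
  merge_cluster.py    pooling, pair identity, word prescreen, greedy clustering
  cluster_filter.py   metrics, 2-of-3 filter, composition & correlation analysis
  recon_quality.py    bitscore ratios, isoform prediction, hit-coverage tables
  expression_quant.py FPKM, cluster aggregation, reference normalization, concordance
  pipeline.py / cli.py  orchestration and the `consensustx` command
```

See `docs/methods.md` for the model, parameter choices and limitations.
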