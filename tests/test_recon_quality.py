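"""Bitscore transform, reconstruction ratios, isoform counting, hit coverage."""

import math

import numpy as np
import pandas as pd
import pytest

from consensustx import synthetic_data as sd
from consensustx.merge_cluster import revcomp
from consensustx.recon_quality import (
    ReferenceGene,
    ScoringScheme,
    best_local_hits,
    bitscore,
    hit_coverage_table,
    isoform_hit_count,
    local_score,
    quality_matrix,
    reconstruction_ratio,
    ungapped_lambda,
)
from consensustx.seq_io import HIT_COLUMNS, AssemblyCollection, SequenceRecord

from _oracles import smith_waterman_score

SCHEME = ScoringScheme()


class TestBitscore:
    def test_zero_raw_score(self):
        assert bitscore(0.0, SCHEME) == pytest.approx(-math.log(SCHEME.K) / math.log(2))

    def test_strictly_increasing(self):
        scores = [bitscore(s, SCHEME) for s in (0, 1, 10, 100)]
        assert scores == sorted(scores) and len(set(scores)) == 4

    def test_exact_value_for_100nt_self_match(self):
        # raw = 1 * 100; bits = (1.28*100 - ln 0.46)/ln 2, computed by hand
        expected = (1.28 * 100 - math.log(0.46)) / math.log(2)
        assert bitscore(100.0, SCHEME) == pytest.approx(expected)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", "A" * 100), SCHEME)
        assert gene.self_bits == pytest.approx(expected)

    def test_unknown_scheme_requires_explicit_constants(self):
        with pytest.raises(ValueError, match="Karlin"):
            ScoringScheme(match=2.0, mismatch=-3.0)
        s = ScoringScheme(match=2.0, mismatch=-3.0, lam=0.6, K=0.1)
        assert s.lam == 0.6

    def test_ungapped_lambda_solves_the_score_equation(self):
        lam = ungapped_lambda(1.0, -1.0)
        # for +1/-1 over a uniform alphabet the solution is exp(lambda) = 3
        assert lam == pytest.approx(math.log(3.0))


class TestLocalScore:
    def test_matches_smith_waterman_oracle(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = sd.random_sequence(int(r.integers(50, 150)), r)
            b = sd.random_sequence(int(r.integers(50, 150)), r)
            assert local_score(a, b, SCHEME) == pytest.approx(
                smith_waterman_score(a, b, SCHEME.match, SCHEME.mismatch,
                                     SCHEME.gap_open, SCHEME.gap_extend)
            )

    def test_oracle_agreement_on_structured_pairs(self, rng):
        gene = sd.random_sequence(300, rng)
        for variant in (gene, gene[:150], sd.mutate_to_identity(gene, 0.95, 3)):
            assert local_score(gene, variant, SCHEME) == pytest.approx(
                smith_waterman_score(gene, variant)
            )


class TestBestLocalHits:
    def test_exact_copy_scores_match_times_length(self, rng):
        seq = sd.random_sequence(800, rng)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", seq), SCHEME)
        contigs = [SequenceRecord("c1", seq), SequenceRecord("c2", sd.random_sequence(400, rng))]
        hits = best_local_hits(gene, contigs, SCHEME)
        assert hits[0][0] == "c1"
        assert hits[0][1] == pytest.approx(SCHEME.match * 800)

    def test_empty_assembly(self, rng):
        gene = ReferenceGene.from_sequence(
            SequenceRecord("g", sd.random_sequence(300, rng)), SCHEME
        )
        assert best_local_hits(gene, [], SCHEME) == []

    def test_half_gene_scores_half(self, rng):
        seq = sd.random_sequence(1000, rng)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", seq), SCHEME)
        hits = best_local_hits(gene, [SequenceRecord("half", seq[:500])], SCHEME)
        assert hits[0][1] == pytest.approx(SCHEME.match * 500)
        assert hits[0][1] == pytest.approx(smith_waterman_score(seq, seq[:500]))

    def test_reverse_strand_found(self, rng):
        seq = sd.random_sequence(600, rng)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", seq), SCHEME)
        hits = best_local_hits(gene, [SequenceRecord("rc", revcomp(seq))], SCHEME)
        assert hits[0][1] == pytest.approx(SCHEME.match * 600)

    def test_prescreen_equivalent_to_exhaustive(self, rng):
        gene_seq = sd.random_sequence(400, rng)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", gene_seq), SCHEME)
        contigs = [
            SequenceRecord("full", gene_seq),
            SequenceRecord("mut", sd.mutate_to_identity(gene_seq, 0.9, 1)),
            SequenceRecord("frag", gene_seq[100:300]),
            SequenceRecord("junk1", sd.random_sequence(300, rng)),
            SequenceRecord("junk2", sd.random_sequence(300, rng)),
        ]
        fast = best_local_hits(gene, contigs, SCHEME, prescreen=True)
        slow = best_local_hits(gene, contigs, SCHEME, prescreen=False)
        fast_scores = dict((h[0], h[1]) for h in fast)
        slow_scores = dict((h[0], h[1]) for h in slow)
        for cid in ("full", "mut", "frag"):  # anything a prescreen may drop is noise
            assert fast_scores[cid] == slow_scores[cid]


class TestReconstructionRatio:
    def test_verbatim_copy_gives_ratio_one(self, rng):
        seq = sd.random_sequence(1000, rng)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", seq), SCHEME)
        cell = reconstruction_ratio(gene, [SequenceRecord("c", seq)], SCHEME)
        assert cell.ratio == pytest.approx(1.0, abs=1e-9)
        assert cell.best_contig_id == "c"
        assert cell.n_hits_above == 1

    def test_no_hits_gives_zero(self, rng):
        gene = ReferenceGene.from_sequence(
            SequenceRecord("g", sd.random_sequence(500, rng)), SCHEME
        )
        cell = reconstruction_ratio(gene, [], SCHEME)
        assert cell.ratio == 0.0 and cell.best_contig_id is None

    def test_half_fragment_ratio_matches_formula(self, rng):
        seq = sd.random_sequence(2000, rng)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", seq), SCHEME)
        cell = reconstruction_ratio(gene, [SequenceRecord("h", seq[:1000])], SCHEME)
        lam, k = SCHEME.lam, SCHEME.K
        expected = (lam * 1000 - math.log(k)) / (lam * 2000 - math.log(k))
        assert cell.ratio == pytest.approx(expected)
        assert cell.ratio == pytest.approx(0.5, abs=0.01)  # ~0.5 for kb-scale genes

    def test_ratio_bounded_by_one(self, rng):
        # nothing can out-score the self alignment under positive-match scoring
        seq = sd.random_sequence(400, rng)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", seq), SCHEME)
        contigs = [SequenceRecord(f"c{i}", seq * 2) for i in range(3)]
        for c in contigs:
            cell = reconstruction_ratio(gene, [c], SCHEME)
            assert 0.0 <= cell.ratio <= 1.0
            assert cell.ratio == pytest.approx(1.0, abs=1e-9)


class TestIsoformHitCount:
    def test_gene_plus_isoform_counts_two(self, rng):
        seq = sd.random_sequence(1200, rng)
        iso = sd.mutate_to_identity(seq, 0.97, 9)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", seq), SCHEME)
        contigs = [SequenceRecord("a", seq), SequenceRecord("b", iso),
                   SequenceRecord("noise", sd.random_sequence(500, rng))]
        assert isoform_hit_count(gene, contigs, SCHEME) == 2

    def test_single_copy_counts_one(self, rng):
        seq = sd.random_sequence(900, rng)
        gene = ReferenceGene.from_sequence(SequenceRecord("g", seq), SCHEME)
        assert isoform_hit_count(gene, [SequenceRecord("a", seq)], SCHEME) == 1

    def test_empty_assembly_counts_zero(self, rng):
        gene = ReferenceGene.from_sequence(
            SequenceRecord("g", sd.random_sequence(900, rng)), SCHEME
        )
        assert isoform_hit_count(gene, [], SCHEME) == 0


class TestQualityMatrix:
    def test_verbatim_assemblies_all_ones(self, rng):
        genes_seq = [sd.random_sequence(600, rng) for _ in range(3)]
        panel = [
            ReferenceGene.from_sequence(SequenceRecord(f"g{i}", s), SCHEME)
            for i, s in enumerate(genes_seq)
        ]
        col = AssemblyCollection()
        for tag in ("A", "B"):
            col.add(tag, [SequenceRecord(f"c{i}", s) for i, s in enumerate(genes_seq)])
        qm = quality_matrix(panel, col, SCHEME)
        assert qm.ratio.shape == (3, 2)
        assert np.allclose(qm.ratio.values, 1.0, atol=1e-9)

    def test_dropped_gene_cell_near_zero(self, rng):
        genes_seq = [sd.random_sequence(600, rng) for _ in range(2)]
        panel = [
            ReferenceGene.from_sequence(SequenceRecord(f"g{i}", s), SCHEME)
            for i, s in enumerate(genes_seq)
        ]
        col = AssemblyCollection()
        col.add("A", [SequenceRecord("c0", genes_seq[0])])  # gene 1 dropped
        qm = quality_matrix(panel, col, SCHEME)
        assert qm.ratio.loc["g0", "A"] == pytest.approx(1.0, abs=1e-9)
        assert qm.ratio.loc["g1", "A"] < 0.1

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            quality_matrix([], AssemblyCollection(), SCHEME)

    def test_summary_shape(self, rng):
        seq = sd.random_sequence(500, rng)
        panel = [ReferenceGene.from_sequence(SequenceRecord("g", seq), SCHEME)]
        col = AssemblyCollection()
        col.add("A", [SequenceRecord("c", seq)])
        s = quality_matrix(panel, col, SCHEME).summary()
        assert list(s.columns) == ["min_ratio", "mean_ratio"]


def _hits(rows):
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


class TestHitCoverageTable:
    def test_ninety_percent_hit(self):
        hits = _hits([["q1", "t1", 99.0, 90, 1, 0, 1, 90, 1, 90, 1e-30, 150.0]])
        table = hit_coverage_table(hits, {"t1": 100})
        assert table[100] == 0 and table[90] == 1 and table[10] == 1

    def test_no_hits_all_zero(self):
        table = hit_coverage_table(_hits([]), {"t1": 100})
        assert (table == 0).all()

    def test_three_targets_enumeration(self):
        hits = _hits(
            [
                ["q1", "t1", 99.0, 100, 0, 0, 1, 100, 1, 100, 1e-40, 180.0],
                ["q2", "t2", 95.0, 55, 2, 0, 1, 55, 10, 64, 1e-25, 90.0],
                ["q3", "t3", 92.0, 20, 1, 0, 1, 20, 41, 60, 1e-22, 40.0],
            ]
        )
        table = hit_coverage_table(hits, {"t1": 100, "t2": 100, "t3": 100})
        assert table[100] == 1 and table[50] == 2 and table[10] == 3

    def test_evalue_filter_and_best_hit_per_target(self):
        hits = _hits(
            [
                ["q1", "t1", 99.0, 100, 0, 0, 1, 100, 1, 100, 1e-5, 180.0],  # filtered
                ["q2", "t1", 95.0, 40, 2, 0, 1, 40, 1, 40, 1e-30, 70.0],
            ]
        )
        table = hit_coverage_table(hits, {"t1": 100})
        assert table[100] == 0 and table[40] == 1

    def test_counts_non_decreasing_as_threshold_drops(self, rng):
        r = np.random.default_rng(3)
        rows = []
        for i in range(30):
            s_start = int(r.integers(1, 50))
            s_end = s_start + int(r.integers(10, 200))
            rows.append([f"q{i}", f"t{i % 7}", 95.0, s_end - s_start + 1, 0, 0,
                         1, 10, s_start, s_end, 1e-30, 50.0])
        table = hit_coverage_table(_hits(rows), {f"t{j}": 250 for j in range(7)})
        # counts grow (weakly) as the coverage threshold drops
        assert (table.sort_index(ascending=False).diff().dropna() >= 0).all()

    def test_unknown_target_rejected(self):
        hits = _hits([["q1", "tX", 99.0, 10, 0, 0, 1, 10, 1, 10, 1e-30, 20.0]])
        with pytest.raises(KeyError):
            hit_coverage_table(hits, {"t1": 100})
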