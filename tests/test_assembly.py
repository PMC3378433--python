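"""Greedy assembly: overlap thresholds, consensus fidelity, read
conservation, input-order invariance, and unigene-set comparison."""

import numpy as np
import pytest

from est454 import assembly, synthetic
from est454.assembly import (AssemblyParams, assemble_greedy, assembly_summary,
                             compare_unigene_sets, membership_table,
                             unigene_sequences)
from est454.synthetic import SyntheticConfig
from est454.types import Read, revcomp

from conftest import random_seq


class TestPairwiseOverlaps:
    def test_exact_30nt_overlap_merges(self, rng):
        ov = random_seq(rng, 30)
        a = random_seq(rng, 70) + ov
        b = ov + random_seq(rng, 70)
        res = assemble_greedy([Read("a", a, "L"), Read("b", b, "L")])
        assert len(res.contigs) == 1 and len(res.singletons) == 0
        assert len(res.contigs[0].consensus) == 170
        assert res.contigs[0].n_reads == 2

    def test_29nt_overlap_stays_singletons(self, rng):
        ov = random_seq(rng, 29)
        a = random_seq(rng, 71) + ov
        b = ov + random_seq(rng, 71)
        res = assemble_greedy([Read("a", a, "L"), Read("b", b, "L")])
        assert len(res.contigs) == 0 and len(res.singletons) == 2

    def test_reverse_complement_overlap_merges(self, rng):
        ov = random_seq(rng, 40)
        a = random_seq(rng, 60) + ov
        b = revcomp(ov + random_seq(rng, 60))
        res = assemble_greedy([Read("a", a, "L"), Read("b", b, "L")])
        assert len(res.contigs) == 1
        assert len(res.contigs[0].consensus) == 160

    def test_containment_merges(self, rng):
        a = random_seq(rng, 200)
        b = a[50:150]
        res = assemble_greedy([Read("a", a, "L"), Read("b", b, "L")])
        assert len(res.contigs) == 1
        assert res.contigs[0].consensus == a

    def test_low_identity_overlap_rejected(self, rng):
        ov = random_seq(rng, 40)
        corrupted = list(ov)
        for i in range(0, 40, 8):  # 5 mismatches -> 87.5% identity
            corrupted[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[corrupted[i]]
        a = random_seq(rng, 60) + ov
        b = "".join(corrupted) + random_seq(rng, 60)
        res = assemble_greedy([Read("a", a, "L"), Read("b", b, "L")],
                              AssemblyParams(min_identity=0.95))
        assert len(res.contigs) == 0

    def test_majority_vote_consensus(self, rng):
        base = random_seq(rng, 120)
        variant = base[:60] + ("A" if base[60] != "A" else "C") + base[61:]
        reads = [Read("r1", base, "L"), Read("r2", base[:100], "L"),
                 Read("r3", variant, "L")]
        res = assemble_greedy(reads)
        assert len(res.contigs) == 1
        assert res.contigs[0].consensus == base  # 2-of-3 majority at column 60


class TestPlantedTruth:
    def test_single_transcript_reassembles_to_one_contig(self, rng):
        cfg = SyntheticConfig(n_transcripts=1,
                              transcript_length_dist=(1000, 1000),
                              reads_per_library=25,  # ~7x coverage
                              error_rate=0.0, seed=42)
        transcripts, truth = synthetic.generate_transcriptome(cfg)
        reads = synthetic.sample_library_reads(transcripts, truth, "leaf_leaf", cfg)
        res = assemble_greedy(reads)
        assert len(res.contigs) == 1
        t = transcripts["t0000"]
        c = res.contigs[0].consensus
        assert c in t or revcomp(c) in t

    def test_read_conservation_partition(self, small_config, small_pool):
        transcripts, truth = small_pool
        reads = synthetic.sample_library_reads(transcripts, truth, "bud_0",
                                               small_config)
        res = assemble_greedy(reads)
        out_ids = sorted(
            [rid for c in res.contigs for rid, _ in c.members]
            + [s.id for s in res.singletons]
        )
        assert out_ids == sorted(r.id for r in reads)
        for c in res.contigs:
            assert c.n_reads >= 2
            assert sum(c.library_counts.values()) == c.n_reads

    def test_input_order_invariance(self, small_config, small_pool):
        transcripts, truth = small_pool
        reads = synthetic.sample_library_reads(transcripts, truth, "fruit_pink",
                                               small_config)[:120]
        res1 = assemble_greedy(reads)
        rng = np.random.default_rng(0)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        res2 = assemble_greedy(shuffled)
        assert [c.consensus for c in res1.contigs] == [
            c.consensus for c in res2.contigs]
        assert [s.id for s in res1.singletons] == [s.id for s in res2.singletons]


class TestSummary:
    def test_unigene_total_identity(self, small_config, small_pool):
        transcripts, truth = small_pool
        reads = synthetic.sample_library_reads(transcripts, truth, "bud_397",
                                               small_config)
        res = assemble_greedy(reads)
        table = assembly_summary(res).set_index("sample")
        row = table.loc["all"]
        assert row["n_unigenes"] == row["n_contigs"] + row["n_singletons"]
        assert row["n_unigenes"] == res.n_unigenes
        assert row["reads_assembled"] == len(reads)
        assert row["reads_in_contigs"] + row["n_singletons"] == len(reads)

    def test_empty_input_zero_row(self):
        res = assemble_greedy([])
        table = assembly_summary(res)
        row = table.iloc[-1]
        assert row["reads_assembled"] == 0 and row["n_unigenes"] == 0

    def test_mean_lengths_match_recomputation(self, small_config, small_pool):
        transcripts, truth = small_pool
        reads = synthetic.sample_library_reads(transcripts, truth, "leaf_leaf",
                                               small_config)
        res = assemble_greedy(reads)
        table = assembly_summary(res).set_index("sample")
        if res.contigs:
            expect = round(sum(len(c.consensus) for c in res.contigs)
                           / len(res.contigs), 1)
            assert table.loc["all", "mean_contig_length"] == expect

    def test_membership_covers_all_reads(self, small_config, small_pool):
        transcripts, truth = small_pool
        reads = synthetic.sample_library_reads(transcripts, truth, "fruit_blue",
                                               small_config)
        res = assemble_greedy(reads)
        table = membership_table(res)
        assert sorted(table["read_id"]) == sorted(r.id for r in reads)
        assert set(table["library_id"]) == {"fruit_blue"}


class TestCompareUnigeneSets:
    def test_identical_sets_fully_shared(self, rng):
        seqs = {f"u{i}": random_seq(rng, 300) for i in range(8)}
        cmp = compare_unigene_sets(seqs, seqs)
        assert cmp.shared == 8 and cmp.unique_to_a == 0 and cmp.unique_to_b == 0

    def test_unrelated_sets_share_nothing(self, rng):
        a = {f"a{i}": random_seq(rng, 300) for i in range(6)}
        b = {f"b{i}": random_seq(rng, 300) for i in range(6)}
        cmp = compare_unigene_sets(a, b)
        assert cmp.shared == 0
        assert cmp.unique_to_a == 6 and cmp.unique_to_b == 6

    def test_overlapping_pools_share_intersection(self, rng):
        pool = {f"t{i}": random_seq(rng, 400) for i in range(9)}
        a = {k: pool[k] for k in list(pool)[:6]}  # t0..t5
        b = {k: pool[k] for k in list(pool)[3:]}  # t3..t8
        cmp = compare_unigene_sets(a, b)
        assert cmp.shared == 3
        assert cmp.unique_to_a == 3 and cmp.unique_to_b == 3

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_unigene_sets({}, {"x": random_seq(rng, 100)})
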