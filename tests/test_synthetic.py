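"""Synthetic generator: determinism, planted truth, sampling statistics."""

import math

import numpy as np
import pytest

from est454 import synthetic
from est454.ssr import SSRParams, find_ssrs
from est454.synthetic import (ConfigurationError, SyntheticConfig,
                              generate_qpcr_table, generate_transcriptome,
                              sample_library_reads, trend_exponents)
from est454.types import default_design


class TestTranscriptome:
    def test_determinism(self, small_config, small_pool):
        transcripts, truth = small_pool
        again, truth2 = generate_transcriptome(small_config)
        assert again == transcripts
        assert [r.proportions for r in truth2] == [r.proportions for r in truth]

    def test_planting_is_copy_in(self):
        cfg = SyntheticConfig(n_transcripts=2, transcript_length_dist=(300, 300),
                              ssr_plant_spec=(("AG", 7, 0, 40),), seed=5)
        transcripts, truth = generate_transcriptome(cfg)
        assert transcripts["t0000"][40:54] == "AG" * 7
        assert truth[0].ssr_loci[0].start == 40
        assert truth[0].ssr_loci[0].end == 54

    def test_mining_returns_exactly_planted_loci(self):
        plant = tuple(("AG", 6, i, 50) for i in range(0, 200, 5))
        cfg = SyntheticConfig(n_transcripts=200,
                              transcript_length_dist=(200, 350),
                              ssr_plant_spec=plant, seed=9)
        transcripts, truth = generate_transcriptome(cfg)
        planted = {(L.sequence_id, L.motif, L.repeat_count, L.start)
                   for rec in truth for L in rec.ssr_loci}
        found = set()
        for tid, seq in transcripts.items():
            for L in find_ssrs(seq, SSRParams(), sequence_id=tid):
                found.add((L.sequence_id, L.motif, L.repeat_count, L.start))
        assert found == planted

    def test_lengths_within_bounds(self, small_config, small_pool):
        transcripts, _ = small_pool
        lo, hi = small_config.transcript_length_dist
        assert all(lo <= len(s) <= hi for s in transcripts.values())

    def test_oversized_planted_ssr_rejected(self):
        cfg = SyntheticConfig(n_transcripts=1, transcript_length_dist=(100, 100),
                              ssr_plant_spec=(("AG", 7, 0, 95),), seed=1)
        with pytest.raises(ConfigurationError):
            generate_transcriptome(cfg)

    def test_proportions_sum_to_one_per_library(self, small_config, small_pool):
        _, truth = small_pool
        for _, _, lib in small_config.design.libraries():
            total = sum(rec.proportions[lib] for rec in truth)
            assert total == pytest.approx(1.0)


class TestTrendExponents:
    @pytest.mark.parametrize("pattern,expected", [
        ("flat", [0, 0, 0, 0]),
        ("up", [-3, -2, -1, 0]),
        ("down", [0, -1, -2, -3]),
        ("up_down", [-2, -1, 0, -1]),
        ("down_up", [0, -1, -2, -1]),
    ])
    def test_peak_normalized_profiles(self, pattern, expected):
        assert trend_exponents(pattern, 4) == expected

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ConfigurationError):
            trend_exponents("sideways", 4)


class TestReadSampling:
    def test_zero_error_reads_are_exact_substrings(self, small_config, small_pool):
        transcripts, truth = small_pool
        reads = sample_library_reads(transcripts, truth, "bud_789", small_config)
        assert len(reads) == small_config.reads_per_library
        assert all(r.sequence in transcripts[r.meta["source"]] for r in reads)

    def test_determinism_per_library(self, small_config, small_pool):
        transcripts, truth = small_pool
        a = sample_library_reads(transcripts, truth, "fruit_green", small_config)
        b = sample_library_reads(transcripts, truth, "fruit_green", small_config)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_mean_length_within_clt_bound(self):
        cfg = SyntheticConfig(n_transcripts=20,
                              transcript_length_dist=(900, 1200),
                              reads_per_library=10000,
                              read_length_dist=(287.0, 50.0, 50),
                              error_rate=0.0, seed=77)
        transcripts, truth = generate_transcriptome(cfg)
        reads = sample_library_reads(transcripts, truth, "leaf_leaf", cfg)
        mean = np.mean([len(r.sequence) for r in reads])
        assert abs(mean - 287.0) <= 2 * 50.0 / math.sqrt(10000)

    def test_zero_proportion_transcript_gets_no_reads(self, small_config):
        transcripts, truth = generate_transcriptome(small_config)
        for rec in truth:
            rec.proportions["leaf_leaf"] = 0.0
        truth[0].proportions["leaf_leaf"] = 1.0
        reads = sample_library_reads(transcripts, truth, "leaf_leaf", small_config)
        assert {r.meta["source"] for r in reads} == {"t0000"}

    def test_unknown_library_rejected(self, small_config, small_pool):
        transcripts, truth = small_pool
        with pytest.raises(ConfigurationError):
            sample_library_reads(transcripts, truth, "root_deep", small_config)

    def test_error_rate_produces_mismatches(self, small_config, small_pool):
        import dataclasses

        transcripts, truth = small_pool
        cfg = dataclasses.replace(small_config, error_rate=0.05)
        reads = sample_library_reads(transcripts, truth, "bud_0", cfg)
        n_exact = sum(r.sequence in transcripts[r.meta["source"]] for r in reads)
        # at 5% per-base error on ~287-nt reads, exact copies are rare
        assert n_exact < len(reads) * 0.05

    def test_adapter_prepended(self, small_config, small_pool):
        import dataclasses

        transcripts, truth = small_pool
        cfg = dataclasses.replace(small_config, adapter_seq="TGACGGTCAGTC")
        reads = sample_library_reads(transcripts, truth, "bud_0", cfg)
        assert all(r.sequence.startswith("TGACGGTCAGTC") for r in reads)


class TestQpcrTable:
    def test_zero_noise_flat_gene_constant_ct(self, small_config, small_pool):
        _, truth = small_pool
        flat = [r for r in truth if r.trends.get("bud") == "flat"][0]
        ct = generate_qpcr_table(truth, small_config, "bud", noise_sd=0.0)
        gene_ct = ct[ct["gene"] == flat.transcript_id]["ct"]
        assert gene_ct.nunique() == 1

    def test_zero_noise_up_gene_steps_one_cycle(self, small_config, small_pool):
        # effect_size 2 => gene-minus-reference CT falls log2(2)=1 per up step
        _, truth = small_pool
        up = [r for r in truth if r.trends.get("bud") == "up"][0]
        ct = generate_qpcr_table(truth, small_config, "bud", noise_sd=0.0)
        gene = (ct[ct["gene"] == up.transcript_id]
                .groupby("stage", sort=False)["ct"].mean())
        ref = (ct[ct["gene"] == "ref1"]
               .groupby("stage", sort=False)["ct"].mean())
        diffs = (gene - ref).tolist()
        steps = [round(a - b, 9) for a, b in zip(diffs, diffs[1:])]
        assert steps == [1.0, 1.0, 1.0]

    def test_all_ct_capped(self, small_config, small_pool):
        _, truth = small_pool
        ct = generate_qpcr_table(truth, small_config, "bud", noise_sd=5.0,
                                 gene_base_ct=38.0)
        assert (ct["ct"] <= 40.0).all()

    def test_determinism(self, small_config, small_pool):
        _, truth = small_pool
        a = generate_qpcr_table(truth, small_config, "fruit")
        b = generate_qpcr_table(truth, small_config, "fruit")
        assert a.equals(b)
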