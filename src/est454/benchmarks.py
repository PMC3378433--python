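"""Planted-truth validation experiments.

Each experiment builds synthetic data with known ground truth, runs one stage
of the pipeline on it, and measures how faithfully the stage recovers the
truth.  They are used by the test suite and by ``scripts/acceptance.py``; the
problem sizes are the package's reference validation conditions (documented in
docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import assembly, expression, qpcr, synthetic
from .ssr import SSRParams, mine_ssrs
from .synthetic import SyntheticConfig
from .types import revcomp


def _child_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def ssr_recovery(seed: int, n_sequences: int = 1000) -> dict:
    """Mine planted microsatellites from rejection-sampled backgrounds.

    About a third of the sequences carry one planted SSR (motifs spanning all
    four length categories, repeat counts at and above threshold); the rest
    are repeat-free background.  Reports recall of the planted loci (exact
    motif, count, and coordinates) and the number of loci found anywhere else.
    """
    motifs = [("AG", 5), ("AG", 9), ("AT", 6), ("CT", 7),
              ("AAG", 4), ("ACC", 5), ("ATC", 4),
              ("AAGT", 3), ("ACGT", 4), ("AACGT", 3), ("AGCTC", 4)]
    plant = tuple(
        (motifs[i % len(motifs)][0], motifs[i % len(motifs)][1], i, 60)
        for i in range(0, n_sequences, 3)
    )
    cfg = SyntheticConfig(
        n_transcripts=n_sequences,
        transcript_length_dist=(200, 400),
        ssr_plant_spec=plant,
        seed=_child_seed(seed, 10),
    )
    transcripts, truth = synthetic.generate_transcriptome(cfg)
    planted = {
        (L.sequence_id, L.motif, L.repeat_count, L.start, L.end)
        for rec in truth for L in rec.ssr_loci
    }
    loci, n_mined = mine_ssrs(transcripts, SSRParams(min_seq_length=0))
    found = {(L.sequence_id, L.motif, L.repeat_count, L.start, L.end)
             for L in loci}
    recalled = planted & found
    return {
        "n_sequences": n_mined,
        "n_planted": len(planted),
        "recall_percent": round(100.0 * len(recalled) / len(planted), 1),
        "false_positives": len(found - planted),
    }


def assembly_fidelity(seed: int, n_transcripts: int = 50,
                      coverage: float = 5.0) -> dict:
    """Assemble error-free reads at uniform coverage and check the partition
    (every read in exactly one contig or singleton) and the no-chimera
    property (each contig's members share one source transcript and its
    consensus is an exact substring of it)."""
    cfg = SyntheticConfig(
        n_transcripts=n_transcripts,
        transcript_length_dist=(700, 900),
        reads_per_library=1,  # replaced below
        error_rate=0.0,
        trend_assignment={i: {} for i in range(n_transcripts)},  # all flat
        seed=_child_seed(seed, 20),
    )
    mean_len = cfg.read_length_dist[0]
    n_reads = math.ceil(n_transcripts * 800 * coverage / mean_len)
    cfg = dataclasses.replace(cfg, reads_per_library=n_reads)
    transcripts, truth = synthetic.generate_transcriptome(cfg)
    for rec in truth:  # uniform abundance so every transcript gets ~coverage
        rec.base_weight = 1.0
    synthetic._fill_proportions(truth, cfg)
    reads = synthetic.sample_library_reads(transcripts, truth, "leaf_leaf", cfg)
    result = assembly.assemble_greedy(reads)
    by_id = {r.id: r for r in reads}
    ids_out = [rid for c in result.contigs for rid, _ in c.members]
    ids_out += [s.id for s in result.singletons]
    partition_ok = sorted(ids_out) == sorted(r.id for r in reads)
    n_chimeric = 0
    for c in result.contigs:
        sources = {by_id[rid].meta["source"] for rid, _ in c.members}
        if len(sources) != 1:
            n_chimeric += 1
            continue
        t = transcripts[next(iter(sources))]
        if c.consensus not in t and revcomp(c.consensus) not in t:
            n_chimeric += 1
    return {
        "n_reads": len(reads),
        "n_contigs": len(result.contigs),
        "n_singletons": len(result.singletons),
        "read_conservation_percent": 100.0 if partition_ok else 0.0,
        "chimeric_contigs": n_chimeric,
    }


def trend_recovery(seed: int, reads_per_library: int = 5000,
                   n_transcripts: int = 40, effect_size: float = 2.0,
                   error_rate: float = 0.01, group: str = "bud",
                   subsample_for_contigs: int = 900) -> dict:
    """Full digital-expression chain on one organ group: sample reads for
    every stage, assemble contigs from a pooled subsample, count reads from
    all libraries against them, classify frequency trends, and score the
    calls of the top-abundant contigs against the planted patterns."""
    cfg = SyntheticConfig(
        n_transcripts=n_transcripts,
        reads_per_library=reads_per_library,
        effect_size=effect_size,
        error_rate=error_rate,
        seed=_child_seed(seed, 30),
    )
    transcripts, truth = synthetic.generate_transcriptome(cfg)
    libs = cfg.design.library_ids(group)
    reads = {lib: synthetic.sample_library_reads(transcripts, truth, lib, cfg)
             for lib in libs}
    pool = [r for lib in libs for r in reads[lib]]
    rng = np.random.default_rng(_child_seed(seed, 31))
    idx = sorted(rng.choice(len(pool), size=min(subsample_for_contigs,
                                                len(pool)), replace=False))
    result = assembly.assemble_greedy([pool[i] for i in idx])
    counts, totals = expression.assign_reads(result.contigs, reads)
    freqs = expression.frequency_table(counts, totals)
    by_id = {r.id: r for r in pool}
    trend_of = {rec.transcript_id: rec.trends.get(group, "flat")
                for rec in truth}
    params = expression.TrendParams()
    contig_by_id = {c.id: c for c in result.contigs}
    n_ok = n_tot = 0
    for lib in libs:
        for cid in expression.top_abundant(counts, lib, params):
            members = contig_by_id[cid].members
            src_votes: dict[str, int] = {}
            for rid, _ in members:
                s = by_id[rid].meta["source"]
                src_votes[s] = src_votes.get(s, 0) + 1
            src = max(sorted(src_votes), key=src_votes.get)
            call = expression.classify_trend(
                [float(freqs.at[cid, lib_]) for lib_ in libs], params)
            n_tot += 1
            n_ok += call.pattern == trend_of[src]
    return {
        "n_calls": n_tot,
        "n_correct": n_ok,
        "recovery_percent": round(100.0 * n_ok / n_tot, 1),
        "n_contigs": len(result.contigs),
    }


def qpcr_roundtrip(seed: int, noise_sd: float = 0.0) -> dict:
    """Planted CT tables pushed through normalization, ddCT folds, and trend
    classification; at zero noise every planted label must come back."""
    cfg = SyntheticConfig(seed=_child_seed(seed, 40))
    _, truth = synthetic.generate_transcriptome(
        dataclasses.replace(cfg, n_transcripts=20,
                            transcript_length_dist=(200, 300)))
    params = expression.TrendParams()
    qp = qpcr.QPCRParams()
    n_ok = n_tot = 0
    for group in cfg.design.trend_groups():
        ct = synthetic.generate_qpcr_table(
            truth, dataclasses.replace(cfg, n_transcripts=20), group,
            ref_genes=("ref1", "ref2"), noise_sd=noise_sd)
        ct = qpcr.load_ct_table(ct, qp)
        dct = qpcr.global_normalize(ct, ["ref1", "ref2"])
        stages = [s.label for s in cfg.design.stages(group)]
        folds = qpcr.ddct_fold(dct, qp.baseline[group], stage_order=stages)
        folds = folds.drop(index=["ref1", "ref2"])
        calls = qpcr.qpcr_trends(folds, stages, params, group=group)
        for rec in truth:
            n_tot += 1
            n_ok += calls[rec.transcript_id].pattern == rec.trends.get(group, "flat")
    return {
        "n_genes": n_tot,
        "n_correct": n_ok,
        "concordance_percent": round(100.0 * n_ok / n_tot),
    }


def read_length_calibration(seed: int, n_reads: int = 10000) -> dict:
    """Sample one library and measure the mean read length (the generator
    targets the platform's 287-nt average)."""
    cfg = SyntheticConfig(
        n_transcripts=30, reads_per_library=n_reads,
        transcript_length_dist=(800, 1200), error_rate=0.0,
        seed=_child_seed(seed, 50),
    )
    transcripts, truth = synthetic.generate_transcriptome(cfg)
    reads = synthetic.sample_library_reads(transcripts, truth, "leaf_leaf", cfg)
    lengths = [len(r.sequence) for r in reads]
    return {
        "n_reads": len(lengths),
        "mean_length_nt": round(float(np.mean(lengths)), 2),
    }
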