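"""End-to-end pipeline driver: simulate -> qc -> assemble -> dge -> ssr ->
qpcr -> report.

Every stage reads its inputs from and writes its artifacts to one output
directory, so stages can be re-run individually from the CLI.  All artifacts
are plain FASTA/TSV and regenerable from (config, seed); two runs with the
same config produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assembly as asm
from . import expression as dge
from . import homology, qc, qpcr, ssr, synthetic
from .io import read_fasta, write_fasta, write_tsv_report
from .types import StageDesign, default_design

log = logging.getLogger("est454")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    outdir: str = "est454_out"
    seed: int = 0
    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig)
    qc: qc.QCParams = field(default_factory=qc.QCParams)
    assembly: asm.AssemblyParams = field(default_factory=asm.AssemblyParams)
    scoring: homology.ScoringParams = field(
        default_factory=lambda: homology.ScoringParams(
            seed_stride=4, min_seed_votes=2))
    trend: dge.TrendParams = field(default_factory=dge.TrendParams)
    ssr: ssr.SSRParams = field(default_factory=ssr.SSRParams)
    qpcr: qpcr.QPCRParams = field(default_factory=qpcr.QPCRParams)
    qpcr_noise_sd: float = 0.25

    @property
    def design(self) -> StageDesign:
        return self.synthetic.design


def demo_config(outdir: str = "est454_demo", seed: int = 0) -> PipelineConfig:
    """A small configuration that runs the whole pipeline in minutes."""
    syn = synthetic.SyntheticConfig(
        n_transcripts=24,
        transcript_length_dist=(500, 900),
        reads_per_library=250,
        error_rate=0.01,
        adapter_seq="TGACGGTCAGTCGTTGAGCA",
        ssr_plant_spec=(("AG", 7, 0, 60), ("AAG", 5, 1, 100), ("ACGT", 4, 2, 80)),
        seed=seed,
    )
    cfg = PipelineConfig(outdir=outdir, seed=seed, synthetic=syn)
    cfg = dataclasses.replace(
        cfg, qc=qc.QCParams(adapters=(syn.adapter_seq,)))
    return cfg


def load_config(path: str) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    simple = {k: v for k, v in raw.items() if k in ("outdir", "seed", "qpcr_noise_sd")}
    cfg = dataclasses.replace(cfg, **simple)
    blocks = {
        "synthetic": synthetic.SyntheticConfig,
        "qc": qc.QCParams,
        "assembly": asm.AssemblyParams,
        "scoring": homology.ScoringParams,
        "trend": dge.TrendParams,
        "ssr": ssr.SSRParams,
        "qpcr": qpcr.QPCRParams,
    }
    unknown = set(raw) - set(simple) - set(blocks)
    if unknown:
        raise PipelineError(f"config: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in blocks.items():
        if name in raw:
            block = dict(raw[name])
            for key in ("adapters", "ssr_plant_spec", "ref_genes"):
                if key in block and isinstance(block[key], list):
                    block[key] = tuple(
                        tuple(x) if isinstance(x, list) else x for x in block[key])
            if "min_repeats" in block:
                block["min_repeats"] = {int(k): int(v)
                                        for k, v in block["min_repeats"].items()}
            kwargs[name] = cls(**block)
    if "seed" in raw and "synthetic" not in kwargs:
        kwargs["synthetic"] = dataclasses.replace(cfg.synthetic, seed=raw["seed"])
    return dataclasses.replace(cfg, **kwargs)


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    transcripts, truth = synthetic.generate_transcriptome(cfg.synthetic, cfg.ssr)
    write_fasta(
        [type("R", (), {"id": k, "sequence": v}) for k, v in transcripts.items()],
        out / "transcripts.fasta",
    )
    write_tsv_report(synthetic.truth_table(truth, cfg.design), out / "truth.tsv")
    write_tsv_report(synthetic.ssr_truth_table(truth), out / "truth_ssr.tsv")
    for group, stage, lib in cfg.design.libraries():
        reads = synthetic.sample_library_reads(transcripts, truth, lib, cfg.synthetic)
        write_fasta(reads, out / f"{lib}.fasta")
        log.info("simulate: %s: %d reads", lib, len(reads))
    for group in cfg.design.trend_groups():
        ct = synthetic.generate_qpcr_table(
            truth, cfg.synthetic, group,
            ref_genes=cfg.qpcr.ref_genes or ("ref1", "ref2"),
            noise_sd=cfg.qpcr_noise_sd, max_ct=cfg.qpcr.max_ct)
        write_tsv_report(ct, out / f"ct_{group}.tsv")
    log.info("simulate: %d transcripts, %d libraries",
             len(transcripts), len(cfg.design.libraries()))


def _library_reads(cfg: PipelineConfig, suffix: str) -> dict[str, list]:
    out = _out(cfg)
    reads = {}
    for _, _, lib in cfg.design.libraries():
        path = out / f"{lib}{suffix}"
        if not path.exists():
            raise PipelineError(f"missing library file {path}")
        reads[lib] = read_fasta(path, library_id=lib)
    return reads


def stage_qc(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    summaries = []
    for lib, reads in _library_reads(cfg, ".fasta").items():
        kept, summary = qc.run_qc(reads, cfg.qc)
        write_fasta(kept, out / f"{lib}.qc.fasta")
        summaries.append(summary)
        log.info("qc: %s: %d -> %d reads", lib, len(reads), len(kept))
    write_tsv_report(pd.concat(summaries, ignore_index=True),
                     out / "qc_summary.tsv")


def stage_assemble(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    pooled = [r for reads in _library_reads(cfg, ".qc.fasta").values()
              for r in reads]
    result = asm.assemble_greedy(pooled, cfg.assembly)
    write_fasta(result.contigs, out / "contigs.fasta")
    write_tsv_report(asm.membership_table(result), out / "membership.tsv")
    write_tsv_report(asm.assembly_summary(result), out / "assembly_summary.tsv")
    log.info("assemble: %d reads -> %d contigs + %d singletons",
             len(pooled), len(result.contigs), len(result.singletons))


def stage_dge(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    contigs = read_fasta(out / "contigs.fasta")
    if not contigs:
        raise PipelineError("dge: no contigs (run assemble first)")
    reads = _library_reads(cfg, ".qc.fasta")
    scoring = dataclasses.replace(cfg.scoring,
                                  evalue_cutoff=cfg.trend.evalue_cutoff)
    counts, totals = dge.assign_reads(contigs, reads, scoring)
    freqs = dge.frequency_table(counts, totals)
    counts.insert(0, "contig_id", counts.index)
    write_tsv_report(counts, out / "read_counts.tsv")
    counts = counts.drop(columns="contig_id")
    report = dge.abundance_report(counts, freqs, cfg.design, cfg.trend)
    write_tsv_report(report, out / "abundance_report.tsv")
    log.info("dge: counted %d libraries over %d contigs",
             len(totals), len(counts))


def stage_ssr(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    contigs = read_fasta(out / "contigs.fasta")
    singles = {}
    membership = pd.read_csv(out / "membership.tsv", sep="\t")
    single_ids = set(membership.loc[
        membership["read_id"] == membership["unigene_id"], "unigene_id"])
    for lib, reads in _library_reads(cfg, ".qc.fasta").items():
        for r in reads:
            if r.id in single_ids:
                singles[r.id] = r.sequence
    unigenes = {c.id: c.sequence for c in contigs} | singles
    loci, n_mined = ssr.mine_ssrs(unigenes, cfg.ssr)
    write_tsv_report(ssr.loci_table(loci), out / "ssr_loci.tsv")
    write_tsv_report(ssr.summarize_ssrs(loci, n_mined), out / "ssr_summary.tsv")
    cands = ssr.primer_candidates(loci, unigenes, cfg.ssr)
    write_tsv_report(
        pd.DataFrame(
            [
                (c.locus.sequence_id, c.locus.motif, c.locus.start, c.locus.end,
                 round(c.gc, 1), c.left_flank, c.right_flank, c.passed,
                 ";".join(c.failure_reasons))
                for c in cands
            ],
            columns=["sequence_id", "motif", "start", "end", "gc_percent",
                     "left_flank", "right_flank", "passed", "reasons"],
        ),
        out / "primer_candidates.tsv",
    )
    log.info("ssr: %d loci in %d unigenes; %d primer candidates pass",
             len(loci), n_mined, sum(c.passed for c in cands))


def stage_qpcr(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    ref_genes = list(cfg.qpcr.ref_genes or ("ref1", "ref2"))
    for group in cfg.design.trend_groups():
        ct = qpcr.load_ct_table(pd.read_csv(out / f"ct_{group}.tsv", sep="\t"),
                                cfg.qpcr)
        dct = qpcr.global_normalize(ct, ref_genes)
        stages = [s.label for s in cfg.design.stages(group)]
        baseline = cfg.qpcr.baseline.get(group, stages[0])
        folds = qpcr.ddct_fold(dct, baseline, stage_order=stages)
        folds = folds.drop(index=[g for g in ref_genes if g in folds.index])
        tab = folds.copy()
        tab.insert(0, "gene", tab.index)
        write_tsv_report(tab, out / f"qpcr_folds_{group}.tsv")
        trends = qpcr.qpcr_trends(folds, stages, cfg.trend, group=group)
        write_tsv_report(
            pd.DataFrame(
                [(g, t.pattern) for g, t in sorted(trends.items())],
                columns=["gene", "pattern"],
            ),
            out / f"qpcr_trends_{group}.tsv",
        )
        log.info("qpcr: %s: %d genes", group, len(trends))


def stage_report(cfg: PipelineConfig) -> None:
    """Predicted (read-frequency) vs observed (qPCR) trend concordance."""
    out = _out(cfg)
    contigs = read_fasta(out / "contigs.fasta")
    transcripts = read_fasta(out / "transcripts.fasta")
    counts = pd.read_csv(out / "read_counts.tsv", sep="\t", index_col="contig_id")
    totals = {lib: len(reads)
              for lib, reads in _library_reads(cfg, ".qc.fasta").items()}
    freqs = dge.frequency_table(counts, totals)
    # map each contig to its source gene by homology against the transcript set
    hits = homology.seed_extend_search(contigs, transcripts, cfg.scoring)
    best: dict[str, homology.AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.score > cur.score:
            best[h.query_id] = h
    gene_of = {cid: h.subject_id for cid, h in best.items()}
    rows = []
    for group in cfg.design.trend_groups():
        stages = [s.label for s in cfg.design.stages(group)]
        obs = pd.read_csv(out / f"qpcr_trends_{group}.tsv", sep="\t",
                          index_col="gene")["pattern"].to_dict()
        # per gene, predict from the deepest contig mapping to it
        depth: dict[str, tuple[int, str]] = {}
        for cid, gene in gene_of.items():
            d = int(counts.loc[cid].sum())
            if gene not in depth or d > depth[gene][0]:
                depth[gene] = (d, cid)
        calls = dge.trend_calls(freqs, cfg.design, group, cfg.trend,
                                ids=[cid for _, cid in depth.values()])
        predicted = {g: calls[cid].pattern for g, (_, cid) in depth.items()
                     if g in obs}
        observed = {g: obs[g] for g in predicted}
        if predicted:
            n_match, n_total, pct = qpcr.concordance(predicted, observed)
        else:  # pragma: no cover - degenerate demo config
            n_match = n_total = pct = 0
        rows.append((group, n_match, n_total, pct))
    write_tsv_report(
        pd.DataFrame(rows, columns=["group", "n_match", "n_total", "percent"]),
        out / "concordance.tsv",
    )
    log.info("report: concordance written")


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "assemble": stage_assemble,
    "dge": stage_dge,
    "ssr": stage_ssr,
    "qpcr": stage_qpcr,
    "report": stage_report,
}

STAGE_ORDER = ["simulate", "qc", "assemble", "dge", "ssr", "qpcr", "report"]


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> None:
    """Run stages in order; any failure raises PipelineError naming the stage."""
    for name in stages or STAGE_ORDER:
        try:
            log.info("stage %s: start", name)
            STAGES[name](cfg)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc
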