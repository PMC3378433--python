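# est454

A toolkit for analysing 454 pyrosequencing EST (expressed sequence tag)
libraries from stage-structured experiments — the kind of study where cDNA
libraries are sequenced from several organs and developmental stages (flower
buds across a cold-acclimation time course measured in chill units, fruit
across ripening stages, leaves) and compared to find differentially expressed
genes and to mine molecular markers.

It is aimed at people working with legacy 454/Sanger EST collections in
non-model organisms, and at anyone who wants a small, fully tested, pure-Python
reference implementation of this classic analysis chain:

1. **Read QC** — end-anchored adapter/primer masking and a minimum-length
   filter (default: drop reads shorter than 50 nt).
2. **Greedy overlap-consensus assembly** — best-overlap-first merging (both
   strands, containments included) with a 30-nt minimum overlap, per-column
   majority-vote consensus, and per-library read tracking.  Contigs (≥ 2
   reads) plus singletons form the unigene set.
3. **Homology search** — a self-contained seed-and-extend local aligner
   (11-mer seeds, ungapped X-drop prescreen, windowed gapped refinement) with
   Karlin–Altschul E-values, `E = K·m·n·e^{−λS}`, and a 1e-5 reporting cutoff.
4. **Digital expression** — count reads homologous to each library's most
   abundant contigs across *all* libraries (best hit per read, so nothing is
   double-counted), convert to percent-of-library frequencies `f_i`, and
   classify each ordered profile: step i is *up* if
   `(f_{i+1}+p)/(f_i+p) ≥ τ`, *down* if `≤ 1/τ`, else *flat* (τ = 1.5,
   p = 0.01% by default); collapsing the steps gives
   `up / down / up_down / down_up / flat / complex`.
5. **qPCR concordance** — ΔΔCT relative quantification
   (`fold = 2^{−(ΔCT_stage − ΔCT_baseline)}`) with global reference-gene
   normalization, a 40-cycle CT cap, trend classification of fold profiles,
   and exact-match concordance between read-predicted and qPCR-observed
   patterns.
6. **EST-SSR mining** — maximal perfect microsatellites with primitive 2–5 nt
   motifs (≥ 5/4/3/3 repeats for di/tri/tetra/penta), canonical motif classes
   under rotation + reverse complement (AG/GA/TC/CT is one class),
   Table-style composition summaries, primer-candidate filtering
   (whole-sequence GC 40–60%, ≥ 20-nt flanks), and marker-screen
   amplification/polymorphism rates.
7. **Synthetic data** — a 454-like read simulator (mean length 287 nt,
   substitution errors, optional adapters) over a shared transcript pool with
   planted expression trends, planted SSR loci on repeat-free backgrounds,
   and matched triplicate CT tables — so every stage is testable against
   known ground truth without any downloads.

## Worked example

```python
from est454 import synthetic, assembly, expression, ssr
from est454.synthetic import SyntheticConfig

cfg = SyntheticConfig(n_transcripts=12, transcript_length_dist=(500, 800),
                      reads_per_library=800, error_rate=0.01, seed=42,
                      ssr_plant_spec=(("AG", 7, 0, 60),))
transcripts, truth = synthetic.generate_transcriptome(cfg)
libs = cfg.design.library_ids("bud")            # four chill-unit stages
reads = {lib: synthetic.sample_library_reads(transcripts, truth, lib, cfg)
         for lib in libs}

result = assembly.assemble_greedy(reads["bud_0"])
print(f"bud_0: {len(reads['bud_0'])} reads -> {len(result.contigs)} contigs, "
      f"{len(result.singletons)} singletons")

counts, totals = expression.assign_reads(result.contigs, reads)
freqs = expression.frequency_table(counts, totals)
for cid in expression.top_abundant(counts, "bud_0", expression.TrendParams(top_n=3)):
    call = expression.classify_trend([float(freqs.at[cid, l]) for l in libs],
                                     expression.TrendParams())
    print(cid, [round(float(freqs.at[cid, l]), 2) for l in libs], "->", call.pattern)

loci, _ = ssr.mine_ssrs({c.id: c.consensus for c in result.contigs})
for L in loci:
    print(f"SSR: {L.sequence_id} ({L.motif})x{L.repeat_count} "
          f"at {L.start}-{L.end}, class {L.canonical}")
```

prints

```
bud_0: 800 reads -> 18 contigs, 28 singletons
contig_00013 [23.12, 25.12, 23.5, 27.5] -> flat
contig_00006 [16.0, 5.62, 4.0, 5.38] -> down
contig_00010 [9.62, 6.5, 4.12, 1.38] -> down
SSR: contig_00016 (AG)x7 at 60-74, class AG
```

The three most read-rich contigs in the first bud library are shown with
their percent-of-library frequencies across the four cold-acclimation stages
and the pattern the classifier assigns (the first is a stably expressed
transcript; the other two decline as acclimation progresses).  The planted
(AG)×7 microsatellite is recovered on its contig with exact coordinates.

The same chain is available from the shell: `est454 all --outdir demo
--seed 7` runs simulate → qc → assemble → dge → ssr → qpcr → report with a
small built-in configuration and writes FASTA/TSV artifacts for every stage
(`est454 simulate --help` etc. for individual stages and YAML configs).

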