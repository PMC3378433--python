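"""Stage-structured synthetic transcriptomes, 454-like read libraries, and
matched qPCR CT tables with known ground truth.

The generator emulates the study design the pipeline targets: several organ
groups sampled over ordered stages (a bud cold-acclimation series, a fruit
ripening series, leaves), all drawing reads from one shared transcript pool.
Each transcript carries an expression pattern per multi-stage group (up, down,
up_down, down_up, or flat) encoded as a multiplicative per-step fold change on
a baseline abundance, so a single ``effect_size`` controls how strong every
planted trend is.  Reads are 454-like: single-end, mean length 287 nt with a
truncated-normal spread, substitution errors only (no homopolymer indel model
— basecalling is out of scope), and an optional 5' adapter for exercising QC.

Background transcript sequence is i.i.d. uniform ACGT, rejection-sampled so
that no accidental microsatellite meets the mining thresholds; planted SSRs
are therefore the only loci present, giving a clean truth set for recall and
false-positive tests.  Junction bases flanking a planted repeat are resampled
so the planted run cannot extend, keeping recorded coordinates exact.

Determinism: every sampling routine derives its RNG from ``config.seed`` (and
the library index, for reads), so identical configs give byte-identical
output regardless of the order libraries are sampled in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ssr import SSRLocus, SSRParams, find_ssrs
from .types import Read, StageDesign, default_design

TREND_CHOICES = ("up", "down", "up_down", "down_up", "flat")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    n_transcripts: int = 40
    transcript_length_dist: tuple[int, int] = (600, 1200)  # min, max nt
    trend_assignment: Optional[Mapping[int, Mapping[str, str]]] = None
    effect_size: float = 2.0  # fold change per trend step
    reads_per_library: int = 5000
    read_length_dist: tuple[float, float, int] = (287.0, 50.0, 50)  # mean, sd, min
    error_rate: float = 0.01  # per-base substitution probability
    adapter_seq: str = ""
    ssr_plant_spec: tuple[tuple[str, int, int, int], ...] = ()  # motif, n, tidx, offset
    seed: int = 0
    design: StageDesign = field(default_factory=default_design)

    def __post_init__(self) -> None:
        if self.n_transcripts < 1 or self.reads_per_library < 1:
            raise ConfigurationError("counts must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigurationError("error_rate must be in [0, 1)")
        if self.effect_size <= 1.0:
            raise ConfigurationError("effect_size must exceed 1")
        lo, hi = self.transcript_length_dist
        if not (0 < lo <= hi):
            raise ConfigurationError("bad transcript_length_dist")
        for motif, count, tidx, offset in self.ssr_plant_spec:
            if not (0 <= tidx < self.n_transcripts):
                raise ConfigurationError(f"planted SSR transcript {tidx} out of range")
            if offset < 0 or count < 2:
                raise ConfigurationError("bad ssr_plant_spec entry")


@dataclass
class TruthRecord:
    """Ground truth for one transcript: trends, expected per-library read
    proportions (summing to 1 within each library over all transcripts), and
    planted SSR loci."""

    transcript_id: str
    trends: dict[str, str]  # organ group -> pattern label
    proportions: dict[str, float]  # library_id -> expected read fraction
    ssr_loci: list[SSRLocus]
    base_weight: float = 1.0


def transcript_id(i: int) -> str:
    return f"t{i:04d}"


def default_trend_assignment(config: SyntheticConfig) -> dict[int, dict[str, str]]:
    """Half the pool is flat (as in a real library, where most transcripts do
    not change); the four trending patterns cycle over the other half,
    independently phased per organ group so one transcript's bud and fruit
    trends differ."""
    trending = ("up", "down", "up_down", "down_up")
    out: dict[int, dict[str, str]] = {}
    groups = config.design.trend_groups()
    for i in range(config.n_transcripts):
        if i % 2 == 0:
            out[i] = {g: "flat" for g in groups}
        else:
            out[i] = {
                g: trending[(i // 2 + gi) % len(trending)]
                for gi, g in enumerate(groups)
            }
    return out


def trend_exponents(pattern: str, n_stages: int) -> list[int]:
    """Cumulative fold exponent per stage for a pattern: one effect-size step
    per stage, turning at the midpoint for the biphasic patterns.

    Exponents are shifted so each pattern peaks at exponent 0 — a transcript
    rises toward (or falls from) its base abundance and never above it.  This
    keeps the per-library normalizing total nearly constant across stages, so
    the expected frequency profile of every transcript follows its planted
    pattern rather than being distorted by other transcripts' trends.
    """
    n_steps = n_stages - 1
    if pattern == "flat":
        steps = [0] * n_steps
    elif pattern == "up":
        steps = [1] * n_steps
    elif pattern == "down":
        steps = [-1] * n_steps
    elif pattern == "up_down":
        turn = math.ceil(n_steps / 2)
        steps = [1] * turn + [-1] * (n_steps - turn)
    elif pattern == "down_up":
        turn = math.ceil(n_steps / 2)
        steps = [-1] * turn + [1] * (n_steps - turn)
    else:
        raise ConfigurationError(f"unknown trend pattern {pattern!r}")
    expo = [0]
    for s in steps:
        expo.append(expo[-1] + s)
    peak = max(expo)
    return [e - peak for e in expo]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _plant_ssr(seq: list[str], motif: str, count: int, offset: int,
               rng: np.random.Generator) -> None:
    unit = motif.upper()
    m = len(unit)
    run = unit * count
    end = offset + len(run)
    seq[offset:end] = list(run)
    # guard junctions so the planted run is maximal exactly as recorded
    if offset > 0 and seq[offset - 1] == unit[-1]:
        choices = [b for b in "ACGT" if b != unit[-1]]
        seq[offset - 1] = choices[int(rng.integers(len(choices)))]
    if end < len(seq) and seq[end] == unit[0]:
        choices = [b for b in "ACGT" if b != unit[0]]
        seq[end] = choices[int(rng.integers(len(choices)))]


def generate_transcriptome(config: SyntheticConfig,
                           ssr_params: SSRParams | None = None
                           ) -> tuple[dict[str, str], list[TruthRecord]]:
    """Generate the shared transcript pool and its truth records.

    Background is rejection-sampled to be free of any maximal perfect repeat
    meeting the mining thresholds, so SSR mining over the pool returns exactly
    the planted loci.  Raises ConfigurationError when a planted SSR does not
    fit inside its transcript.
    """
    ssr_params = ssr_params or SSRParams()
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.transcript_length_dist
    lengths = rng.integers(lo, hi + 1, size=config.n_transcripts)
    planted: dict[int, list[tuple[str, int, int]]] = {}
    for motif, count, tidx, offset in config.ssr_plant_spec:
        if offset + len(motif) * count > lengths[tidx]:
            raise ConfigurationError(
                f"planted SSR ({motif} x{count} at {offset}) exceeds transcript "
                f"{tidx} bounds (length {lengths[tidx]})"
            )
        planted.setdefault(tidx, []).append((motif.upper(), count, offset))

    assignment = (dict(config.trend_assignment)
                  if config.trend_assignment is not None
                  else default_trend_assignment(config))
    base_weights = np.exp(rng.normal(0.0, 0.6, size=config.n_transcripts))

    transcripts: dict[str, str] = {}
    truth: list[TruthRecord] = []
    for i in range(config.n_transcripts):
        tid = transcript_id(i)
        want = [
            SSRLocus(sequence_id=tid, motif=m, repeat_count=c,
                     start=off, end=off + len(m) * c)
            for m, c, off in sorted(planted.get(i, []), key=lambda t: t[2])
        ]
        for _attempt in range(200):
            chars = list(_random_seq(rng, int(lengths[i])))
            for m, c, off in planted.get(i, []):
                _plant_ssr(chars, m, c, off, rng)
            seq = "".join(chars)
            if find_ssrs(seq, ssr_params, sequence_id=tid) == want:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigurationError(
                f"could not build a repeat-free background for {tid}")
        transcripts[tid] = seq
        truth.append(TruthRecord(
            transcript_id=tid,
            trends=dict(assignment.get(i, {})),
            proportions={},
            ssr_loci=want,
            base_weight=float(base_weights[i]),
        ))

    _fill_proportions(truth, config)
    return transcripts, truth


def _fill_proportions(truth: list[TruthRecord], config: SyntheticConfig) -> None:
    design = config.design
    for group_name, stages in design.groups:
        n = len(stages)
        weights = np.zeros(len(truth))
        per_stage = []
        for rec in truth:
            pattern = rec.trends.get(group_name, "flat")
            expo = trend_exponents(pattern if n >= 2 else "flat", max(n, 2))
            per_stage.append([rec.base_weight * config.effect_size ** e
                              for e in expo[:n]])
        arr = np.array(per_stage)  # transcripts x stages
        arr = arr / arr.sum(axis=0, keepdims=True)
        for si, st in enumerate(stages):
            lib = design.library_id(group_name, st)
            for ti, rec in enumerate(truth):
                rec.proportions[lib] = float(arr[ti, si])


def sample_library_reads(transcripts: Mapping[str, str],
                         truth: Sequence[TruthRecord],
                         library_id: str,
                         config: SyntheticConfig) -> list[Read]:
    """Draw one library's reads: multinomial over transcripts by expected
    proportion, truncated-normal lengths, uniform start positions, i.i.d.
    substitution errors, optional 5' adapter.  Each read records its source
    transcript and coordinates in ``meta`` (for tests only)."""
    all_libs = [lib for _, _, lib in config.design.libraries()]
    if library_id not in all_libs:
        raise ConfigurationError(f"library {library_id!r} not in stage design")
    rng = np.random.default_rng([config.seed, 2, all_libs.index(library_id)])
    mean, sd, min_len = config.read_length_dist
    props = np.array([rec.proportions[library_id] for rec in truth])
    counts = rng.multinomial(config.reads_per_library, props)
    reads: list[Read] = []
    serial = 0
    for rec, n in zip(truth, counts):
        seq = transcripts[rec.transcript_id]
        tlen = len(seq)
        for _ in range(int(n)):
            L = int(round(rng.normal(mean, sd)))
            L = max(min_len, min(L, tlen))
            start = int(rng.integers(0, tlen - L + 1))
            frag = seq[start:start + L]
            if config.error_rate > 0:
                n_err = rng.binomial(L, config.error_rate)
                if n_err:
                    pos = rng.choice(L, size=n_err, replace=False)
                    chars = list(frag)
                    for p in pos:
                        alt = [b for b in "ACGT" if b != chars[p]]
                        chars[p] = alt[int(rng.integers(3))]
                    frag = "".join(chars)
            if config.adapter_seq:
                frag = config.adapter_seq.upper() + frag
            reads.append(Read(
                id=f"{library_id}_r{serial:06d}",
                sequence=frag,
                library_id=library_id,
                meta={"source": rec.transcript_id, "start": start,
                      "end": start + L},
            ))
            serial += 1
    return reads


def generate_qpcr_table(truth: Sequence[TruthRecord],
                        config: SyntheticConfig,
                        group: str,
                        n_replicates: int = 3,
                        ref_genes: Sequence[str] = ("ref1", "ref2"),
                        noise_sd: float = 0.25,
                        gene_base_ct: float = 26.0,
                        ref_ct: float = 20.0,
                        max_ct: float = 40.0,
                        genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Triplicate-style CT table consistent with the planted trends.

    A gene's mean CT drops by log2(effect_size) per planted up-step relative
    to the (flat) reference genes; Gaussian replicate noise with ``noise_sd``
    cycles is added and everything is capped at ``max_ct``.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if not ref_genes:
        raise ConfigurationError("need at least one reference gene")
    stages = config.design.stages(group)
    rng = np.random.default_rng([config.seed, 3])
    by_id = {rec.transcript_id: rec for rec in truth}
    gene_list = list(genes) if genes is not None else [r.transcript_id for r in truth]
    step = math.log2(config.effect_size)
    rows = []
    for gene in gene_list:
        rec = by_id[gene]
        pattern = rec.trends.get(group, "flat")
        expo = trend_exponents(pattern, len(stages))
        for si, st in enumerate(stages):
            for rep in range(1, n_replicates + 1):
                ct = gene_base_ct - step * expo[si]
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append((gene, st.label, rep, min(ct, max_ct)))
    for ref in ref_genes:
        for st in stages:
            for rep in range(1, n_replicates + 1):
                ct = ref_ct
                if noise_sd > 0:
                    ct += rng.normal(0.0, noise_sd)
                rows.append((ref, st.label, rep, min(ct, max_ct)))
    return pd.DataFrame(rows, columns=["gene", "stage", "replicate", "ct"])


def truth_table(truth: Sequence[TruthRecord], design: StageDesign) -> pd.DataFrame:
    """Tidy truth: one row per transcript with trends and per-library expected
    proportions."""
    libs = [lib for _, _, lib in design.libraries()]
    rows = []
    for rec in truth:
        row = {"transcript_id": rec.transcript_id}
        for g in design.trend_groups():
            row[f"trend_{g}"] = rec.trends.get(g, "flat")
        for lib in libs:
            row[f"prop_{lib}"] = rec.proportions[lib]
        rows.append(row)
    return pd.DataFrame(rows)


def ssr_truth_table(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    rows = [
        (L.sequence_id, L.motif, L.repeat_count, L.start, L.end)
        for rec in truth for L in rec.ssr_loci
    ]
    return pd.DataFrame(
        rows, columns=["transcript_id", "motif", "repeats", "start", "end"])
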