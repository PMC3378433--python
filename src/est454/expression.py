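"""Digital differential expression from cross-library read counts.

The core inference of the pipeline: for each library's most abundant contigs,
count homologous reads from every library (best hit per read at the E-value
cutoff, so no read is counted twice), convert counts to percent-of-library
frequencies, and classify the frequency profile across ordered stages into an
expression pattern: up, down, up_down (rises then falls), down_up, flat, or
complex (two or more sign changes).

The step rule: consecutive stages i -> i+1 are called "up" when
(f[i+1] + p) / (f[i] + p) >= tau, "down" when <= 1/tau, and "flat" otherwise.
``p`` is a small absolute frequency offset (percent) that damps ratios between
near-zero frequencies; the default 0.01% corresponds to one read in a
10,000-read library.  Keeping the offset in frequency space makes trend calls
exactly invariant to rescaling a library's counts and total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import homology
from .types import Read, StageDesign


@dataclass(frozen=True)
class TrendParams:
    top_n: int = 30
    fold_threshold: float = 1.5  # tau: ratio defining an up/down step
    pseudo_freq: float = 0.01  # percent; 1 read per 10,000
    evalue_cutoff: float = 1e-5

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.pseudo_freq < 0:
            raise ValueError("pseudo_freq must be >= 0")


@dataclass(frozen=True)
class TrendCall:
    id: str
    group: str
    values: tuple[float, ...]
    pattern: str


def assign_reads(contigs, reads_by_library: Mapping[str, Sequence[Read]],
                 scoring: homology.ScoringParams | None = None
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count reads homologous to each contig, per library.

    Each read contributes to at most one contig: its best-scoring hit with
    E <= cutoff.  Returns (counts DataFrame indexed by contig id with one
    column per library, per-library read totals).
    """
    if scoring is None:
        # reads are near-identical to their source transcript, so sparse
        # seeding with a two-seed quorum is ample and much faster
        scoring = homology.ScoringParams(seed_stride=4, min_seed_votes=2)
    recs = homology.as_records(contigs)
    if not recs or not reads_by_library:
        raise ValueError("contigs and read libraries must be non-empty")
    index = homology.KmerIndex(recs, scoring.kmer_size)
    contig_ids = [cid for cid, _ in recs]
    libs = sorted(reads_by_library)
    counts = pd.DataFrame(0, index=contig_ids, columns=libs, dtype=int)
    totals = {}
    for lib in libs:
        reads = reads_by_library[lib]
        totals[lib] = len(reads)
        hits = homology.seed_extend_search(reads, recs, scoring, index=index)
        best: dict[str, homology.AlignmentHit] = {}
        for h in hits:
            cur = best.get(h.query_id)
            # higher score wins; exact ties go to the smaller contig id
            if cur is None or h.score > cur.score or (
                    h.score == cur.score and h.subject_id < cur.subject_id):
                best[h.query_id] = h
        for h in best.values():
            counts.at[h.subject_id, lib] += 1
    return counts, totals


def top_abundant(counts: pd.DataFrame, library: str,
                 params: TrendParams | None = None) -> list[str]:
    """The ``top_n`` contigs by read count in ``library`` (count > 0),
    descending, ties broken by contig id."""
    params = params or TrendParams()
    col = counts[library]
    ranked = sorted(col[col > 0].items(), key=lambda kv: (-kv[1], kv[0]))
    return [cid for cid, _ in ranked[: params.top_n]]


def frequency_table(counts: pd.DataFrame,
                    totals: Mapping[str, int]) -> pd.DataFrame:
    """Percent-of-library frequencies: 100 * count / total reads assembled."""
    freqs = counts.astype(float).copy()
    for lib in counts.columns:
        total = totals[lib]
        if total <= 0:
            raise ValueError(f"library {lib!r} has zero total reads")
        freqs[lib] = 100.0 * counts[lib] / total
    return freqs


def classify_steps(values: Sequence[float], tau: float, pseudo: float) -> list[int]:
    """Sign (+1/0/-1) of each consecutive step under the tau-band rule."""
    steps = []
    for f0, f1 in zip(values, values[1:]):
        a, b = f0 + pseudo, f1 + pseudo
        if a == 0 and b == 0:
            steps.append(0)
        elif a == 0:
            steps.append(1)
        elif b / a >= tau:
            steps.append(1)
        elif b / a <= 1.0 / tau:
            steps.append(-1)
        else:
            steps.append(0)
    return steps


def classify_trend(values: Sequence[float],
                   params: TrendParams | None = None,
                   id: str = "", group: str = "") -> TrendCall:
    """Collapse the step signs of an ordered profile into a pattern label.

    Flat steps are absorbed; a monotone non-mixed profile is up or down, one
    sign change gives up_down or down_up, all-flat gives flat, and two or more
    sign changes give complex.  Requires at least two values.
    """
    if len(values) < 2:
        raise ValueError("need >= 2 ordered values to classify a trend")
    params = params or TrendParams()
    steps = classify_steps(values, params.fold_threshold, params.pseudo_freq)
    runs: list[int] = []
    for s in steps:
        if s != 0 and (not runs or runs[-1] != s):
            runs.append(s)
    if not runs:
        pattern = "flat"
    elif runs == [1]:
        pattern = "up"
    elif runs == [-1]:
        pattern = "down"
    elif runs == [1, -1]:
        pattern = "up_down"
    elif runs == [-1, 1]:
        pattern = "down_up"
    else:
        pattern = "complex"
    return TrendCall(id=id, group=group, values=tuple(float(v) for v in values),
                     pattern=pattern)


def abundance_report(counts: pd.DataFrame, freqs: pd.DataFrame,
                     design: StageDesign,
                     params: TrendParams | None = None) -> pd.DataFrame:
    """One row per (source library, top-abundant contig): per-library counts,
    frequencies, and the trend pattern in every multi-stage organ group."""
    params = params or TrendParams()
    libs = list(counts.columns)
    ordered_libs = [lib for lib in design.library_ids() if lib in libs]
    rows = []
    for src in ordered_libs:
        for cid in top_abundant(counts, src, params):
            row: dict = {"source_library": src, "contig_id": cid}
            for lib in ordered_libs:
                row[f"count_{lib}"] = int(counts.at[cid, lib])
            for lib in ordered_libs:
                row[f"freq_{lib}"] = round(float(freqs.at[cid, lib]), 4)
            for group in design.trend_groups():
                glibs = [l for l in design.library_ids(group) if l in libs]
                if len(glibs) >= 2:
                    call = classify_trend(
                        [float(freqs.at[cid, l]) for l in glibs],
                        params, id=cid, group=group)
                    row[f"pattern_{group}"] = call.pattern
            rows.append(row)
    return pd.DataFrame(rows)


def trend_calls(freqs: pd.DataFrame, design: StageDesign, group: str,
                params: TrendParams | None = None,
                ids: Sequence[str] | None = None) -> dict[str, TrendCall]:
    """Classify the ``group`` profile of each contig (or of ``ids`` only)."""
    params = params or TrendParams()
    glibs = [l for l in design.library_ids(group) if l in freqs.columns]
    if len(glibs) < 2:
        raise ValueError(f"group {group!r} has fewer than two libraries")
    which = ids if ids is not None else list(freqs.index)
    return {
        cid: classify_trend([float(freqs.at[cid, l]) for l in glibs],
                            params, id=cid, group=group)
        for cid in which
    }
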