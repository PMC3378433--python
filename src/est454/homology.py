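"""Self-contained nucleotide local-alignment search with E-values.

Used wherever the pipeline needs sequence homology: assigning reads to contigs
across libraries and comparing unigene sets between assemblies.  The engine is
a classic seed-and-extend design: an 11-mer index over both strands of the
subjects, ungapped X-drop extension from seeds as a prescreen, then gapped
refinement restricted to a window around the seeded diagonal.  Significance is
the ungapped Karlin-Altschul E-value E = K*m*n*exp(-lambda*S) applied to the
(possibly gapped) score — the standard approximation.  Only the best hit per
(query, subject) pair is kept so downstream read counting never double-counts.

`sw_align_oracle` computes the exact optimal local alignment by full dynamic
programming (via Biopython's PairwiseAligner) and serves as the independent
reference the heuristic is checked against: a seed-and-extend score can never
exceed it, and equals it whenever an exact shared k-mer lies on the optimal
alignment path and the band window covers that path.

Gap convention: a gap of length L costs gap_open + (L - 1) * gap_extend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .types import revcomp


@dataclass(frozen=True)
class ScoringParams:
    """BLASTN-like scoring and search parameters."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    kmer_size: int = 11
    evalue_cutoff: float = 1e-5
    karlin_k: float = 0.621
    karlin_lambda: float = 1.33
    seed_stride: int = 1  # query k-mer sampling stride
    min_seed_votes: int = 1  # seeds on one diagonal band needed to evaluate
    window_pad: int = 24  # slack around the seeded region for refinement
    xdrop: float = 12.0

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    query_span: tuple[int, int]  # on the original (plus-strand) query
    subject_span: tuple[int, int]
    strand: str  # '+' or '-'


def _aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.match_score = scoring.match
    aln.mismatch_score = scoring.mismatch
    aln.open_gap_score = scoring.gap_open
    aln.extend_gap_score = scoring.gap_extend
    return aln


def sw_align_oracle(a: str, b: str, scoring: ScoringParams | None = None
                    ) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Exact optimal local alignment of ``a`` vs ``b`` by full dynamic
    programming.  Returns (score, span on a, span on b); score 0 with empty
    spans when no positive-scoring alignment exists.

    Intended as a reference at modest scale (sequences <= ~2,000 nt).
    """
    scoring = scoring or ScoringParams()
    if min(len(a), len(b)) == 0:
        return 0.0, (0, 0), (0, 0)
    if max(len(a), len(b)) > 2000:
        raise ValueError("oracle is meant for sequences <= 2000 nt")
    aligner = _aligner(scoring)
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, (0, 0), (0, 0)
    aln = aligner.align(a, b)[0]
    ablocks, bblocks = aln.aligned
    aspan = (int(ablocks[0][0]), int(ablocks[-1][1]))
    bspan = (int(bblocks[0][0]), int(bblocks[-1][1]))
    return float(score), aspan, bspan


def evalue(score: float, query_len: int, total_subject_len: int,
           scoring: ScoringParams | None = None) -> float:
    """Karlin-Altschul expected number of chance alignments of >= ``score``
    in an m x n search space: E = K * m * n * exp(-lambda * S)."""
    scoring = scoring or ScoringParams()
    if query_len <= 0 or total_subject_len <= 0:
        raise ValueError("lengths must be positive")
    return (scoring.karlin_k * query_len * total_subject_len
            * math.exp(-scoring.karlin_lambda * score))


def _ungapped_extend(q: str, s: str, qpos: int, spos: int, k: int,
                     match: float, mismatch: float, xdrop: float) -> float:
    """Score of an ungapped X-drop extension around an exact k-mer seed."""
    score = best = k * match
    i, j = qpos + k, spos + k
    while i < len(q) and j < len(s):
        score += match if q[i] == s[j] else mismatch
        if score > best:
            best = score
        elif best - score > xdrop:
            break
        i += 1
        j += 1
    score = best
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        score += match if q[i] == s[j] else mismatch
        if score > best:
            best = score
        elif best - score > xdrop:
            break
        i -= 1
        j -= 1
    return best


class KmerIndex:
    """Exact k-mer positional index over a set of subject sequences."""

    def __init__(self, subjects: Sequence[tuple[str, str]], k: int):
        self.k = k
        self.subjects = subjects
        self.total_len = sum(len(s) for _, s in subjects)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for sidx, (_, seq) in enumerate(subjects):
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos:pos + k], []).append((sidx, pos))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.index.get(kmer, [])


def as_records(sequences) -> list[tuple[str, str]]:
    """Normalise dicts / Read-like / Contig-like inputs to (id, seq) pairs."""
    if isinstance(sequences, Mapping):
        return [(k, v) for k, v in sequences.items()]
    out = []
    for rec in sequences:
        if isinstance(rec, tuple):
            out.append(rec)
            continue
        seq = getattr(rec, "sequence", None)
        if seq is None:
            seq = rec.consensus
        out.append((rec.id, seq))
    return out


def seed_extend_search(queries, subjects,
                       scoring: ScoringParams | None = None,
                       index: KmerIndex | None = None) -> list[AlignmentHit]:
    """Search every query against every subject; report the best hit per
    (query, subject) pair with E-value <= ``evalue_cutoff``.

    Both query strands are searched; a minus-strand hit means the reverse
    complement of the query aligned to the subject, and its query span is
    reported in original query coordinates.
    """
    scoring = scoring or ScoringParams()
    subj = as_records(subjects)
    if not subj:
        return []
    idx = index if index is not None else KmerIndex(subj, scoring.kmer_size)
    aligner = _aligner(scoring)
    hits: list[AlignmentHit] = []
    for qid, qseq in as_records(queries):
        best: dict[int, AlignmentHit] = {}
        for strand in ("+", "-"):
            q = qseq if strand == "+" else revcomp(qseq)
            cands = _collect_candidates(q, idx, scoring)
            for (sidx, dlo, dhi, seed) in cands:
                sid, sseq = subj[sidx]
                qpos, spos = seed
                pre = _ungapped_extend(q, sseq, qpos, spos, scoring.kmer_size,
                                       scoring.match, scoring.mismatch,
                                       scoring.xdrop)
                if pre < scoring.kmer_size * scoring.match + 3:
                    continue  # bare chance seed; cannot reach significance
                ws = max(0, dlo - scoring.window_pad)
                we = min(len(sseq), dhi + len(q) + scoring.window_pad)
                window = sseq[ws:we]
                score = aligner.score(window, q)
                if score <= 0:
                    continue
                ev = evalue(score, len(qseq), 2 * idx.total_len, scoring)
                if ev > scoring.evalue_cutoff:
                    continue
                aln = aligner.align(window, q)[0]
                tblocks, qblocks = aln.aligned
                sspan = (ws + int(tblocks[0][0]), ws + int(tblocks[-1][1]))
                qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
                if strand == "-":
                    qs, qe = len(qseq) - qe, len(qseq) - qs
                cur = best.get(sidx)
                if cur is None or score > cur.score:
                    best[sidx] = AlignmentHit(
                        query_id=qid, subject_id=sid, score=float(score),
                        evalue=ev, query_span=(qs, qe), subject_span=sspan,
                        strand=strand,
                    )
        hits.extend(best[sidx] for sidx in sorted(best))
    return hits


def _collect_candidates(q: str, idx: KmerIndex, scoring: ScoringParams):
    """Group seed matches by (subject, diagonal band); return one entry per
    band: (subject index, min diag, max diag, representative seed)."""
    k = idx.k
    band = 8
    groups: dict[tuple[int, int], list] = {}
    for qpos in range(0, len(q) - k + 1, scoring.seed_stride):
        for sidx, spos in idx.lookup(q[qpos:qpos + k]):
            d = spos - qpos
            key = (sidx, d // band)
            groups.setdefault(key, []).append((d, qpos, spos))
    out = []
    merged: dict[int, list] = {}
    for (sidx, _), seeds in groups.items():
        merged.setdefault(sidx, []).append(seeds)
    for sidx, seedgroups in merged.items():
        for seeds in seedgroups:
            if len(seeds) < scoring.min_seed_votes:
                continue
            diags = [d for d, _, _ in seeds]
            d0, q0, s0 = max(seeds, key=lambda t: t[1])  # a representative
            out.append((sidx, min(diags), max(diags), (q0, s0)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def hits_table(hits: Iterable[AlignmentHit]):
    import pandas as pd

    return pd.DataFrame(
        [
            (h.query_id, h.subject_id, h.score, h.evalue,
             h.query_span[0], h.query_span[1],
             h.subject_span[0], h.subject_span[1], h.strand)
            for h in hits
        ],
        columns=["query", "subject", "score", "evalue", "q_start", "q_end",
                 "s_start", "s_end", "strand"],
    )
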