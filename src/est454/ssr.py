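"""EST-SSR microsatellite mining, motif classing, and marker-screen summaries.

A simple sequence repeat (SSR) here is a maximal perfect tandem repeat of a
primitive 2-5 nt motif.  Mining thresholds follow common EST-SSR practice for
454 unigene sets: dinucleotide motifs need >= 5 repeat units, trinucleotide
>= 4, tetra- and pentanucleotide >= 3, and sequences shorter than 120 nt are
excluded from mining.  Motifs are grouped into canonical classes under cyclic
rotation and reverse complementation (AG, GA, TC and CT are one class), which
is how EST-SSR surveys tabulate motif composition.

Primer-candidate filtering keeps loci on sequences with whole-sequence GC
between 40 and 60% and at least 20 nt of flanking sequence on each side of the
repeat.  Marker screens record, per primer pair, which accessions amplified
and whether products were polymorphic; the summary reports the amplification
rate (amplified in at least one accession) and polymorphism rate in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import gc_percent, revcomp

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SSRParams:
    """Mining thresholds.

    min_repeats maps motif length (2-5) to the minimum number of perfect
    repeat units; min_seq_length is the mining length filter in nt; gc_range
    (percent) and min_flank (nt) are the primer-candidate criteria.
    """

    min_seq_length: int = 120
    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: {2: 5, 3: 4, 4: 3, 5: 3}
    )
    gc_range: tuple[float, float] = (40.0, 60.0)
    min_flank: int = 20

    def __post_init__(self) -> None:
        if any(m not in (2, 3, 4, 5) for m in self.min_repeats):
            raise ValueError("motif lengths must be 2-5")
        if any(r < 2 for r in self.min_repeats.values()):
            raise ValueError("min_repeats must be >= 2")


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem repeat.  Coordinates are 0-based half-open;
    end - start == motif_length * repeat_count always holds."""

    sequence_id: str
    motif: str
    repeat_count: int
    start: int
    end: int

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def canonical(self) -> str:
        return canonical_class(self.motif)


@dataclass(frozen=True)
class PrimerCandidate:
    locus: SSRLocus
    gc: float
    left_flank: int
    right_flank: int
    passed: bool
    failure_reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class MarkerScreenRecord:
    """One screened primer pair: per-accession amplification flags and the
    overall polymorphism call."""

    primer_id: str
    amplified: Mapping[str, bool]
    call: str  # no_product | monomorphic | polymorphic

    def __post_init__(self) -> None:
        if self.call not in ("no_product", "monomorphic", "polymorphic"):
            raise ValueError(f"unknown call {self.call!r}")
        if self.call != "no_product" and not any(self.amplified.values()):
            raise ValueError(
                f"{self.primer_id}: {self.call} requires amplification somewhere"
            )

    @property
    def amplified_anywhere(self) -> bool:
        return any(self.amplified.values())


def is_primitive(motif: str) -> bool:
    """True if ``motif`` is not a whole-number repetition of a shorter unit."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Canonical representative of a motif: the lexicographically smallest
    string over all cyclic rotations of the motif and of its reverse
    complement.  Raises ValueError for non-primitive motifs."""
    motif = motif.upper()
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    variants = []
    for m in (motif, revcomp(motif)):
        variants.extend(m[i:] + m[:i] for i in range(len(m)))
    return min(variants)


def find_ssrs(sequence: str, params: SSRParams | None = None,
              sequence_id: str = "") -> list[SSRLocus]:
    """All maximal perfect tandem repeats of primitive 2-5 nt motifs meeting
    the repeat-count thresholds.

    Each physical run is reported once, under its primitive motif (a (AT)n run
    is never additionally reported as (ATAT)m).  Runs of different motif
    classes may overlap and are all reported.  Non-ACGT characters never match
    and therefore break runs.
    """
    params = params or SSRParams()
    s = sequence.upper()
    n = len(s)
    loci: list[SSRLocus] = []
    for m, min_rep in sorted(params.min_repeats.items()):
        if n < m * min_rep:
            continue
        i = m
        while i < n:
            if s[i] == s[i - m] and s[i] in _ACGT:
                a = i  # start of a run of period-m matches
                while i < n and s[i] in _ACGT and s[i] == s[i - m]:
                    i += 1
                total = i - (a - m)  # full repeated span, incl. partial unit
                count = total // m
                start = a - m
                motif = s[start:start + m]
                if count >= min_rep and is_primitive(motif):
                    loci.append(
                        SSRLocus(
                            sequence_id=sequence_id,
                            motif=motif,
                            repeat_count=count,
                            start=start,
                            end=start + m * count,
                        )
                    )
            else:
                i += 1
    loci.sort(key=lambda L: (L.start, L.motif_length))
    return loci


def mine_ssrs(sequences: Mapping[str, str] | Iterable,
              params: SSRParams | None = None) -> tuple[list[SSRLocus], int]:
    """Mine a unigene set; sequences shorter than ``min_seq_length`` are
    skipped.  Returns (loci, number of sequences mined)."""
    params = params or SSRParams()
    items = _as_items(sequences)
    loci: list[SSRLocus] = []
    n_mined = 0
    for sid, seq in items:
        if len(seq) < params.min_seq_length:
            continue
        n_mined += 1
        loci.extend(find_ssrs(seq, params, sequence_id=sid))
    return loci, n_mined


def summarize_ssrs(loci: Sequence[SSRLocus], n_sequences: int) -> pd.DataFrame:
    """Motif-composition summary over mined loci.

    One row per motif-length category (DNR, TNR, TetraNR, PentaNR) and one per
    canonical class within each category.  ``percent_of_category`` is the share
    within the total SSR count (for categories) or within the category (for
    classes); ``percent_of_total`` is the category count over the number of
    mined sequences (for categories) or the class count over all SSRs (for
    classes).  Percentages are rounded to one decimal.
    """
    cat_names = {2: "DNR", 3: "TNR", 4: "TetraNR", 5: "PentaNR"}
    total = len(loci)
    rows = []
    for m in (2, 3, 4, 5):
        cat = [L for L in loci if L.motif_length == m]
        pct_cat = round(100.0 * len(cat) / total, 1) if total else 0.0
        pct_tot = round(100.0 * len(cat) / n_sequences, 1) if n_sequences else 0.0
        rows.append(("category", cat_names[m], len(cat), pct_cat, pct_tot))
        classes: dict[str, int] = {}
        for L in cat:
            classes[L.canonical] = classes.get(L.canonical, 0) + 1
        for cls in sorted(classes):
            cnt = classes[cls]
            pc = round(100.0 * cnt / len(cat), 1) if cat else 0.0
            pt = round(100.0 * cnt / total, 1) if total else 0.0
            rows.append((cat_names[m], cls, cnt, pc, pt))
    rows.append(("category", "Total", total, None,
                 round(100.0 * total / n_sequences, 1) if n_sequences else 0.0))
    return pd.DataFrame(
        rows,
        columns=["level", "name", "count", "percent_of_category",
                 "percent_of_total"],
    )


def summarize_counts(category_counts: Mapping[str, int],
                     class_counts: Mapping[str, Mapping[str, int]] | None = None,
                     n_sequences: int | None = None) -> pd.DataFrame:
    """Motif-composition summary from pre-tabulated counts (same shape as
    :func:`summarize_ssrs`, for when only the tallies are available).

    ``category_counts`` maps category name (DNR/TNR/TetraNR/PentaNR) to SSR
    count; ``class_counts`` optionally maps a category name to its canonical
    class counts.  Percentages are rounded to one decimal.
    """
    total = sum(category_counts.values())
    rows = []
    for cat, cnt in category_counts.items():
        pct_cat = round(100.0 * cnt / total, 1) if total else 0.0
        pct_tot = (round(100.0 * cnt / n_sequences, 1)
                   if n_sequences else None)
        rows.append(("category", cat, cnt, pct_cat, pct_tot))
        for cls, ccnt in (class_counts or {}).get(cat, {}).items():
            pc = round(100.0 * ccnt / cnt, 1) if cnt else 0.0
            pt = round(100.0 * ccnt / total, 1) if total else 0.0
            rows.append((cat, cls, ccnt, pc, pt))
    rows.append(("category", "Total", total, None,
                 round(100.0 * total / n_sequences, 1) if n_sequences else None))
    return pd.DataFrame(
        rows,
        columns=["level", "name", "count", "percent_of_category",
                 "percent_of_total"],
    )


def primer_candidates(loci: Sequence[SSRLocus],
                      sequences: Mapping[str, str],
                      params: SSRParams | None = None) -> list[PrimerCandidate]:
    """Flag loci suitable for primer design: whole-sequence GC inside
    ``gc_range`` (inclusive) and both flanks >= ``min_flank`` nt."""
    params = params or SSRParams()
    lo, hi = params.gc_range
    out = []
    for L in loci:
        seq = sequences[L.sequence_id]
        gc = gc_percent(seq)
        left = L.start
        right = len(seq) - L.end
        reasons = []
        if not (lo <= gc <= hi):
            reasons.append(f"gc {gc:.1f}% outside {lo:g}-{hi:g}%")
        if left < params.min_flank:
            reasons.append(f"left flank {left} < {params.min_flank}")
        if right < params.min_flank:
            reasons.append(f"right flank {right} < {params.min_flank}")
        out.append(
            PrimerCandidate(
                locus=L, gc=gc, left_flank=left, right_flank=right,
                passed=not reasons, failure_reasons=tuple(reasons),
            )
        )
    return out


def marker_screen_summary(records: Sequence[MarkerScreenRecord]) -> dict:
    """Amplification and polymorphism rates (integer percent) plus counts.

    Amplification rate: share of primer pairs producing a product in at least
    one accession.  Polymorphism rate: share called polymorphic.
    """
    if not records:
        raise ValueError("no marker screen records")
    n = len(records)
    n_amp = sum(r.amplified_anywhere for r in records)
    n_poly = sum(r.call == "polymorphic" for r in records)
    n_mono = sum(r.call == "monomorphic" for r in records)
    return {
        "n_primers": n,
        "n_amplified": n_amp,
        "n_monomorphic": n_mono,
        "n_polymorphic": n_poly,
        "amplification_rate_percent": round(100.0 * n_amp / n),
        "polymorphism_rate_percent": round(100.0 * n_poly / n),
    }


def loci_table(loci: Sequence[SSRLocus]) -> pd.DataFrame:
    """Tidy table of loci (0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            (L.sequence_id, L.motif, L.canonical, L.repeat_count, L.start, L.end)
            for L in loci
        ],
        columns=["sequence_id", "motif", "class", "repeats", "start", "end"],
    )


def _as_items(sequences) -> list[tuple[str, str]]:
    if isinstance(sequences, Mapping):
        return list(sequences.items())
    items = []
    for rec in sequences:
        seq = getattr(rec, "sequence", None)
        if seq is None:
            seq = rec.consensus
        items.append((rec.id, seq))
    return items
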