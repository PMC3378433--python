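"""Greedy overlap-consensus EST assembly with per-library read tracking.

Reads are merged best-overlap-first: all candidate end overlaps (both strands,
containments included) are found by k-mer seeding, scored as the number of
matching bases in the overlap, and merged highest score first until no overlap
of length >= ``min_overlap`` at identity >= ``min_identity`` remains.  The
consensus is a per-column majority vote with ties broken in favour of the
first-merged base.  Units that absorbed at least two reads are contigs; reads
that never merged remain singletons.  Together they are the unigene set.

Determinism: reads are processed in sorted-id order and ties between equal
overlaps are broken by longer overlap, then the lexicographically smaller pair
of unit names, so the result does not depend on input file order.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import Read, revcomp
from . import homology

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class AssemblyParams:
    min_overlap: int = 30
    min_identity: float = 0.95
    kmer_size: int = 16

    def __post_init__(self) -> None:
        if self.min_overlap < self.kmer_size:
            raise ValueError("min_overlap must be >= kmer_size")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class Contig:
    """Consensus of >= 2 reads, with membership and per-library counts."""

    id: str
    consensus: str
    members: list[tuple[str, str]]  # (read_id, orientation '+'/'-')
    library_counts: dict[str, int]

    @property
    def n_reads(self) -> int:
        return len(self.members)


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    singletons: list[Read]
    library_totals: dict[str, int]  # reads assembled per library
    read_library: dict[str, str] = field(default_factory=dict)

    @property
    def n_unigenes(self) -> int:
        return len(self.contigs) + len(self.singletons)


class _Unit:
    __slots__ = ("uid", "name", "seq", "cols", "members")

    def __init__(self, uid: int, name: str, seq: str,
                 members: list[tuple[str, str]],
                 cols: Optional[list[dict[str, int]]] = None):
        self.uid = uid
        self.name = name
        self.seq = seq
        self.cols = cols  # per-column base counts; built lazily on merge
        self.members = members

    def columns(self) -> list[dict[str, int]]:
        if self.cols is None:
            self.cols = [{b: 1} for b in self.seq]
        return self.cols

    def flipped(self, uid: int, name: str) -> "_Unit":
        """Reverse-complemented copy (members' orientations toggled)."""
        cols = None
        if self.cols is not None:
            cols = [
                {_COMP.get(b, "N"): c for b, c in col.items()}
                for col in reversed(self.cols)
            ]
        members = [(rid, "-" if o == "+" else "+") for rid, o in self.members]
        return _Unit(uid, name, revcomp(self.seq), members, cols)


def _consensus_base(col: dict[str, int]) -> str:
    # max count; ties go to the earliest-inserted (first-merged) base
    best_b, best_c = None, -1
    for b, c in col.items():
        if c > best_c:
            best_b, best_c = b, c
    return best_b


def _merge_columns(left: _Unit, right: _Unit, offset: int) -> list[dict[str, int]]:
    lcols = left.columns()
    rcols = right.columns()
    out = [dict(c) for c in lcols[:offset]]
    ov = min(len(lcols) - offset, len(rcols))
    for i in range(ov):
        col = dict(lcols[offset + i])
        for b, c in rcols[i].items():
            col[b] = col.get(b, 0) + c
        out.append(col)
    if len(rcols) > ov:
        out.extend(dict(c) for c in rcols[ov:])
    else:
        out.extend(dict(c) for c in lcols[offset + ov:])
    return out


def _overlap_metrics(xseq: str, yseq: str, diag: int, min_overlap: int,
                     min_identity: float):
    """Evaluate the implied end-overlap of y placed at ``diag`` along x.

    Returns (score, overlap_len) or None if below thresholds.  Score is the
    number of matching bases in the overlap.
    """
    sx = max(0, diag)
    ex = min(len(xseq), diag + len(yseq))
    L = ex - sx
    if L < min_overlap:
        return None
    a = xseq[sx:ex]
    b = yseq[sx - diag:ex - diag]
    if a == b:
        mm = 0
    else:
        mm = sum(1 for c1, c2 in zip(a, b) if c1 != c2)
    if L - mm < min_identity * L:
        return None
    return (L - mm, L)


class _GreedyAssembler:
    """Incremental index + heap machinery behind :func:`assemble_greedy`."""

    MAX_BUCKET = 1000

    def __init__(self, reads: Sequence[Read], params: AssemblyParams):
        self.params = params
        self.k = params.kmer_size
        # number of leading k-mer positions indexed as "prefix" seeds: enough
        # to catch any error-free overlap of exactly min_overlap
        self.prefix_window = params.min_overlap - self.k + 1
        self.units: dict[int, _Unit] = {}
        self.full_index: dict[str, list[tuple[int, int]]] = {}
        self.prefix_index: dict[str, list[tuple[int, int, str]]] = {}
        self.heap: list = []
        self.evaluated: set = set()
        self.next_uid = 0
        self.n_contig = 0
        self.read_library: dict[str, str] = {}
        for rd in sorted(reads, key=lambda r: r.id):
            self.read_library[rd.id] = rd.library_id
            unit = _Unit(self.next_uid, rd.id, rd.sequence, [(rd.id, "+")])
            self.next_uid += 1
            self.units[unit.uid] = unit
            self._find_candidates(unit)
            self._insert(unit)

    # -- indexing ---------------------------------------------------------
    def _insert(self, unit: _Unit) -> None:
        """Index the unit's k-mers (the unit is already registered)."""
        seq = unit.seq
        k = self.k
        for pos in range(len(seq) - k + 1):
            self.full_index.setdefault(seq[pos:pos + k], []).append((unit.uid, pos))
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for pos in range(min(self.prefix_window, len(s) - k + 1)):
                self.prefix_index.setdefault(s[pos:pos + k], []).append(
                    (unit.uid, pos, strand))

    def _find_candidates(self, unit: _Unit) -> None:
        """Push scored overlaps between ``unit`` and all live units."""
        k = self.k
        seen: set[tuple[int, int, str, int]] = set()
        # (a) unit's prefix (either strand) lies inside another unit:
        #     other is left, unit is right
        for strand, s in (("+", unit.seq), ("-", revcomp(unit.seq))):
            for p in range(min(self.prefix_window, len(s) - k + 1)):
                bucket = self.full_index.get(s[p:p + k], ())
                if len(bucket) > self.MAX_BUCKET:
                    continue
                for vid, q in bucket:
                    if vid in self.units and vid != unit.uid:
                        seen.add((vid, unit.uid, strand, q - p))
        # (b) another unit's prefix lies inside this unit: unit is left
        seq = unit.seq
        for q in range(len(seq) - k + 1):
            bucket = self.prefix_index.get(seq[q:q + k], ())
            if len(bucket) > self.MAX_BUCKET:
                continue
            for vid, p, strand in bucket:
                if vid in self.units and vid != unit.uid:
                    seen.add((unit.uid, vid, strand, q - p))
        for key in sorted(seen, key=self._cand_sort_key):
            self._evaluate(key)

    def _cand_sort_key(self, key):
        xid, yid, strand, diag = key
        return (self.units[xid].name, self.units[yid].name, strand, diag)

    def _evaluate(self, key) -> None:
        if key in self.evaluated:
            return
        self.evaluated.add(key)
        xid, yid, strand, diag = key
        x, y = self.units[xid], self.units[yid]
        yseq = y.seq if strand == "+" else revcomp(y.seq)
        m = _overlap_metrics(x.seq, yseq, diag, self.params.min_overlap,
                             self.params.min_identity)
        if m is None:
            return
        score, length = m
        pair = tuple(sorted((x.name, y.name)))
        heapq.heappush(self.heap, (-score, -length, pair, strand, diag,
                                   xid, yid))

    # -- merging ----------------------------------------------------------
    def _merge(self, xid: int, yid: int, strand: str, diag: int) -> None:
        x = self.units.pop(xid)
        y = self.units.pop(yid)
        name = f"contig{self.n_contig:06d}"
        self.n_contig += 1
        uid = self.next_uid
        self.next_uid += 1
        yor = y.flipped(y.uid, y.name) if strand == "-" else y
        if diag >= 0:
            left, right, off = x, yor, diag
        else:
            left, right, off = yor, x, -diag
        cols = _merge_columns(left, right, off)
        seq = "".join(_consensus_base(c) for c in cols)
        merged = _Unit(uid, name, seq, left.members + right.members, cols)
        self.units[merged.uid] = merged
        self._find_candidates(merged)
        self._insert(merged)

    def run(self) -> tuple[list[_Unit], list[_Unit]]:
        while self.heap:
            negs, negl, pair, strand, diag, xid, yid = heapq.heappop(self.heap)
            if xid not in self.units or yid not in self.units:
                continue  # stale entry
            self._merge(xid, yid, strand, diag)
        merged, single = [], []
        for uid in sorted(self.units):
            u = self.units[uid]
            (merged if len(u.members) > 1 else single).append(u)
        return merged, single


def assemble_greedy(reads: Sequence[Read],
                    params: AssemblyParams | None = None) -> AssemblyResult:
    """Assemble reads into contigs and singletons.

    Every input read ends up in exactly one contig or as exactly one
    singleton (read conservation).
    """
    params = params or AssemblyParams()
    reads = list(reads)
    asm = _GreedyAssembler(reads, params)
    merged_units, single_units = asm.run()
    by_id = {r.id: r for r in reads}
    contigs = []
    for i, u in enumerate(sorted(merged_units, key=lambda u: u.name)):
        lib_counts: dict[str, int] = {}
        for rid, _ in u.members:
            lib = asm.read_library[rid]
            lib_counts[lib] = lib_counts.get(lib, 0) + 1
        contigs.append(
            Contig(
                id=f"contig_{i:05d}",
                consensus=u.seq,
                members=sorted(u.members),
                library_counts=dict(sorted(lib_counts.items())),
            )
        )
    singletons = sorted((by_id[u.members[0][0]] for u in single_units),
                        key=lambda r: r.id)
    lib_totals: dict[str, int] = {}
    for r in reads:
        lib_totals[r.library_id] = lib_totals.get(r.library_id, 0) + 1
    return AssemblyResult(
        contigs=contigs,
        singletons=singletons,
        library_totals=dict(sorted(lib_totals.items())),
        read_library=dict(asm.read_library),
    )


def assembly_summary(result: AssemblyResult) -> pd.DataFrame:
    """Per-library and overall summary: reads assembled, reads in contigs,
    contig/singleton counts and mean lengths (unigene totals included)."""
    libs = sorted(result.library_totals)
    rows = []

    def _row(name, reads_assembled, reads_in_contigs, n_contigs, n_single,
             contig_lens, single_lens):
        rows.append(
            {
                "sample": name,
                "reads_assembled": reads_assembled,
                "reads_in_contigs": reads_in_contigs,
                "n_contigs": n_contigs,
                "n_singletons": n_single,
                "n_unigenes": n_contigs + n_single,
                "mean_contig_length": round(
                    sum(contig_lens) / len(contig_lens), 1) if contig_lens else 0.0,
                "mean_singleton_length": round(
                    sum(single_lens) / len(single_lens), 1) if single_lens else 0.0,
            }
        )

    for lib in libs:
        lib_contigs = [c for c in result.contigs if lib in c.library_counts]
        lib_single = [s for s in result.singletons if s.library_id == lib]
        _row(
            lib,
            result.library_totals[lib],
            sum(c.library_counts[lib] for c in lib_contigs),
            len(lib_contigs),
            len(lib_single),
            [len(c.consensus) for c in lib_contigs],
            [len(s.sequence) for s in lib_single],
        )
    _row(
        "all",
        sum(result.library_totals.values()),
        sum(c.n_reads for c in result.contigs),
        len(result.contigs),
        len(result.singletons),
        [len(c.consensus) for c in result.contigs],
        [len(s.sequence) for s in result.singletons],
    )
    return pd.DataFrame(rows)


def unigene_sequences(result: AssemblyResult) -> dict[str, str]:
    """Contig consensus plus singleton sequences, keyed by id."""
    out = {c.id: c.consensus for c in result.contigs}
    for s in result.singletons:
        out[s.id] = s.sequence
    return out


@dataclass
class SetComparison:
    shared: int
    unique_to_a: int
    unique_to_b: int
    shared_in_a: int
    shared_in_b: int


def compare_unigene_sets(set_a, set_b,
                         scoring: homology.ScoringParams | None = None
                         ) -> SetComparison:
    """Count unigenes shared between two sets by cross-set homology.

    A unigene is shared if it has a local-alignment hit (E <= cutoff) in the
    other set.  The two directions can disagree in size (a long contig can
    absorb several short unigenes), so the headline ``shared`` is the larger
    of the two per-side counts; both per-side counts are returned.
    """
    scoring = scoring or homology.ScoringParams()
    a = homology.as_records(set_a)
    b = homology.as_records(set_b)
    if not a or not b:
        raise ValueError("both unigene sets must be non-empty")
    hits_ab = homology.seed_extend_search(a, b, scoring)
    hits_ba = homology.seed_extend_search(b, a, scoring)
    # union of cross-hits from both search directions
    shared_a = {h.query_id for h in hits_ab} | {h.subject_id for h in hits_ba}
    shared_b = {h.query_id for h in hits_ba} | {h.subject_id for h in hits_ab}
    return SetComparison(
        shared=max(len(shared_a), len(shared_b)),
        unique_to_a=len(a) - len(shared_a),
        unique_to_b=len(b) - len(shared_b),
        shared_in_a=len(shared_a),
        shared_in_b=len(shared_b),
    )


def membership_table(result: AssemblyResult) -> pd.DataFrame:
    lib = result.read_library
    rows = [
        (rid, c.id, lib.get(rid, ""), orient)
        for c in result.contigs
        for rid, orient in c.members
    ]
    rows.extend((s.id, s.id, s.library_id, "+") for s in result.singletons)
    return pd.DataFrame(
        rows, columns=["read_id", "unigene_id", "library_id", "orientation"])
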