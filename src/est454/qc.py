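"""Pre-assembly read QC: adapter masking and minimum-length filtering.

Adapter (PCR primer) matching is exact-substring and end-anchored: a read
prefix equal to an adapter suffix (or a read suffix equal to an adapter
prefix) over at least ``min_adapter_match`` bases is trimmed off, the longest
such match first.  Internal sequence is never altered, and a read is never
lengthened.  After masking, reads shorter than ``min_length`` (50 nt by
default) are removed.

An optional mean-quality threshold stands in for platform-internal quality
filtering; it is disabled by default and a no-op for reads without qualities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .types import Read


@dataclass(frozen=True)
class QCParams:
    min_length: int = 50
    adapters: tuple[str, ...] = ()
    min_adapter_match: int = 10
    min_mean_quality: Optional[float] = None  # disabled by default

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_adapter_match < 1:
            raise ValueError("min_adapter_match must be >= 1")


def _trim_one(seq: str, adapter: str, min_match: int) -> str:
    n = min(len(seq), len(adapter))
    # longest read prefix that equals an adapter suffix
    for L in range(n, min_match - 1, -1):
        if seq[:L] == adapter[-L:]:
            seq = seq[L:]
            break
    n = min(len(seq), len(adapter))
    # longest read suffix that equals an adapter prefix
    for L in range(n, min_match - 1, -1):
        if seq[-L:] == adapter[:L]:
            seq = seq[:-L]
            break
    return seq


def mask_adapters(reads: Sequence[Read], params: QCParams) -> list[Read]:
    """Return new reads with adapter-matching ends trimmed; inputs untouched."""
    out = []
    for r in reads:
        seq = r.sequence
        for adapter in params.adapters:
            if len(adapter) >= params.min_adapter_match:
                seq = _trim_one(seq, adapter.upper(), params.min_adapter_match)
        qual = r.quality
        if qual is not None and len(seq) != len(r.sequence):
            # end-trimming only, so the kept bases are a contiguous slice
            start = r.sequence.find(seq) if seq else 0
            qual = qual[start:start + len(seq)]
        out.append(Read(id=r.id, sequence=seq, library_id=r.library_id,
                        quality=qual, meta=dict(r.meta)))
    return out


def filter_short(reads: Sequence[Read], params: QCParams
                 ) -> tuple[list[Read], int]:
    """Keep reads of length >= min_length; return (retained, removed count)."""
    retained = [r for r in reads if len(r.sequence) >= params.min_length]
    return retained, len(reads) - len(retained)


def filter_quality(reads: Sequence[Read], params: QCParams
                   ) -> tuple[list[Read], int]:
    """Optional mean-quality filter; identity when disabled or no qualities."""
    if params.min_mean_quality is None:
        return list(reads), 0
    retained = [
        r for r in reads
        if r.quality is None
        or (sum(r.quality) / len(r.quality)) >= params.min_mean_quality
    ]
    return retained, len(reads) - len(retained)


def run_qc(reads: Sequence[Read], params: QCParams
           ) -> tuple[list[Read], pd.DataFrame]:
    """Mask adapters then drop short (and optionally low-quality) reads.
    Returns the retained reads and a per-library summary table."""
    masked = mask_adapters(reads, params)
    kept_q, n_qual = filter_quality(masked, params)
    kept, n_short = filter_short(kept_q, params)
    summary = qc_summary(reads, masked, kept)
    return kept, summary


def qc_summary(before: Sequence[Read], masked: Sequence[Read],
               after: Sequence[Read]) -> pd.DataFrame:
    """Per-library bookkeeping: input reads, reads with trimmed ends, reads
    removed, and mean retained length."""
    libs = sorted({r.library_id for r in before})
    masked_len = {r.id: len(r.sequence) for r in masked}
    rows = []
    for lib in libs:
        lib_before = [r for r in before if r.library_id == lib]
        lib_after = [r for r in after if r.library_id == lib]
        n_masked = sum(
            1 for r in lib_before if masked_len.get(r.id, len(r.sequence)) < len(r.sequence)
        )
        mean_len = (
            round(sum(len(r.sequence) for r in lib_after) / len(lib_after), 1)
            if lib_after else 0.0
        )
        rows.append(
            {
                "library_id": lib,
                "input_reads": len(lib_before),
                "masked_reads": n_masked,
                "removed_reads": len(lib_before) - len(lib_after),
                "retained_reads": len(lib_after),
                "mean_length": mean_len,
            }
        )
    return pd.DataFrame(rows)
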