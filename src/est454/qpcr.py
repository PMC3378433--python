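"""Relative qPCR quantification by the ddCT (2^-ddCT) method.

CT tables hold gene x stage x replicate threshold-cycle values (triplicate
reactions are the norm; values above the 40-cycle cap are truncated on load).
Normalization is "global": the reference level of a stage is the arithmetic
mean of the reference genes' replicate-mean CTs, i.e. the geometric mean of
their linear quantities.  dCT(gene, stage) subtracts that level from the
gene's replicate-mean CT; the fold change relative to a baseline stage
(bud time point 0, or green fruit) is 2^-(dCT(stage) - dCT(baseline)), so the
baseline fold is exactly 1.

Trend classification of fold profiles reuses the digital-expression step rule,
with no frequency offset (folds live on a scale of ~1).  Concordance between
read-predicted and qPCR-observed patterns is exact pattern equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .expression import TrendCall, TrendParams, classify_trend


@dataclass(frozen=True)
class QPCRParams:
    max_ct: float = 40.0
    baseline: Mapping[str, str] = field(
        default_factory=lambda: {"bud": "0", "fruit": "green"}
    )
    ref_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.max_ct <= 0:
            raise ValueError("max_ct must be positive")


REQUIRED_COLUMNS = ("gene", "stage", "replicate", "ct")


def load_ct_table(df: pd.DataFrame, params: QPCRParams | None = None) -> pd.DataFrame:
    """Validate a CT table and truncate values above ``max_ct`` to the cap."""
    params = params or QPCRParams()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CT table missing columns: {missing}")
    out = df.copy()
    out["stage"] = out["stage"].astype(str)
    if (out["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    out.loc[out["ct"] > params.max_ct, "ct"] = params.max_ct
    return out


def global_normalize(ct: pd.DataFrame, ref_genes: Sequence[str]) -> pd.DataFrame:
    """dCT table (genes x stages): replicate-mean CT minus the per-stage mean
    of the reference genes' replicate-mean CTs.

    Raises if any reference gene is missing in any stage, naming both.
    """
    if not ref_genes:
        raise ValueError("ref_genes must be non-empty")
    mean_ct = ct.groupby(["gene", "stage"])["ct"].mean().unstack("stage")
    for ref in ref_genes:
        if ref not in mean_ct.index:
            raise ValueError(f"reference gene {ref!r} absent from CT table")
        for stage in mean_ct.columns:
            if pd.isna(mean_ct.at[ref, stage]):
                raise ValueError(
                    f"reference gene {ref!r} has no CT in stage {stage!r}")
    ref_level = mean_ct.loc[list(ref_genes)].mean(axis=0)
    return mean_ct.subtract(ref_level, axis=1)


def ddct_fold(dct: pd.DataFrame, baseline_stage: str,
              stage_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Fold change per gene and stage: 2^-(dCT(stage) - dCT(baseline))."""
    baseline_stage = str(baseline_stage)
    if baseline_stage not in dct.columns:
        raise ValueError(f"baseline stage {baseline_stage!r} not in dCT table")
    folds = 2.0 ** (-(dct.subtract(dct[baseline_stage], axis=0)))
    if stage_order is not None:
        folds = folds[[str(s) for s in stage_order]]
    return folds


def qpcr_trends(folds: pd.DataFrame, stage_order: Sequence[str],
                params: TrendParams | None = None,
                group: str = "") -> dict[str, TrendCall]:
    """Trend pattern of each gene's fold profile across ordered stages."""
    params = params or TrendParams(pseudo_freq=0.0)
    if params.pseudo_freq:
        params = TrendParams(top_n=params.top_n,
                             fold_threshold=params.fold_threshold,
                             pseudo_freq=0.0,
                             evalue_cutoff=params.evalue_cutoff)
    cols = [str(s) for s in stage_order]
    return {
        gene: classify_trend([float(folds.at[gene, c]) for c in cols],
                             params, id=gene, group=group)
        for gene in folds.index
    }


def concordance(predicted: Mapping[str, TrendCall | str],
                observed: Mapping[str, TrendCall | str]) -> tuple[int, int, int]:
    """(n_match, n_total, percent) of genes whose predicted and observed
    patterns are identical.  Percent is rounded to the nearest integer.
    The two mappings must cover the same gene set."""
    if set(predicted) != set(observed):
        raise ValueError("predicted and observed gene sets differ")
    if not predicted:
        raise ValueError("empty gene set")

    def _pat(x):
        return x.pattern if isinstance(x, TrendCall) else str(x)

    n_total = len(predicted)
    n_match = sum(_pat(predicted[g]) == _pat(observed[g]) for g in predicted)
    return n_match, n_total, round(100.0 * n_match / n_total)
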