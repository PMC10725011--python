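"""Median-of-ratios size-factor normalization across samples.

Size factors are estimated on gene-level summed retained counts (the stable
choice: site-level rows are far too sparse for a median-of-ratios estimator)
and then applied to the site-level count vectors. Note that dividing every
count in a sample by one scalar cannot change any gene's within-gene read
proportions, so the Shannon index, effective site number, and effective
density are provably invariant to this step; it is kept on by default so
normalized gene totals are available for reporting and inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gene_assignment import GeneSiteMatrix


@dataclass
class SizeFactors:
    """Per-sample scaling constants; dividing counts by them equalizes depth."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        bad = {s: f for s, f in self.factors.items() if not f > 0}
        if bad:
            raise ValidationError(f"non-positive size factors: {bad}")

    def __getitem__(self, sample_id: str) -> float:
        return self.factors[sample_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.factors), "factor": list(self.factors.values())}
        )


def size_factors(gene_totals: pd.DataFrame, pseudo_reference: bool = False) -> SizeFactors:
    """Median-of-ratios estimator on a genes x samples count matrix.

    Each gene's geometric mean across samples is the reference; a sample's
    factor is the median over genes of count / reference. Only genes positive
    in every sample enter by default; with ``pseudo_reference`` the geometric
    mean is taken over the positive entries of each gene instead, which
    rescues sparse data where no gene is covered everywhere.
    """
    if gene_totals.shape[1] < 2:
        raise ValidationError("size factors need at least 2 samples")
    counts = gene_totals.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(counts)
    if pseudo_reference:
        finite = np.isfinite(logs)
        usable = finite.any(axis=1)
        if not usable.any():
            raise ValidationError("no gene has a positive count in any sample")
        log_ref = np.full(counts.shape[0], -np.inf)
        log_ref[usable] = np.nanmean(np.where(finite, logs, np.nan), axis=1)[usable]
        ratios = np.where(finite, logs - log_ref[:, None], np.nan)
        factors = np.exp(np.nanmedian(ratios, axis=0))
    else:
        all_positive = np.isfinite(logs).all(axis=1)
        if not all_positive.any():
            raise ValidationError(
                "no gene has positive counts in all samples; "
                "re-run with pseudo_reference=True"
            )
        log_ref = logs[all_positive].mean(axis=1)
        factors = np.exp(np.median(logs[all_positive] - log_ref[:, None], axis=0))
    return SizeFactors(dict(zip(gene_totals.columns, factors)))


def apply_size_factors(matrix: GeneSiteMatrix, factors: SizeFactors) -> GeneSiteMatrix:
    """Divide every site count by its sample's factor; site sets are unchanged."""
    missing = set(matrix.sample_ids) - set(factors.factors)
    if missing:
        raise ValidationError(f"samples without a size factor: {sorted(missing)}")
    return GeneSiteMatrix(
        locus_tags=list(matrix.locus_tags),
        sample_ids=list(matrix.sample_ids),
        vectors={
            (g, s): v / factors[s] for (g, s), v in matrix.vectors.items()
        },
        trimmed=dict(matrix.trimmed),
        audit=matrix.audit,
    )
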