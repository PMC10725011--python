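"""The diversity core: Shannon index, effective site number, effective density.

Each gene is treated as an ecological community whose "species" are its
unique transposon insertion sites and whose "individuals" are the reads at
each site. The Shannon index H' = -sum p_i ln p_i summarizes richness and
evenness of insertions within the gene; its exponential 'D = exp(H') is the
effective number of sites — the count of equally-abundant sites that would
yield the same index (the Hill number of order 1, which satisfies the
doubling property that raw indices lack). Dividing by gene length gives the
effective density ED, the per-gene fitness proxy: genes whose disruption is
costly in a condition show depleted, uneven insertions there, hence lower ED.

Natural logarithms throughout, forced by the exp() inverse in 'D.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ValidationError
from .formats_io import GeneModel
from .gene_assignment import GeneSiteMatrix

DIVERSITY_COLUMNS = ["locus_tag", "sample_id", "S", "H", "D_eff", "ED", "L"]


def shannon_index(counts: np.ndarray) -> float:
    """Shannon index (nats) of a vector of positive site read counts.

    The empty vector (a gene with no insertions) yields 0. Zero or negative
    entries are a validation error: zero-count sites are not sites and must
    be removed upstream. Invariant under scaling all counts by any c > 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        return 0.0
    if np.any(counts <= 0):
        raise ValidationError("site counts must be strictly positive")
    p = counts / counts.sum()
    terms = p * np.log(p)
    # compensated summation keeps very long vectors exact to double precision
    if counts.size > 10_000:
        return -math.fsum(terms)
    return float(-terms.sum())


def effective_sites(counts: np.ndarray) -> float:
    """Effective number of insertion sites, exp(H').

    Equals S exactly when all counts are equal and lies in [1, S] otherwise.
    Defined as 0 for a gene with no insertions: exp of an empty sum would
    wrongly report one effective site where there are none, and never-hit
    genes must rank as minimal diversity.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        return 0.0
    return float(np.exp(shannon_index(counts)))


def effective_density(counts: np.ndarray, length: int) -> float:
    """Effective density ED = 'D / gene length, the per-gene fitness proxy."""
    if length < 1:
        raise ValidationError(f"gene length must be >= 1, got {length}")
    return effective_sites(counts) / length


def diversity_matrix(
    matrix: GeneSiteMatrix,
    genes: list[GeneModel],
    length_mode: str = "full",
) -> pd.DataFrame:
    """Per (gene, sample) diversity records: S, H, D_eff, ED, L.

    ``length_mode`` chooses the ED denominator: the full annotated gene
    length (default) or the trimmed core length that actually hosts the
    counted sites. Output is rectangular — one row per (gene, sample) pair,
    ordered by locus_tag then sample — and deterministic.
    """
    if length_mode not in {"full", "trimmed"}:
        raise ValidationError(f"length_mode must be 'full' or 'trimmed', got {length_mode!r}")
    by_tag = {g.locus_tag: g for g in genes}
    missing = [t for t in matrix.locus_tags if t not in by_tag]
    if missing:
        raise ValidationError(f"genes in matrix but not annotation: {missing[:5]}")
    rows = []
    for tag in matrix.locus_tags:
        if length_mode == "full":
            L = by_tag[tag].length
        else:
            L = matrix.trimmed[tag].retained_length
        for sample in matrix.sample_ids:
            vec = matrix.vector(tag, sample)
            H = shannon_index(vec)
            D = effective_sites(vec)
            rows.append(
                {
                    "locus_tag": tag,
                    "sample_id": sample,
                    "S": len(vec),
                    "H": H,
                    "D_eff": D,
                    "ED": D / L,
                    "L": L,
                }
            )
    return pd.DataFrame(rows, columns=DIVERSITY_COLUMNS)
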