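"""Replicate QC, coding-sequence trimming, and per-gene site collection.

Insertions near the ends of an annotated gene can reflect mis-annotated
start codons (5') or tolerated truncations (3') rather than true loss of
function, so 20% of each coding sequence is trimmed from both ends before
any diversity statistic is computed; only sites in the central 60% count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .formats_io import GeneModel, InsertionProfile, SampleSheet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrimmedInterval:
    """Central sub-interval of a gene retained for diversity analysis."""

    locus_tag: str
    lo: int
    hi: int

    @property
    def retained_length(self) -> int:
        return self.hi - self.lo + 1


@dataclass
class GeneSiteMatrix:
    """Per (gene, sample) vectors of site read counts inside the trimmed interval.

    Vectors hold one strictly positive entry per unique insertion site,
    ordered by genomic position. Genes never hit in a sample have an empty
    vector (S = 0). The audit frame accounts for every read in each profile:
    retained (in some trimmed interval), trimmed_region (in a gene but
    outside its core), or intergenic.
    """

    locus_tags: list[str]
    sample_ids: list[str]
    vectors: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    trimmed: dict[str, TrimmedInterval] = field(default_factory=dict)
    audit: pd.DataFrame | None = None

    def vector(self, locus_tag: str, sample_id: str) -> np.ndarray:
        return self.vectors.get((locus_tag, sample_id), np.empty(0))

    def S(self, locus_tag: str, sample_id: str) -> int:
        return len(self.vector(locus_tag, sample_id))

    def gene_totals(self) -> pd.DataFrame:
        """Summed retained read counts, genes x samples (normalization input)."""
        data = {
            s: [self.vector(g, s).sum() for g in self.locus_tags]
            for s in self.sample_ids
        }
        return pd.DataFrame(data, index=pd.Index(self.locus_tags, name="locus_tag"))

    def subset_samples(self, sample_ids: list[str]) -> "GeneSiteMatrix":
        keep = set(sample_ids)
        return GeneSiteMatrix(
            locus_tags=list(self.locus_tags),
            sample_ids=[s for s in self.sample_ids if s in keep],
            vectors={k: v for k, v in self.vectors.items() if k[1] in keep},
            trimmed=dict(self.trimmed),
            audit=None,
        )


def filter_samples(
    sheet: SampleSheet,
    min_mapped_fraction: float = 0.8,
    strict: bool = True,
) -> SampleSheet:
    """Exclude replicates whose mapped-read fraction is not above the threshold.

    The rule is strictly greater-than: a sample mapping exactly 80% of its
    reads is excluded. Samples without a recorded mapped_fraction pass with
    a warning. With ``strict``, fewer than two surviving replicates in any
    condition is an error, since the downstream t-test needs within-condition
    variance.
    """
    frame = sheet.frame.copy()
    known = frame["mapped_fraction"].notna()
    fails = known & (frame["mapped_fraction"] <= min_mapped_fraction) & frame["include"]
    for row in frame[fails].itertuples(index=False):
        logger.info(
            "excluding %s: mapped_fraction %.3f <= %.3f",
            row.sample_id, row.mapped_fraction, min_mapped_fraction,
        )
    for row in frame[~known & frame["include"]].itertuples(index=False):
        logger.warning("%s has no mapped_fraction; passing QC unchecked", row.sample_id)
    frame.loc[fails, "include"] = False
    filtered = SampleSheet(frame)
    if strict:
        for cond in filtered.conditions():
            n = len(filtered.samples_for(cond))
            if n < 2:
                raise ValidationError(
                    f"condition {cond!r} has {n} replicate(s) after QC; "
                    "at least 2 are required"
                )
    return filtered


def trimmed_interval(gene: GeneModel, trim_fraction: float = 0.2) -> TrimmedInterval:
    """Trim ``floor(trim_fraction * L)`` nucleotides from each end of the gene.

    The floor rule guarantees short genes keep a non-empty core, and the trim
    is symmetric, so strand never matters.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ConfigurationError(
            f"trim_fraction must be in [0, 0.5), got {trim_fraction}"
        )
    cut = int(np.floor(trim_fraction * gene.length))
    return TrimmedInterval(gene.locus_tag, gene.start + cut, gene.end - cut)


def assign_sites(
    profiles: list[InsertionProfile],
    genes: list[GeneModel],
    trim_fraction: float = 0.2,
) -> GeneSiteMatrix:
    """Collect each gene's in-core site count vector for every sample.

    A site contributes to a gene iff its position lies in the closed trimmed
    interval [lo, hi]; a site inside two overlapping genes contributes to
    both (disruption affects both annotations). Sites on replicons absent
    from the annotation are ignored with a warning; intergenic reads are
    tallied in the audit but dropped.
    """
    trimmed = {g.locus_tag: trimmed_interval(g, trim_fraction) for g in genes}
    by_rep_genes: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_rep_genes.setdefault(g.replicon, []).append(g)

    matrix = GeneSiteMatrix(
        locus_tags=[g.locus_tag for g in genes],
        sample_ids=[p.sample_id for p in profiles],
        trimmed=trimmed,
    )
    audit_rows = []
    warned: set[str] = set()
    for profile in profiles:
        retained = trimmed_region = intergenic = 0.0
        for rep, (pos, cnt) in profile.by_replicon().items():
            rep_genes = by_rep_genes.get(rep)
            if rep_genes is None:
                if rep not in warned:
                    logger.warning(
                        "replicon %r in profiles but absent from annotation; "
                        "its sites are ignored", rep,
                    )
                    warned.add(rep)
                continue
            in_core = np.zeros(len(pos), dtype=bool)
            in_gene = np.zeros(len(pos), dtype=bool)
            for gene in rep_genes:
                iv = trimmed[gene.locus_tag]
                lo_i = np.searchsorted(pos, iv.lo, side="left")
                hi_i = np.searchsorted(pos, iv.hi, side="right")
                if hi_i > lo_i:
                    matrix.vectors[(gene.locus_tag, profile.sample_id)] = cnt[
                        lo_i:hi_i
                    ].copy()
                in_core[lo_i:hi_i] = True
                g_lo = np.searchsorted(pos, gene.start, side="left")
                g_hi = np.searchsorted(pos, gene.end, side="right")
                in_gene[g_lo:g_hi] = True
            retained += cnt[in_core].sum()
            trimmed_region += cnt[in_gene & ~in_core].sum()
            intergenic += cnt[~in_gene].sum()
        audit_rows.append(
            {
                "sample_id": profile.sample_id,
                "retained": retained,
                "trimmed_region": trimmed_region,
                "intergenic": intergenic,
                "total_annotated_replicons": retained + trimmed_region + intergenic,
            }
        )
        if intergenic:
            logger.info(
                "%s: %.0f intergenic reads dropped", profile.sample_id, intergenic
            )
    matrix.audit = pd.DataFrame(audit_rows)
    return matrix
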