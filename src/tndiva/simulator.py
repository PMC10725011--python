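"""Seeded generator of synthetic comparative TnSeq experiments.

The generator emulates the shape of a two-condition transposon mutant
library screen: a multi-replicon bacterial genome, a dense Tn5-style library
with insertions at arbitrary coordinates, heavy-tailed (lognormal) per-site
mutant abundances, replicated sequencing of the pool under a reference and a
treatment condition, and a known subset of genes whose mutants are depleted
in the treatment. Depletion acts multiplicatively on site abundances — a
gene-level fitness cost shrinks the representation of all of that gene's
mutants — and detection therefore works through sampling: a depleted gene
receives proportionally fewer reads, fewer of its sites are observed, and
its effective density drops.

Extras mirroring common artefacts: per-replicate depth multipliers (one
anomalously shallow replicate), and a contamination fraction of reads mapped
to a decoy replicon, which lowers the sample sheet's mapped_fraction.

Every sample draws from its own pseudorandom stream derived from the master
seed and the sample id, so dropping a sample never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .diversity import effective_sites
from .formats_io import (
    GeneModel,
    InsertionProfile,
    SampleSheet,
    write_annotation_tsv,
    write_insertion_table,
    write_sample_sheet,
)

COG_LETTERS = "CDEFGHIJKLMNOPQTUVRS"
DECOY_REPLICON = "decoy_contaminant"


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic experiment.

    Defaults describe a desk-scale two-condition screen: 500 genes on two
    replicons, a dense Tn5 library at 100 insertion sites per kb,
    lognormal(sigma=1.5) site abundances, 4 replicates per condition at 200k
    reads, 25 genes depleted four-fold (d = 0.25) in the treatment condition,
    and a 5% contaminant read fraction. Depth and site density are chosen so
    sequencing is sampling-limited at roughly 2.5 reads per unique site — the
    regime of real dense Tn5 screens, and the one in which a fitness
    depletion visibly removes effective sites.
    """

    n_genes: int = 500
    gene_length_range: tuple[int, int] = (300, 2400)
    intergenic_fraction: float = 0.12
    sites_per_kb: float = 100.0
    abundance_sigma: float = 1.5
    conditions: tuple[str, str] = ("Ground", "ISS")
    replicates: int = 4
    reads_per_replicate: int = 200_000
    depth_multipliers: dict[str, float] = field(default_factory=dict)
    n_depleted: int = 25
    depletion_factor: float = 0.25
    contamination_fraction: float | dict[str, float] = 0.05
    n_replicons: int = 2
    ta_sites: bool = False
    ta_spacing: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.depletion_factor <= 1:
            raise ConfigurationError("depletion_factor must be in (0, 1]")
        if not 0 <= self.intergenic_fraction < 1:
            raise ConfigurationError("intergenic_fraction must be in [0, 1)")
        if self.n_depleted > self.n_genes:
            raise ConfigurationError("more depleted genes than genes")
        fracs = (
            self.contamination_fraction.values()
            if isinstance(self.contamination_fraction, dict)
            else [self.contamination_fraction]
        )
        if any(not 0 <= f < 1 for f in fracs):
            raise ConfigurationError("contamination fractions must be in [0, 1)")

    def sample_ids(self) -> list[str]:
        return [
            f"{cond}_{i + 1}"
            for cond in self.conditions
            for i in range(self.replicates)
        ]

    def contamination_for(self, sample_id: str) -> float:
        if isinstance(self.contamination_fraction, dict):
            return self.contamination_fraction.get(sample_id, 0.0)
        return self.contamination_fraction


@dataclass
class SimResult:
    config: SimConfig
    genes: list[GeneModel]
    sheet: SampleSheet
    profiles: list[InsertionProfile]
    truth: pd.DataFrame  # locus_tag, is_depleted, depletion_factor


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Independent stream per sample, stable across sample-set changes."""
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def _layout_genome(config: SimConfig, rng: np.random.Generator):
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    # first replicon carries ~70% of genes, the rest split the remainder
    if config.n_replicons == 1:
        shares = [config.n_genes]
    else:
        first = int(round(0.7 * config.n_genes))
        rest = config.n_genes - first
        per = rest // (config.n_replicons - 1)
        shares = [first] + [per] * (config.n_replicons - 2) + [rest - per * (config.n_replicons - 2)]
    mean_gap = config.intergenic_fraction / (1 - config.intergenic_fraction) * lengths.mean()
    genes: list[GeneModel] = []
    replicon_len: dict[str, int] = {}
    idx = 0
    for r, share in enumerate(shares):
        rep = f"replicon_{r + 1}"
        pos = 1
        for _ in range(share):
            gap = int(rng.integers(0, max(1, int(2 * mean_gap)) + 1))
            start = pos + gap
            end = start + int(lengths[idx]) - 1
            n_cogs = rng.choice([0, 1, 2], p=[0.25, 0.6, 0.15])
            cogs = frozenset(rng.choice(list(COG_LETTERS), size=n_cogs, replace=False))
            genes.append(
                GeneModel(
                    locus_tag=f"gene_{idx + 1:04d}",
                    replicon=rep,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    cog_categories=cogs,
                    product="hypothetical protein" if not cogs else "simulated protein",
                )
            )
            pos = end + 1
            idx += 1
        replicon_len[rep] = pos + int(mean_gap)
    return genes, replicon_len


def _place_sites(config: SimConfig, replicon_len: dict[str, int], rng: np.random.Generator):
    reps, positions = [], []
    for rep, length in replicon_len.items():
        n_sites = int(round(config.sites_per_kb * length / 1000))
        if config.ta_sites:
            grid = np.arange(1, length + 1, config.ta_spacing)
            candidates = grid
        else:
            candidates = None
        if candidates is not None:
            if n_sites > candidates.size:
                raise ConfigurationError(
                    f"{rep}: {n_sites} sites requested but only {candidates.size} "
                    "TA positions available"
                )
            pos = np.sort(rng.choice(candidates, size=n_sites, replace=False))
        else:
            if n_sites > length:
                raise ConfigurationError(
                    f"{rep}: {n_sites} sites requested on {length} bp"
                )
            pos = np.sort(rng.choice(length, size=n_sites, replace=False) + 1)
        reps.append(np.full(n_sites, rep))
        positions.append(pos)
    return np.concatenate(reps), np.concatenate(positions)


def simulate_experiment(config: SimConfig) -> SimResult:
    """Generate one fully reproducible synthetic experiment."""
    layout_rng = np.random.default_rng([config.seed, 0])
    sites_rng = np.random.default_rng([config.seed, 1])
    decoy_rng = np.random.default_rng([config.seed, 2])

    genes, replicon_len = _layout_genome(config, layout_rng)
    site_rep, site_pos = _place_sites(config, replicon_len, sites_rng)
    abundance = sites_rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=site_pos.size)

    depleted_tags = set(
        layout_rng.choice(
            [g.locus_tag for g in genes], size=config.n_depleted, replace=False
        )
    )
    depleted_site = np.zeros(site_pos.size, dtype=bool)
    for g in genes:
        if g.locus_tag in depleted_tags:
            mask = (site_rep == g.replicon) & (site_pos >= g.start) & (site_pos <= g.end)
            depleted_site |= mask

    cond_abundance = {
        config.conditions[0]: abundance,
        config.conditions[1]: np.where(
            depleted_site, abundance * config.depletion_factor, abundance
        ),
    }

    n_decoy = 50
    decoy_pos = np.sort(decoy_rng.choice(100_000, size=n_decoy, replace=False) + 1)
    decoy_abund = decoy_rng.lognormal(0.0, config.abundance_sigma, size=n_decoy)
    decoy_p = decoy_abund / decoy_abund.sum()

    profiles, sheet_rows = [], []
    for cond in config.conditions:
        p = cond_abundance[cond] / cond_abundance[cond].sum()
        for i in range(config.replicates):
            sample_id = f"{cond}_{i + 1}"
            rng = _sample_rng(config.seed, sample_id)
            mult = config.depth_multipliers.get(sample_id, 1.0)
            reads = int(round(config.reads_per_replicate * mult))
            f = config.contamination_for(sample_id)
            n_contam = int(round(f * reads))
            counts = rng.multinomial(reads - n_contam, p)
            profile = InsertionProfile(sample_id=sample_id)
            nz = counts > 0
            for rep, pos, c in zip(site_rep[nz], site_pos[nz], counts[nz]):
                profile.counts[(str(rep), int(pos))] = float(c)
            if n_contam:
                dc = rng.multinomial(n_contam, decoy_p)
                for pos, c in zip(decoy_pos[dc > 0], dc[dc > 0]):
                    profile.counts[(DECOY_REPLICON, int(pos))] = float(c)
            profiles.append(profile)
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "condition": cond,
                    "mapped_fraction": 1.0 - f,
                    "include": True,
                }
            )

    truth = pd.DataFrame(
        {
            "locus_tag": [g.locus_tag for g in genes],
            "is_depleted": [g.locus_tag in depleted_tags for g in genes],
            "depletion_factor": [
                config.depletion_factor if g.locus_tag in depleted_tags else 1.0
                for g in genes
            ],
        }
    )
    return SimResult(
        config=config,
        genes=genes,
        sheet=SampleSheet(pd.DataFrame(sheet_rows)),
        profiles=profiles,
        truth=truth,
    )


def null_config(seed: int = 0, n_genes: int = 1000, **overrides) -> SimConfig:
    """A no-effect configuration: same abundances in both conditions."""
    return replace(
        SimConfig(seed=seed, n_genes=n_genes, n_depleted=0), **overrides
    )


def expected_effective_sites(
    site_abundances: np.ndarray,
    reads: int,
    n_draws: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo expectation of the observed effective site number.

    Draws ``n_draws`` multinomial samples of ``reads`` reads over the given
    abundances and averages the effective site number of the non-zero
    counts. Used to calibrate what finite sequencing depth does to observed
    diversity.
    """
    abund = np.asarray(site_abundances, dtype=float)
    if np.any(abund <= 0):
        raise ConfigurationError("site abundances must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    p = abund / abund.sum()
    values = []
    for _ in range(n_draws):
        counts = rng.multinomial(reads, p)
        values.append(effective_sites(counts[counts > 0]))
    return float(np.mean(values))


def write_experiment(sim: SimResult, outdir: str | Path) -> None:
    """Write the experiment in the package's external formats, plus truth.tsv."""
    outdir = Path(outdir)
    counts_dir = outdir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)
    for profile in sim.profiles:
        write_insertion_table(profile, counts_dir / f"{profile.sample_id}.tsv")
    write_annotation_tsv(sim.genes, outdir / "annotation.tsv")
    write_sample_sheet(sim.sheet, outdir / "samples.tsv")
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
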