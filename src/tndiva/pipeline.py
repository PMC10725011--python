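"""End-to-end orchestration: QC -> trimming -> normalization -> diversity ->
comparison -> consensus -> COG tallies -> replicate-subset reruns.

All outputs are plain TSV/JSON written deterministically (fixed column and
row order, 12 significant digits), so re-running with identical inputs and
configuration yields byte-identical files. A run manifest records the
configuration hash and input checksums for provenance; it deliberately
contains no timestamps.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .comparative_stats import compare, consensus, run_subset_analyses
from .diversity import diversity_matrix
from .errors import ConfigurationError, TnDivAError
from .formats_io import (
    read_annotation,
    read_insertion_table,
    read_sample_sheet,
    write_results_table,
)
from .functional_summary import tally_cog
from .gene_assignment import assign_sites, filter_samples
from .normalization import apply_size_factors, size_factors

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one comparison run.

    Defaults are the analysis constants of the method: 20% coding-sequence
    trim per end, replicates kept only above 80% mapped reads, |log2FC| > 1,
    Cook's distance > 4/n, Welch p <= 0.05 and <= 0.01.
    """

    counts_dir: str = ""
    annotation: str = ""
    annotation_format: str = "tsv"
    samples: str = ""
    out_dir: str = "tndiva_out"
    dialect: str = "tsv"
    trim_fraction: float = 0.2
    min_mapped_fraction: float = 0.8
    length_mode: str = "full"
    normalize: bool = True
    pseudo_reference: bool = False
    log2fc_cutoff: float = 1.0
    cooks_threshold_factor: float = 4.0
    subsets: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def run(config: RunConfig, through: str = "compare") -> dict:
    """Execute the pipeline; returns the result bundle in memory.

    Stages run in a fixed order and any failure aborts with the stage name
    attached, so a broken input is traceable to the step that rejected it.
    ``through="diversity"`` stops after writing effective_density.tsv.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        counts_dir = Path(config.counts_dir)
        suffix = ".wig" if config.dialect == "wig" else ".tsv"
        count_files = sorted(counts_dir.glob(f"*{suffix}"))
        if not count_files:
            raise ConfigurationError(f"no {suffix} files in {counts_dir}")
        sheet = read_sample_sheet(config.samples)
        genes = read_annotation(config.annotation, format=config.annotation_format)

        stage = "replicate QC"
        sheet = filter_samples(sheet, config.min_mapped_fraction)
        kept = set(sheet.included["sample_id"])
        profiles = [
            read_insertion_table(p, dialect=config.dialect)
            for p in count_files
            if p.stem in kept
        ]
        missing = kept - {p.sample_id for p in profiles}
        if missing:
            raise ConfigurationError(f"no count file for samples: {sorted(missing)}")

        stage = "site assignment"
        matrix = assign_sites(profiles, genes, trim_fraction=config.trim_fraction)
        _write_tsv(matrix.audit, out / "assignment_audit.tsv")

        stage = "normalization"
        if config.normalize:
            factors = size_factors(
                matrix.gene_totals(), pseudo_reference=config.pseudo_reference
            )
            _write_tsv(factors.to_frame(), out / "size_factors.tsv")
            matrix = apply_size_factors(matrix, factors)

        stage = "diversity"
        div = diversity_matrix(matrix, genes, length_mode=config.length_mode)
        _write_tsv(div, out / "effective_density.tsv")

        results = None
        cons = None
        if through != "diversity":
            stage = "comparison"
            results = compare(
                div,
                sheet,
                log2fc_cutoff=config.log2fc_cutoff,
                cooks_threshold_factor=config.cooks_threshold_factor,
            )
            write_results_table(results, out / "comparison.tsv")
            cons = consensus(results)
            _write_tsv(
                pd.DataFrame(
                    sorted(cons["sizes"].items()), columns=["set", "n_genes"]
                ),
                out / "consensus_sizes.tsv",
            )

            stage = "COG tallies"
            tally_rows = []
            for method, hit_set in cons["sets"].items():
                tally = tally_cog(hit_set, genes)
                for cat, n in sorted(tally.counts.items()):
                    tally_rows.append({"method": method, "category": cat, "n_genes": n})
            _write_tsv(
                pd.DataFrame(tally_rows, columns=["method", "category", "n_genes"]),
                out / "cog_tally.tsv",
            )

        stage = "subset analyses"
        if config.subsets and through != "diversity":
            sub_results, overlap = run_subset_analyses(
                div,
                sheet,
                config.subsets,
                log2fc_cutoff=config.log2fc_cutoff,
                cooks_threshold_factor=config.cooks_threshold_factor,
            )
            for name, frame in sub_results.items():
                write_results_table(frame, out / f"comparison_{name}.tsv")
            _write_tsv(overlap, out / "overlap_report.tsv")
    except TnDivAError as exc:
        raise TnDivAError(
            f"pipeline failed at stage {stage!r}: {exc} "
            "(check the inputs this stage consumes)"
        ) from exc

    stage = "manifest"
    manifest = {
        "tndiva_version": __version__,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {
            str(p): _sha256(p)
            for p in [*count_files, Path(config.annotation), Path(config.samples)]
        },
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {"sheet": sheet, "matrix": matrix, "diversity": div, "results": results,
            "consensus": cons}
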