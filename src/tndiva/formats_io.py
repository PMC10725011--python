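"""Readers and writers for insertion-site tables, annotations, sample sheets and results.

All genomic coordinates are 1-based and inclusive, matching GFF3. An insertion
site is a bare (replicon, position) pair — the coordinate to which the 5' end
of a sequencing read mapped; strand of insertion is deliberately not tracked,
so sites on opposite strands at the same coordinate collapse into one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "locus_tag",
    "mean_ED_A",
    "mean_ED_B",
    "log2FC",
    "log2fc_hit",
    "cooksD",
    "influential",
    "welch_t",
    "welch_df",
    "welch_p",
    "p_adj",
    "sig05",
    "sig01",
    "direction",
    "consensus_all3",
    "consensus_cooks_welch",
]


@dataclass
class InsertionProfile:
    """One sample's transposon insertion map: (replicon, position) -> read count.

    Counts are integers on input but may become fractional after size-factor
    normalization, so they are stored as floats throughout.
    """

    sample_id: str
    counts: dict[tuple[str, int], float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    def replicons(self) -> list[str]:
        return sorted({rep for rep, _ in self.counts})

    def by_replicon(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Position-sorted (positions, counts) arrays per replicon."""
        grouped: dict[str, list[tuple[int, float]]] = {}
        for (rep, pos), c in self.counts.items():
            grouped.setdefault(rep, []).append((pos, c))
        out = {}
        for rep, pairs in grouped.items():
            pairs.sort()
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            cnt = np.array([c for _, c in pairs], dtype=float)
            out[rep] = (pos, cnt)
        return out

    def validate(self) -> None:
        for (rep, pos), c in self.counts.items():
            if pos < 1:
                raise ValidationError(
                    f"sample {self.sample_id}: position {pos} on {rep} is < 1 "
                    "(coordinates are 1-based)"
                )
            if c < 0:
                raise ValidationError(
                    f"sample {self.sample_id}: negative count {c} at {rep}:{pos}"
                )


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene interval (1-based, inclusive)."""

    locus_tag: str
    replicon: str
    start: int
    end: int
    strand: str = "+"
    cog_categories: frozenset[str] = frozenset()
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleSheet:
    """Replicate metadata: sample id, condition label, mapped-read fraction, include flag."""

    frame: pd.DataFrame  # columns: sample_id, condition, mapped_fraction, include

    def __post_init__(self) -> None:
        required = {"sample_id", "condition"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample ids: {sorted(set(dups))}")
        if "mapped_fraction" not in self.frame.columns:
            self.frame = self.frame.assign(mapped_fraction=np.nan)
        if "include" not in self.frame.columns:
            self.frame = self.frame.assign(include=True)
        self.frame = self.frame.reset_index(drop=True)

    @property
    def included(self) -> pd.DataFrame:
        return self.frame[self.frame["include"]].reset_index(drop=True)

    def conditions(self) -> list[str]:
        """Condition labels among included samples, in order of first appearance."""
        return list(dict.fromkeys(self.included["condition"]))

    def samples_for(self, condition: str) -> list[str]:
        inc = self.included
        return list(inc.loc[inc["condition"] == condition, "sample_id"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        keep = set(sample_ids)
        unknown = keep - set(self.frame["sample_id"])
        if unknown:
            raise ValidationError(f"unknown sample ids in subset: {sorted(unknown)}")
        return SampleSheet(self.frame[self.frame["sample_id"].isin(keep)].copy())


# ---------------------------------------------------------------------------
# insertion tables


def _parse_count(token: str, path: str, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed count {token!r}") from exc
    if not math.isfinite(value):
        raise ParseError(f"{path}:{lineno}: non-finite count {token!r}")
    if value < 0:
        raise ValidationError(f"{path}:{lineno}: negative count {value}")
    return value


def _parse_position(token: str, path: str, lineno: int) -> int:
    try:
        pos = int(token)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed position {token!r}") from exc
    if pos < 1:
        raise ValidationError(
            f"{path}:{lineno}: position {pos} invalid in a 1-based file"
        )
    return pos


def read_insertion_table(
    path: str | Path, dialect: str = "tsv", sample_id: str | None = None
) -> InsertionProfile:
    """Read one sample's insertion sites from a TSV or wiggle-track file.

    TSV dialect: tab-separated ``replicon  position  count`` with optional
    ``#`` comment lines and an optional header row. Wig dialect: UCSC-style
    ``variableStep chrom=<replicon>`` blocks of ``position value`` lines
    (``fixedStep`` blocks are also accepted). Duplicate (replicon, position)
    rows are summed with a logged warning — merged sequencing runs of the
    same library legitimately produce them.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if dialect not in {"tsv", "wig"}:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'tsv' or 'wig'")

    counts: dict[tuple[str, int], float] = {}
    duplicates = 0

    def add(rep: str, pos: int, value: float) -> None:
        nonlocal duplicates
        key = (rep, pos)
        if key in counts:
            duplicates += 1
            counts[key] += value
        else:
            counts[key] = value

    with open(path, encoding="utf-8") as fh:
        if dialect == "tsv":
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                    )
                if lineno == 1 and fields[0] == "replicon":
                    continue  # header row
                rep = fields[0]
                add(
                    rep,
                    _parse_position(fields[1], str(path), lineno),
                    _parse_count(fields[2], str(path), lineno),
                )
        else:
            rep = None
            fixed_pos = None
            fixed_step = 1
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("variableStep"):
                    rep = _wig_chrom(line, str(path), lineno)
                    fixed_pos = None
                    continue
                if line.startswith("fixedStep"):
                    rep = _wig_chrom(line, str(path), lineno)
                    attrs = dict(
                        token.split("=", 1) for token in line.split()[1:] if "=" in token
                    )
                    fixed_pos = _parse_position(attrs.get("start", "1"), str(path), lineno)
                    fixed_step = int(attrs.get("step", "1"))
                    continue
                if rep is None:
                    raise ParseError(
                        f"{path}:{lineno}: data line before any step declaration"
                    )
                fields = line.split()
                if fixed_pos is not None:
                    value = _parse_count(fields[0], str(path), lineno)
                    if value > 0:
                        add(rep, fixed_pos, value)
                    fixed_pos += fixed_step
                else:
                    if len(fields) != 2:
                        raise ParseError(
                            f"{path}:{lineno}: expected 'position value', got {line!r}"
                        )
                    value = _parse_count(fields[1], str(path), lineno)
                    if value > 0:
                        add(rep, _parse_position(fields[0], str(path), lineno), value)

    if duplicates:
        logger.warning(
            "%s: %d duplicate (replicon, position) rows summed", path, duplicates
        )
    profile = InsertionProfile(sample_id=sample_id, counts=counts)
    profile.validate()
    return profile


def _wig_chrom(line: str, path: str, lineno: int) -> str:
    for token in line.split()[1:]:
        if token.startswith("chrom="):
            return token.split("=", 1)[1]
    raise ParseError(f"{path}:{lineno}: step declaration without chrom=")


def write_insertion_table(profile: InsertionProfile, path: str | Path) -> None:
    """Write a profile as a sorted three-column TSV (inverse of the tsv dialect)."""
    rows = sorted(profile.counts.items())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("replicon\tposition\tcount\n")
        for (rep, pos), c in rows:
            fh.write(f"{rep}\t{pos}\t{_fmt(c)}\n")


# ---------------------------------------------------------------------------
# annotations

ANNOTATION_TSV_COLUMNS = ["locus_tag", "replicon", "start", "end", "strand", "cog", "product"]


def read_annotation(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (gene/CDS features keyed by ``locus_tag``)
    or a flat TSV with columns locus_tag, replicon, start, end, strand, cog, product.
    """
    path = Path(path)
    if format == "gff3":
        genes = _read_gff3(path)
    elif format == "tsv":
        genes = _read_annotation_tsv(path)
    else:
        raise ValidationError(f"unknown annotation format {format!r}")

    tags = [g.locus_tag for g in genes]
    seen: set[str] = set()
    dups = sorted({t for t in tags if t in seen or seen.add(t)})
    if dups:
        raise ValidationError(f"duplicate locus_tags in annotation: {dups}")
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    genes: dict[str, GeneModel] = {}
    for feature in gffutils.DataIterator(str(path)):
        if feature.featuretype not in {"gene", "CDS"}:
            continue
        tags = feature.attributes.get("locus_tag")
        if not tags:
            continue
        tag = tags[0]
        if tag in genes:
            continue  # CDS child of an already-seen gene
        cog = feature.attributes.get("cog", [""])[0]
        product = feature.attributes.get("product", [""])[0]
        genes[tag] = GeneModel(
            locus_tag=tag,
            replicon=feature.seqid,
            start=feature.start,
            end=feature.end,
            strand=feature.strand if feature.strand in {"+", "-"} else "+",
            cog_categories=frozenset(cog) if cog else frozenset(),
            product=product,
        )
    return list(genes.values())


def _read_annotation_tsv(path: Path) -> list[GeneModel]:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"locus_tag": str})
    missing = set(ANNOTATION_TSV_COLUMNS[:5]) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: annotation TSV missing columns {sorted(missing)}")
    genes = []
    for row in frame.itertuples(index=False):
        cog = getattr(row, "cog", "")
        cog = "" if (isinstance(cog, float) and math.isnan(cog)) else str(cog)
        product = getattr(row, "product", "")
        product = "" if (isinstance(product, float) and math.isnan(product)) else str(product)
        genes.append(
            GeneModel(
                locus_tag=str(row.locus_tag),
                replicon=str(row.replicon),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                cog_categories=frozenset(cog.strip()) if cog.strip() else frozenset(),
                product=product,
            )
        )
    return genes


def write_annotation_tsv(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_TSV_COLUMNS) + "\n")
        for g in genes:
            cog = "".join(sorted(g.cog_categories))
            fh.write(
                f"{g.locus_tag}\t{g.replicon}\t{g.start}\t{g.end}\t{g.strand}\t{cog}\t{g.product}\n"
            )


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV/TSV sample sheet (sample_id, condition[, mapped_fraction, include]).

    A missing include column defaults to True; a missing mapped_fraction is
    carried as NaN (QC then passes the sample through with a warning).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    frame.columns = [str(c).strip() for c in frame.columns]
    if "include" in frame.columns:
        frame["include"] = (
            frame["include"]
            .astype(str)
            .str.strip()
            .str.lower()
            .map({"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False})
        )
        if frame["include"].isna().any():
            raise ParseError(f"{path}: unparseable include values")
    if "mapped_fraction" in frame.columns:
        frame["mapped_fraction"] = pd.to_numeric(frame["mapped_fraction"])
        bad = frame["mapped_fraction"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValidationError(f"{path}: mapped_fraction outside [0, 1]")
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    frame = sheet.frame.copy()
    frame["include"] = frame["include"].map({True: "true", False: "false"})
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# results


def _fmt(value: float) -> str:
    """Shortest exact decimal form of a number; infinities as Inf/-Inf."""
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (float, np.floating)):
        value = float(value)
        if math.isinf(value):
            return "Inf" if value > 0 else "-Inf"
        if math.isnan(value):
            return "NA"
        return repr(value)
    return str(value)


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene comparison table as TSV, sorted by locus_tag.

    Numeric fields are written in shortest-exact decimal form, so a
    write/read round trip is lossless; infinite fold changes serialize as
    ``Inf``/``-Inf``.
    """
    if results.empty:
        raise ValidationError("refusing to write an empty results table")
    frame = results.sort_values("locus_tag").reset_index(drop=True)
    cols = [c for c in RESULT_COLUMNS if c in frame.columns] + [
        c for c in frame.columns if c not in RESULT_COLUMNS
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in frame[cols].itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        keep_default_na=False,
        true_values=["true"],
        false_values=["false"],
    )
    return frame
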