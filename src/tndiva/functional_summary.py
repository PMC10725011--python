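"""COG functional-category tallies over hit gene sets.

Each hit gene contributes one count to every COG category letter it carries,
so the total number of predictions can exceed the number of genes. Three
pseudo-categories are first-class bins alongside the letters: hypothetical
proteins, general function prediction only, and function unknown. Genes with
no category are binned by keywords in their product annotation, defaulting
to hypothetical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import ValidationError
from .formats_io import GeneModel

HYPOTHETICAL = "hypothetical"
GENERAL_FUNCTION = "general_function"
UNKNOWN_FUNCTION = "unknown_function"

# COG letters whose meaning is one of the pseudo-bins
DEFAULT_LETTER_MAP = {"R": GENERAL_FUNCTION, "S": UNKNOWN_FUNCTION}

# keywords scanned in the product description of uncategorized genes
DEFAULT_KEYWORDS = {
    "hypothetical": HYPOTHETICAL,
    "general function": GENERAL_FUNCTION,
    "unknown function": UNKNOWN_FUNCTION,
    "uncharacterized": UNKNOWN_FUNCTION,
}


@dataclass
class CogTally:
    counts: dict[str, int] = field(default_factory=dict)
    total_predictions: int = 0
    total_genes: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items())
        return pd.DataFrame(rows, columns=["category", "n_genes"])


def tally_cog(
    hit_genes: Iterable[str],
    genes: list[GeneModel],
    letter_map: dict[str, str] | None = None,
    keywords: dict[str, str] | None = None,
) -> CogTally:
    """Count hit genes per functional category.

    Multi-category genes count once in each of their categories; genes with
    an empty category set fall into a pseudo-category chosen by product
    keywords (hypothetical by default), so every hit gene contributes at
    least one tally.
    """
    letter_map = DEFAULT_LETTER_MAP if letter_map is None else letter_map
    keywords = DEFAULT_KEYWORDS if keywords is None else keywords
    by_tag = {g.locus_tag: g for g in genes}
    hits = sorted(set(hit_genes))
    missing = [t for t in hits if t not in by_tag]
    if missing:
        raise ValidationError(f"hit genes absent from annotation: {missing}")

    tally = CogTally()
    for tag in hits:
        gene = by_tag[tag]
        if gene.cog_categories:
            cats = sorted(letter_map.get(c, c) for c in gene.cog_categories)
        else:
            product = gene.product.lower()
            cats = [
                next(
                    (bin_ for kw, bin_ in keywords.items() if kw in product),
                    HYPOTHETICAL,
                )
            ]
        for cat in cats:
            tally.counts[cat] = tally.counts.get(cat, 0) + 1
        tally.total_predictions += len(cats)
        tally.total_genes += 1
    return tally
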