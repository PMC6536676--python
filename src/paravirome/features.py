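"""Annotated gene features shared across modules.

A :class:`GeneFeature` is one annotated gene with 1-based inclusive
coordinates, a strand, a functional-module category (the closed
vocabulary used by the completeness screen) and a free-text product.
Categories are consumed from GFF3 ``module_category`` attributes;
annotation itself is upstream of this package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["GeneFeature", "MODULE_CATEGORIES", "MODULE_KEYWORDS", "categorize_product"]

MODULE_CATEGORIES = {
    "integration", "lysogeny_switch", "replication", "packaging",
    "head_tail", "lysis", "mtase", "parB_like", "terminase_large", "other",
}


@dataclass
class GeneFeature:
    """One annotated gene (or tRNA) on a replicon."""

    id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    feature_type: str = "CDS"  # "CDS" or "tRNA"
    module_category: str = "other"
    product: str = ""
    disrupted: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature {self.id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.id}: strand must be + or -")
        if self.module_category not in MODULE_CATEGORIES:
            raise ValueError(f"feature {self.id}: unknown module category {self.module_category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def shifted(self, offset: int) -> "GeneFeature":
        return GeneFeature(
            self.id, self.contig, self.start + offset, self.end + offset,
            self.strand, self.feature_type, self.module_category, self.product,
            self.disrupted,
        )


# Convenience keyword table mapping product text to module categories;
# shipped as a default, overridable by the caller.  Order matters: the
# first matching pattern wins, so more specific phage vocabulary comes
# before generic words.
MODULE_KEYWORDS: list[tuple[str, str]] = [
    (r"terminase large", "terminase_large"),
    (r"parb", "parB_like"),
    (r"methyltransferase|mtase", "mtase"),
    (r"integrase|recombinase|transposase", "integration"),
    (r"\bcI\b|\bcro\b|xre|repressor", "lysogeny_switch"),
    (r"terminase|portal|packaging", "packaging"),
    (r"capsid|head|tail|baseplate|sheath|connector", "head_tail"),
    (r"endolysin|holin|lysin|amidase|muramidase", "lysis"),
    (r"replication|primase|helicase|polymerase", "replication"),
]


def categorize_product(product: str, keywords: list[tuple[str, str]] | None = None) -> str:
    """Map free-text product annotation to a module category."""
    table = MODULE_KEYWORDS if keywords is None else keywords
    for pattern, category in table:
        if re.search(pattern, product, flags=re.IGNORECASE):
            return category
    return "other"
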