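"""Virome catalog: loading, validation and census statistics.

The catalog is a flat TSV with one row per virome member -- an induced
(active) temperate phage, an in-silico predicted prophage, or a lytic
phage known only from culture work.  Each row records host strain, family
(*Siphoviridae*, *Myoviridae*, *Podoviridae*), lifestyle, integration
strategy (tyrosine recombinase, serine recombinase or Mu-like
transposase), the integration site, genome size / GC / gene count, and
replicon coordinates where the element sits in its host genome.

All census operations (virome size, lysogen and polylysogen counts,
family tallies, integration-site tallies) are pure functions over a list
of :class:`CatalogEntry`.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path

__all__ = [
    "CatalogEntry",
    "CatalogParseError",
    "CatalogValidationError",
    "default_catalog_path",
    "load_catalog",
    "read_catalog",
    "write_catalog",
    "virome_size",
    "count_lysogens",
    "polylysogen_census",
    "tally_by_family",
    "tally_integration_sites",
    "tally_integration_strategies",
    "genome_size_from_coords",
    "cross_validate_sizes",
    "normalize_site_name",
]

FAMILIES = {"Siphoviridae", "Myoviridae", "Podoviridae", "unclassified"}
LIFESTYLES = {"induced_active", "insilico_prophage", "lytic"}
STRATEGIES = {"tyr", "ser", "tnp", "unknown"}
SITE_CLASSES = {"tRNA", "gene_disruption", "intergenic", "other_gene", "not_identified"}

_COLUMNS = [
    "name", "host_strain", "family", "lifestyle", "previously_described",
    "integration_strategy", "integration_site_class", "integration_site_name",
    "genome_size", "gc_percent", "gene_count",
    "replicon_accession", "start", "end",
    "replicon_accession_2", "start_2", "end_2",
    "attB_core",
]


class CatalogParseError(ValueError):
    """A row could not be parsed at all (names the offending line)."""


class CatalogValidationError(ValueError):
    """Parsed rows violate catalog invariants."""


@dataclass
class CatalogEntry:
    """One virome member (a phage or prophage)."""

    name: str
    host_strain: str | None
    family: str
    lifestyle: str
    previously_described: bool
    integration_strategy: str = "unknown"
    integration_site_class: str = "not_identified"
    integration_site_name: str | None = None
    genome_size: int | None = None
    gc_percent: float | None = None
    gene_count: int | None = None
    replicon_accession: str | None = None
    start: int | None = None
    end: int | None = None
    replicon_accession_2: str | None = None
    start_2: int | None = None
    end_2: int | None = None
    attB_core: str | None = None

    @property
    def is_multi_contig(self) -> bool:
        return self.replicon_accession_2 is not None

    @property
    def has_coordinates(self) -> bool:
        return self.start is not None and self.end is not None


_TRNA_RE = re.compile(
    r"^tRNA[-_ ]*([A-Za-z]{3})[-_ ]*\(?([A-Za-z]{3})\)?$", re.IGNORECASE
)


def normalize_site_name(name: str) -> str:
    """Canonicalize an integration-site name for tallying.

    tRNA sites become ``tRNA-Xaa(ANT)`` regardless of the punctuation of
    the input (``tRNA_Met_(CAT)`` and ``trna-met(cat)`` both map to
    ``tRNA-Met(CAT)``); distinct anticodons stay distinct.  Non-tRNA site
    names are whitespace-collapsed and casefolded so tallies merge
    case variants.
    """
    name = " ".join(name.split())
    m = _TRNA_RE.match(name)
    if m:
        aa, anticodon = m.groups()
        return f"tRNA-{aa.capitalize()}({anticodon.upper()})"
    return name.casefold()


def default_catalog_path() -> Path:
    """Path of the packaged virome catalog fixture."""
    return Path(resources.files("paravirome").joinpath("data/paracoccus_virome_catalog.tsv"))


def _parse_row(row: dict[str, str], lineno: int) -> CatalogEntry:
    def opt(key: str) -> str | None:
        v = (row.get(key) or "").strip()
        return v or None

    def opt_int(key: str) -> int | None:
        v = opt(key)
        if v is None:
            return None
        try:
            return int(v.replace(",", ""))
        except ValueError:
            raise CatalogParseError(f"line {lineno}: column {key!r}: not an integer: {v!r}")

    def opt_float(key: str) -> float | None:
        v = opt(key)
        if v is None:
            return None
        try:
            return float(v)
        except ValueError:
            raise CatalogParseError(f"line {lineno}: column {key!r}: not a number: {v!r}")

    name = opt("name")
    if name is None:
        raise CatalogParseError(f"line {lineno}: missing entry name")
    prev = (row.get("previously_described") or "false").strip().lower()
    if prev not in {"true", "false"}:
        raise CatalogParseError(f"line {lineno}: previously_described must be true/false, got {prev!r}")
    return CatalogEntry(
        name=name,
        host_strain=opt("host_strain"),
        family=opt("family") or "unclassified",
        lifestyle=opt("lifestyle") or "",
        previously_described=prev == "true",
        integration_strategy=opt("integration_strategy") or "unknown",
        integration_site_class=opt("integration_site_class") or "not_identified",
        integration_site_name=opt("integration_site_name"),
        genome_size=opt_int("genome_size"),
        gc_percent=opt_float("gc_percent"),
        gene_count=opt_int("gene_count"),
        replicon_accession=opt("replicon_accession"),
        start=opt_int("start"),
        end=opt_int("end"),
        replicon_accession_2=opt("replicon_accession_2"),
        start_2=opt_int("start_2"),
        end_2=opt_int("end_2"),
        attB_core=opt("attB_core"),
    )


def validate_entries(entries: list[CatalogEntry]) -> list[str]:
    """Collect invariant violations; never drops entries."""
    issues: list[str] = []
    seen: set[str] = set()
    for e in entries:
        where = f"entry {e.name!r}"
        if e.name in seen:
            issues.append(f"{where}: duplicate name")
        seen.add(e.name)
        if e.family not in FAMILIES:
            issues.append(f"{where}: unknown family {e.family!r}")
        if e.lifestyle not in LIFESTYLES:
            issues.append(f"{where}: unknown lifestyle {e.lifestyle!r}")
        if e.integration_strategy not in STRATEGIES:
            issues.append(f"{where}: unknown integration strategy {e.integration_strategy!r}")
        if e.integration_site_class not in SITE_CLASSES:
            issues.append(f"{where}: unknown site class {e.integration_site_class!r}")
        if e.genome_size is not None and e.genome_size <= 0:
            issues.append(f"{where}: genome_size must be > 0")
        if e.gc_percent is not None and not (0.0 <= e.gc_percent <= 100.0):
            issues.append(f"{where}: gc_percent outside [0, 100]")
        for s, t in ((e.start, e.end), (e.start_2, e.end_2)):
            if s is not None and t is not None and s > t:
                issues.append(f"{where}: start > end ({s} > {t})")
        if e.lifestyle == "lytic":
            if e.integration_strategy != "unknown" or e.integration_site_name:
                issues.append(f"{where}: lytic entries carry no integration metadata")
        if e.lifestyle == "insilico_prophage" and not e.host_strain:
            issues.append(f"{where}: in-silico prophage without a host strain")
    return issues


def read_catalog(path: str | Path) -> tuple[list[CatalogEntry], list[str]]:
    """Parse a catalog TSV; return ``(entries, validation_issues)``.

    Raises :class:`CatalogParseError` on rows that cannot be parsed at
    all; invariant violations are reported, not silently dropped.
    """
    path = Path(path)
    entries: list[CatalogEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise CatalogParseError(f"{path}: empty file (no header)")
        missing = [c for c in _COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CatalogParseError(f"{path}: header missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            if row.get(None):
                raise CatalogParseError(f"line {lineno}: too many fields")
            entries.append(_parse_row(row, lineno))
    return entries, validate_entries(entries)


def load_catalog(path: str | Path | None = None) -> list[CatalogEntry]:
    """Load and validate a catalog (the packaged fixture by default)."""
    if path is None:
        path = default_catalog_path()
    entries, issues = read_catalog(path)
    if issues:
        raise CatalogValidationError("; ".join(issues))
    return entries


def write_catalog(entries: list[CatalogEntry], path: str | Path) -> None:
    """Write entries back to the documented TSV schema (round-trip safe)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for e in entries:
            row = []
            for f in dc_fields(e):
                v = getattr(e, f.name)
                if v is None:
                    row.append("")
                elif isinstance(v, bool):
                    row.append("true" if v else "false")
                else:
                    row.append(str(v))
            writer.writerow(row)


# ---------------------------------------------------------------------------
# census statistics
# ---------------------------------------------------------------------------

def _subset(entries: list[CatalogEntry], lifestyle: str | None) -> list[CatalogEntry]:
    if lifestyle is None:
        return entries
    if lifestyle not in LIFESTYLES:
        raise ValueError(f"unknown lifestyle filter {lifestyle!r}")
    return [e for e in entries if e.lifestyle == lifestyle]


def virome_size(entries: list[CatalogEntry], lifestyle: str | None = None) -> int:
    """Number of unique virome members, optionally restricted by lifestyle."""
    return len({e.name for e in _subset(entries, lifestyle)})


def count_lysogens(entries: list[CatalogEntry]) -> int:
    """Distinct host strains carrying at least one in-silico prophage."""
    return len({e.host_strain for e in entries if e.lifestyle == "insilico_prophage"})


def polylysogen_census(entries: list[CatalogEntry]) -> tuple[dict[str, int], int]:
    """Per-host prophage counts plus the number of polylysogens (>= 2)."""
    hist = Counter(
        e.host_strain for e in entries if e.lifestyle == "insilico_prophage"
    )
    poly = sum(1 for n in hist.values() if n >= 2)
    return dict(hist), poly


def tally_by_family(entries: list[CatalogEntry], lifestyle: str | None = None) -> dict[str, int]:
    """Family counts over the (optionally lifestyle-filtered) subset."""
    return dict(Counter(e.family for e in _subset(entries, lifestyle)))


def tally_integration_sites(
    entries: list[CatalogEntry], include_active: bool = False
) -> dict[str, int]:
    """Counts of normalized integration-site names among prophages.

    By default only in-silico prophages are counted; ``include_active``
    adds the induced active phages (their att sites were mapped onto the
    host chromosomes they were induced from).  Entries whose site was not
    identified are excluded.
    """
    lifestyles = {"insilico_prophage"}
    if include_active:
        lifestyles.add("induced_active")
    tally: Counter[str] = Counter()
    for e in entries:
        if e.lifestyle not in lifestyles:
            continue
        if e.integration_site_class == "not_identified" or not e.integration_site_name:
            continue
        tally[normalize_site_name(e.integration_site_name)] += 1
    return dict(tally)


def tally_integration_strategies(
    entries: list[CatalogEntry], lifestyle: str | None = "insilico_prophage"
) -> dict[str, int]:
    """Recombinase-class counts (tyr / ser / tnp) over the subset."""
    return dict(
        Counter(
            e.integration_strategy
            for e in _subset(entries, lifestyle)
            if e.integration_strategy != "unknown"
        )
    )


def genome_size_from_coords(start: int, end: int) -> int:
    """Span of a 1-based inclusive coordinate interval."""
    if start < 1 or end < 1:
        raise ValueError("coordinates are 1-based; must be >= 1")
    if start > end:
        raise ValueError(f"start > end ({start} > {end})")
    return end - start + 1


def cross_validate_sizes(
    entries: list[CatalogEntry],
) -> list[tuple[str, int, int]]:
    """Audit stated genome sizes against replicon coordinates.

    Returns ``(name, stated_size, size_from_coords)`` for every
    single-contig entry whose coordinate span disagrees with its stated
    genome size.  Multi-contig entries and entries without coordinates
    are skipped.  Reports, never raises.
    """
    mismatches = []
    for e in entries:
        if not e.has_coordinates or e.is_multi_contig or e.genome_size is None:
            continue
        span = genome_size_from_coords(e.start, e.end)
        if span != e.genome_size:
            mismatches.append((e.name, e.genome_size, span))
    return mismatches
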