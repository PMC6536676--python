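"""All-vs-all nucleotide comparison with identity ribbons.

Every unordered pair of (pro)phage genomes is compared on both strands
with greedy non-overlapping HSPs, filtered at a stringent E-value
(1e-100 by default, so only substantial regions of high similarity
survive).  Hits carry an identity bin for ribbon-style colouring, and
genomes are classified as unique (no hits at all), near-identical to a
partner (>= 99% identity HSPs covering >= 95% of both genomes), or
showing only local similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import ScoringParams, evalue, find_hsps

__all__ = [
    "RibbonHit",
    "RelationshipCall",
    "IDENTITY_BINS",
    "identity_bin",
    "all_vs_all_genomes",
    "classify_relationships",
    "hit_frequency_profile",
]

# bin edges partition [0, 100]; labels follow ribbon-colour convention
IDENTITY_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 85.0, "<85"),
    (85.0, 95.0, "85-95"),
    (95.0, 99.0, "95-99"),
    (99.0, 100.0001, ">=99"),
)

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def identity_bin(identity_percent: float, bins=IDENTITY_BINS) -> str:
    for lo, hi, label in bins:
        if lo <= identity_percent < hi:
            return label
    raise ValueError(f"identity {identity_percent} outside [0, 100]")


@dataclass
class RibbonHit:
    """One local similarity region between two genomes (1-based inclusive)."""

    genome_a: str
    genome_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity_percent: float
    bit_score: float
    evalue: float
    strand: str
    identity_bin: str

    def touches(self, genome: str) -> tuple[int, int] | None:
        if genome == self.genome_a:
            return self.a_start, self.a_end
        if genome == self.genome_b:
            return self.b_start, self.b_end
        return None


def all_vs_all_genomes(
    genomes: dict[str, str],
    evalue_max: float = 1e-100,
    min_raw_score: int = 300,
    params: ScoringParams | None = None,
) -> list[RibbonHit]:
    """HSPs for every unordered genome pair on both strands.

    Self-comparisons are excluded.  ``min_raw_score`` defaults to 300,
    i.e. with the +2 match score the shortest reportable HSP at 100%
    identity is ~150 nt.  E-values use the database convention: n is
    the total length of all genomes other than the query.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    params = params or ScoringParams.nucleotide()
    total = sum(len(s) for s in genomes.values())
    names = sorted(genomes)
    hits: list[RibbonHit] = []
    for i, a in enumerate(names):
        space = total - len(genomes[a])
        for b in names[i + 1 :]:
            sb = genomes[b]
            for strand, subject in (("+", sb), ("-", _revcomp(sb))):
                for h in find_hsps(genomes[a], subject, params, min_raw_score,
                                   query_id=a, subject_id=b, search_space=space):
                    if h.evalue > evalue_max:
                        continue
                    if strand == "+":
                        bs, be = h.subject_start, h.subject_end
                    else:
                        bs = len(sb) - h.subject_end + 1
                        be = len(sb) - h.subject_start + 1
                    hits.append(
                        RibbonHit(
                            genome_a=a, genome_b=b,
                            a_start=h.query_start, a_end=h.query_end,
                            b_start=bs, b_end=be,
                            identity_percent=h.identity_percent,
                            bit_score=h.bit_score, evalue=h.evalue,
                            strand=strand,
                            identity_bin=identity_bin(h.identity_percent),
                        )
                    )
    return hits


@dataclass
class RelationshipCall:
    genome: str
    relationship: str  # unique | near_identical | local_similarity
    partners: list[str]


def _merged_span(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    span = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            span += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    return span + (cur_e - cur_s + 1)


def classify_relationships(
    genomes: dict[str, str],
    hits: list[RibbonHit],
    near_identity: float = 99.0,
    near_mutual_coverage: float = 95.0,
) -> list[RelationshipCall]:
    """unique / near_identical / local_similarity per genome.

    Near-identity requires a partner whose >= ``near_identity``%-identity
    HSPs cover at least ``near_mutual_coverage`` percent of *both*
    genomes (a symmetric criterion), so the class is reciprocal.
    """
    pair_hits: dict[tuple[str, str], list[RibbonHit]] = {}
    touched: set[str] = set()
    for h in hits:
        pair_hits.setdefault((h.genome_a, h.genome_b), []).append(h)
        touched.update((h.genome_a, h.genome_b))
    partners: dict[str, list[str]] = {g: [] for g in genomes}
    for (a, b), hs in pair_hits.items():
        good = [h for h in hs if h.identity_percent >= near_identity]
        cov_a = 100.0 * _merged_span([(h.a_start, h.a_end) for h in good]) / len(genomes[a])
        cov_b = 100.0 * _merged_span([(h.b_start, h.b_end) for h in good]) / len(genomes[b])
        if cov_a >= near_mutual_coverage and cov_b >= near_mutual_coverage:
            partners[a].append(b)
            partners[b].append(a)
    calls = []
    for g in sorted(genomes):
        if partners[g]:
            rel = "near_identical"
        elif g in touched:
            rel = "local_similarity"
        else:
            rel = "unique"
        calls.append(RelationshipCall(genome=g, relationship=rel, partners=sorted(partners[g])))
    return calls


def hit_frequency_profile(
    genome: str, genome_length: int, hits: list[RibbonHit], bin_size: int = 1000
) -> list[int]:
    """Per-window counts of HSPs overlapping each window of the genome."""
    if bin_size < 100:
        raise ValueError("bin_size must be >= 100")
    n_bins = (genome_length + bin_size - 1) // bin_size
    counts = [0] * n_bins
    for h in hits:
        iv = h.touches(genome)
        if iv is None:
            continue
        first = (iv[0] - 1) // bin_size
        last = (iv[1] - 1) // bin_size
        for k in range(first, min(last, n_bins - 1) + 1):
            counts[k] += 1
    return counts
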