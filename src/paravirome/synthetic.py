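"""Synthetic host genomes with planted prophages and machine-readable truth.

The generator emulates the situation the downstream stages are built
for: a bacterial replicon at a characteristic GC content (Paracoccus
replicons sit around 60-68% GC), tRNA genes, and a modular temperate
phage cassette inserted at a target site with a duplicated att core --
the upstream copy completing an intact tRNA gene when the target is a
tRNA 3' end.  Prophage cassettes get their own (usually lower) GC so
that boundary refinement by GC contrast is testable, and proteome
generators plant homolog pairs at controlled identity so that network
thresholds are testable.

Sequences are i.i.d. with per-base probabilities set from the GC
target; no repeat structure is injected except the planted att cores,
which keeps the direct-repeat recovery oracle clean.  Everything is
bit-reproducible given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import GeneFeature, MODULE_CATEGORIES

__all__ = [
    "HostGenomeSpec",
    "ProphageSpec",
    "PlantedTruth",
    "random_sequence",
    "random_protein",
    "generate_host_genome",
    "build_prophage",
    "simulate_integration",
    "mutate_to_identity",
    "generate_proteome_clusters",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

REQUIRED_MODULES = ("integration", "lysogeny_switch", "replication", "packaging", "head_tail", "lysis")
DEFAULT_MODULE_LAYOUT: list[tuple[str, int]] = [
    ("integration", 1),
    ("lysogeny_switch", 2),
    ("replication", 2),
    ("packaging", 2),
    ("head_tail", 4),
    ("lysis", 2),
]


@dataclass(frozen=True)
class HostGenomeSpec:
    """A host replicon: length, GC target, tRNA genes and CDS density."""

    length: int = 50_000
    gc_target: float = 63.0
    trna_genes: tuple[tuple[int, int, str], ...] = ()  # (start, length, name)
    cds_density: float = 0.8  # genes per kb
    def __post_init__(self):
        if not (0.0 <= self.gc_target <= 100.0):
            raise ValueError("gc_target must be within [0, 100]")
        if self.length < 1:
            raise ValueError("length must be positive")
        last_end = 0
        for start, length, _name in sorted(self.trna_genes):
            if start < 1 or start + length - 1 > self.length:
                raise ValueError("tRNA gene outside the replicon")
            if start <= last_end:
                raise ValueError("overlapping tRNA genes")
            last_end = start + length - 1


@dataclass(frozen=True)
class ProphageSpec:
    """A modular temperate-phage cassette to be planted into a host."""

    length: int = 40_000
    gc_target: float = 58.0
    module_layout: tuple[tuple[str, int], ...] = tuple(DEFAULT_MODULE_LAYOUT)
    att_core_length: int = 20
    integrase_class: str = "tyr"

    def __post_init__(self):
        if self.att_core_length < 0:
            raise ValueError("att_core_length must be >= 0")
        seen = set()
        for category, count in self.module_layout:
            if category not in MODULE_CATEGORIES:
                raise ValueError(f"unknown module category {category!r}")
            if count < 1:
                raise ValueError("module gene counts must be >= 1")
            if category in seen:
                raise ValueError(f"module {category!r} listed twice")
            seen.add(category)
        if self.integrase_class not in {"tyr", "ser", "tnp"}:
            raise ValueError("integrase_class must be tyr, ser or tnp")


@dataclass
class PlantedTruth:
    """Ground truth for one simulated integration (1-based inclusive)."""

    prophage_interval: tuple[int, int]
    attL_interval: tuple[int, int] | None
    attR_interval: tuple[int, int] | None
    att_core: str
    target_feature: str  # feature id or "intergenic"
    site_class: str
    gene_modules: dict[str, str] = field(default_factory=dict)


def random_sequence(length: int, gc_percent: float, rng: np.random.Generator) -> str:
    """i.i.d. nucleotides with P(G) = P(C) = gc/2."""
    g = gc_percent / 200.0
    a = (100.0 - gc_percent) / 200.0
    codes = rng.choice(4, size=length, p=[a, g, g, a])
    return _BASES[codes].tobytes().decode("ascii")


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_host_genome(
    spec: HostGenomeSpec, seed: int, contig: str = "host"
) -> tuple[str, list[GeneFeature]]:
    """Random replicon with the spec's tRNA genes plus background CDS.

    CDS are placed uniformly in the space between tRNA genes at
    ``cds_density`` genes per kb with random lengths of 300-1500 bp;
    placement failures (no room) raise rather than silently dropping
    features.
    """
    rng = np.random.default_rng(seed)
    seq = random_sequence(spec.length, spec.gc_target, rng)
    features: list[GeneFeature] = []
    occupied: list[tuple[int, int]] = []
    for i, (start, length, name) in enumerate(sorted(spec.trna_genes)):
        end = start + length - 1
        strand = "+" if name.endswith("+") or not name.endswith("-") else "-"
        features.append(
            GeneFeature(
                id=f"trna_{i + 1}", contig=contig, start=start, end=end,
                strand=strand, feature_type="tRNA", product=name.rstrip("+-"),
            )
        )
        occupied.append((start, end))

    n_cds = int(round(spec.cds_density * spec.length / 1000.0))
    attempts = 0
    placed = 0
    while placed < n_cds:
        attempts += 1
        if attempts > 50 * max(n_cds, 1):
            raise RuntimeError("could not place CDS features without overlap; lower cds_density")
        length = int(rng.integers(300, 1501))
        start = int(rng.integers(1, max(2, spec.length - length)))
        end = start + length - 1
        if any(s <= end and start <= e for s, e in occupied):
            continue
        occupied.append((start, end))
        placed += 1
        features.append(
            GeneFeature(
                id=f"cds_{placed}", contig=contig, start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-",
                product="hypothetical protein",
            )
        )
    features.sort(key=lambda f: f.start)
    return seq, features


def build_prophage(
    spec: ProphageSpec, seed: int, contig: str = "prophage"
) -> tuple[str, list[GeneFeature]]:
    """Cassette sequence plus module-labeled gene features (local coords)."""
    rng = np.random.default_rng(seed)
    seq = random_sequence(spec.length, spec.gc_target, rng)
    n_genes = sum(count for _, count in spec.module_layout)
    gap = 50
    gene_len = max(120, (spec.length - gap * (n_genes + 1)) // max(n_genes, 1))
    features: list[GeneFeature] = []
    pos = gap + 1
    idx = 0
    for category, count in spec.module_layout:
        for k in range(count):
            idx += 1
            end = min(pos + gene_len - 1, spec.length)
            if pos > spec.length:
                raise ValueError("prophage too short for the requested module layout")
            product = f"{category} protein {k + 1}"
            if category == "integration" and k == 0:
                product = {
                    "tyr": "tyrosine recombinase (integrase)",
                    "ser": "serine recombinase (integrase)",
                    "tnp": "Mu-like transposase",
                }[spec.integrase_class]
            features.append(
                GeneFeature(
                    id=f"phage_{idx:03d}", contig=contig, start=pos, end=end,
                    strand="+", module_category=category, product=product,
                )
            )
            pos = end + gap + 1
    return seq, features


def simulate_integration(
    host_seq: str,
    host_features: list[GeneFeature],
    prophage_spec: ProphageSpec,
    target_feature: str,
    seed: int,
    contig: str = "lysogen",
) -> tuple[str, list[GeneFeature], PlantedTruth]:
    """Plant the cassette at a target with an exact duplicated att core.

    ``target_feature`` is the id of a tRNA gene (3'-end integration,
    reconstituting an intact copy), the id of a CDS (gene disruption),
    or ``"intergenic"``.  The att core is host sequence: the
    3'-terminal ``att_core_length`` bases of the tRNA for the tRNA
    case, the bases immediately 5' of the insertion point otherwise.
    """
    L = prophage_spec.att_core_length
    phage_seq, phage_features = build_prophage(prophage_spec, seed + 1, contig=contig)
    P = len(phage_seq)
    rng = np.random.default_rng(seed)

    by_id = {f.id: f for f in host_features}
    if target_feature == "intergenic":
        occupied = sorted((f.start, f.end) for f in host_features)
        gaps = []
        prev = 1
        for s, e in occupied:
            if s - prev > 2 * L + 100:
                gaps.append((prev + L, s - L - 1))
            prev = max(prev, e + 1)
        if len(host_seq) - prev > 2 * L + 100:
            gaps.append((prev + L, len(host_seq) - L))
        if not gaps:
            raise ValueError("no intergenic space wide enough for insertion")
        g = gaps[int(rng.integers(0, len(gaps)))]
        insert_after = int(rng.integers(g[0], g[1] + 1))
        site_class = "intergenic"
    else:
        feat = by_id[target_feature]
        if feat.length < max(L, 1):
            raise ValueError(f"target feature {target_feature} shorter than att core length")
        if feat.feature_type == "tRNA":
            site_class = "tRNA"
            # insertion immediately after the 3' terminus (plus strand) or
            # immediately before it (minus strand, genomic-left 3' end)
            insert_after = feat.end if feat.strand == "+" else feat.start - 1
        else:
            site_class = "gene_disruption"
            insert_after = (feat.start + feat.end) // 2

    def _break_extension(seq: str, pos: int, forbidden: str) -> str:
        """Force seq[pos] != forbidden so the planted repeat is exactly
        maximal (chance extension would make the truth core ill-defined)."""
        if not forbidden or seq[pos] != forbidden:
            return seq
        alt = [b for b in "ACGT" if b != forbidden]
        repl = alt[int(rng.integers(0, len(alt)))]
        return seq[:pos] + repl + seq[pos + 1 :]

    if site_class == "tRNA" and by_id[target_feature].strand == "-":
        core = host_seq[insert_after : insert_after + L] if L else ""
        if L:
            before = host_seq[insert_after - 1] if insert_after >= 1 else ""
            after = host_seq[insert_after + L] if insert_after + L < len(host_seq) else ""
            phage_seq = _break_extension(phage_seq, len(phage_seq) - 1, before)
            phage_seq = _break_extension(phage_seq, 0, after)
            P = len(phage_seq)
        lysogen = host_seq[:insert_after] + core + phage_seq + host_seq[insert_after:]
        attL = (insert_after + 1, insert_after + L) if L else None
        attR = (insert_after + L + P + 1, insert_after + 2 * L + P) if L else None
        cassette = (insert_after + 1, insert_after + L + P + (L if L else 0))
    else:
        core = host_seq[insert_after - L : insert_after] if L else ""
        if L:
            before = host_seq[insert_after - L - 1] if insert_after - L >= 1 else ""
            after = host_seq[insert_after] if insert_after < len(host_seq) else ""
            phage_seq = _break_extension(phage_seq, len(phage_seq) - 1, before)
            phage_seq = _break_extension(phage_seq, 0, after)
            P = len(phage_seq)
        lysogen = host_seq[:insert_after] + phage_seq + core + host_seq[insert_after:]
        attL = (insert_after - L + 1, insert_after) if L else None
        attR = (insert_after + P + 1, insert_after + P + L) if L else None
        cassette = (
            (attL[0], attR[1]) if L else (insert_after + 1, insert_after + P)
        )

    offset = P + L
    lys_features: list[GeneFeature] = []
    for f in host_features:
        g = GeneFeature(f.id, contig, f.start, f.end, f.strand, f.feature_type,
                        f.module_category, f.product, f.disrupted)
        if f.start > insert_after:
            g = g.shifted(offset)
        elif f.end > insert_after:  # feature straddles the insertion point
            g.end = insert_after
            g.disrupted = True
            g.product = (g.product + " (disrupted by prophage insertion)").strip()
        lys_features.append(g)
    phage_offset = insert_after + (L if site_class == "tRNA" and by_id[target_feature].strand == "-" else 0)
    gene_modules: dict[str, str] = {}
    for f in phage_features:
        g = f.shifted(phage_offset)
        g.contig = contig
        lys_features.append(g)
        gene_modules[g.id] = g.module_category
    lys_features.sort(key=lambda f: (f.start, f.id))

    truth = PlantedTruth(
        prophage_interval=cassette,
        attL_interval=attL,
        attR_interval=attR,
        att_core=core,
        target_feature=target_feature,
        site_class=site_class,
        gene_modules=gene_modules,
    )
    return lysogen, lys_features, truth


def mutate_to_identity(
    sequence: str,
    target_identity: float,
    seed: int,
    alphabet: str = AMINO_ACIDS,
) -> str:
    """Point-substitute to a target percent identity (length preserved).

    Exactly ``round(L * (1 - t/100))`` positions are substituted with a
    different symbol, so the realized position-wise identity equals the
    target up to rounding.
    """
    if not (0.0 <= target_identity <= 100.0):
        raise ValueError("target_identity must be within [0, 100]")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    k = int(round(n * (1.0 - target_identity / 100.0)))
    if k == 0:
        return sequence
    positions = rng.choice(n, size=k, replace=False)
    out = list(sequence)
    for p in positions:
        choices = [c for c in alphabet if c != out[p]]
        out[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def generate_proteome_clusters(
    n_phages: int,
    shared_matrix: np.ndarray | list[list[int]],
    identity_levels: float | np.ndarray = 100.0,
    seed: int = 0,
    n_background: int = 5,
    protein_length: int = 250,
) -> tuple[dict[str, dict[str, str]], list[dict]]:
    """Per-phage proteomes with planted homolog pairs.

    Phage pair (i, j) shares exactly ``shared_matrix[i][j]`` planted
    homolog pairs at the stated identity level; all other proteins are
    mutually unrelated random sequences.  Returns ``(proteomes, truth)``
    where proteomes maps phage -> {protein_id: sequence} and truth is a
    list of planted-pair records sufficient to score edge recovery.
    """
    shared = np.asarray(shared_matrix, dtype=int)
    if shared.shape != (n_phages, n_phages) or not np.array_equal(shared, shared.T):
        raise ValueError("shared_matrix must be a symmetric n_phages x n_phages matrix")
    if (shared < 0).any():
        raise ValueError("shared_matrix must be non-negative")
    ident = np.asarray(identity_levels, dtype=float)
    if ident.ndim == 0:
        ident = np.full((n_phages, n_phages), float(ident))
    rng = np.random.default_rng(seed)
    names = [f"phage{i + 1}" for i in range(n_phages)]
    proteomes: dict[str, dict[str, str]] = {n: {} for n in names}
    counters = {n: 0 for n in names}
    truth: list[dict] = []

    def add(phage: str, seq: str) -> str:
        counters[phage] += 1
        pid = f"{phage}|p{counters[phage]:03d}"
        proteomes[phage][pid] = seq
        return pid

    for i in range(n_phages):
        for j in range(i + 1, n_phages):
            for _ in range(int(shared[i, j])):
                base = random_protein(protein_length, rng)
                pid_i = add(names[i], base)
                sub_seed = int(rng.integers(0, 2**31 - 1))
                pid_j = add(names[j], mutate_to_identity(base, ident[i, j], sub_seed))
                truth.append(
                    {"phage_a": names[i], "protein_a": pid_i,
                     "phage_b": names[j], "protein_b": pid_j,
                     "identity": float(ident[i, j])}
                )
    for name in names:
        for _ in range(n_background):
            add(name, random_protein(protein_length, rng))
    return proteomes, truth
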