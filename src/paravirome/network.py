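"""Gene-sharing and marker similarity networks of (pro)phages.

Nodes are (pro)phages (or, for the protein-identity network, single
proteins); an edge connects two phages when at least one protein pair
is reciprocally similar under the thresholds (E-value 1e-10, HSP query
coverage >= 75%, identity >= 80% by default), and the edge weight is
the number of such reciprocal one-to-one pairs.  Components and
degree-0 orphans summarize the clustering; graphs are exported to
GraphML / GEXF / TSV rather than laid out.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .align import AlignmentHit, ScoringParams, evalue, local_align

__all__ = [
    "Thresholds",
    "reciprocal_pairs",
    "build_phage_network",
    "build_marker_network",
    "build_protein_identity_network",
    "components_and_orphans",
    "export_network",
    "load_network",
]


@dataclass(frozen=True)
class Thresholds:
    """Reciprocal-similarity thresholds for network edges."""

    evalue_max: float = 1e-10
    query_coverage_min: float = 75.0
    identity_min: float = 80.0

    def __post_init__(self):
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        for v in (self.query_coverage_min, self.identity_min):
            if not (0.0 <= v <= 100.0):
                raise ValueError("coverage and identity thresholds must be within [0, 100]")


def _pair_passes(
    seq_a: str,
    seq_b: str,
    hit: AlignmentHit,
    thresholds: Thresholds,
    space_ab: int,
    space_ba: int,
) -> bool:
    """Reciprocity from a single exact DP: the optimal local alignment is
    direction-independent, so the two directions differ only in which
    side coverage and the E-value m are computed on."""
    if hit.identity_percent < thresholds.identity_min:
        return False
    cov_a = 100.0 * (hit.query_end - hit.query_start + 1) / len(seq_a)
    cov_b = 100.0 * (hit.subject_end - hit.subject_start + 1) / len(seq_b)
    if cov_a < thresholds.query_coverage_min or cov_b < thresholds.query_coverage_min:
        return False
    e_ab = evalue(hit.bit_score, len(seq_a), space_ab)
    e_ba = evalue(hit.bit_score, len(seq_b), space_ba)
    return e_ab <= thresholds.evalue_max and e_ba <= thresholds.evalue_max


def reciprocal_pairs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams | None = None,
) -> list[tuple[str, str]]:
    """One-to-one reciprocally similar protein pairs between two proteomes.

    A pair qualifies when the alignment passes the identity threshold
    and passes coverage and E-value in both directions (coverage on the
    respective query; E-value with the database convention, n = total
    residues of the other proteome).  Candidates are resolved to a
    one-to-one matching greedily by descending bit score.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    params = params or ScoringParams.protein()
    space_ab = sum(len(s) for s in proteome_b.values())
    space_ba = sum(len(s) for s in proteome_a.values())
    candidates: list[tuple[float, str, str]] = []
    for id_a, seq_a in proteome_a.items():
        for id_b, seq_b in proteome_b.items():
            hit = local_align(seq_a, seq_b, params, id_a, id_b)
            if hit is None:
                continue
            if _pair_passes(seq_a, seq_b, hit, thresholds, space_ab, space_ba):
                candidates.append((hit.bit_score, id_a, id_b))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for _, id_a, id_b in candidates:
        if id_a in used_a or id_b in used_b:
            continue
        used_a.add(id_a)
        used_b.add(id_b)
        pairs.append((id_a, id_b))
    return pairs


def build_phage_network(
    proteomes: dict[str, dict[str, str]],
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams | None = None,
    node_attrs: dict[str, dict] | None = None,
) -> nx.Graph:
    """Whole-proteome gene-sharing network.

    Edge weight = number of reciprocal one-to-one protein pairs; the
    matched pairs are kept on the edge (``pairs`` attribute,
    ';'-joined) so the weight is auditable.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    params = params or ScoringParams.protein()
    g = nx.Graph()
    for phage in sorted(proteomes):
        g.add_node(phage, **(node_attrs or {}).get(phage, {}))
    for a, b in itertools.combinations(sorted(proteomes), 2):
        pairs = reciprocal_pairs(proteomes[a], proteomes[b], thresholds, params)
        if pairs:
            g.add_edge(a, b, weight=len(pairs), pairs=";".join(f"{x}~{y}" for x, y in pairs))
    return g


def build_marker_network(
    marker_map: dict[str, tuple[str, str] | None],
    thresholds: Thresholds = Thresholds(),
    params: ScoringParams | None = None,
) -> nx.Graph:
    """Single-marker network (integrase, large terminase, major capsid).

    ``marker_map`` maps each phage to its (protein id, sequence) marker
    or ``None``; phages missing the marker stay as flagged isolated
    nodes.  Edges have weight 1.
    """
    params = params or ScoringParams.protein()
    g = nx.Graph()
    for phage in sorted(marker_map):
        g.add_node(phage, missing_marker=marker_map[phage] is None)
    present = [(p, m) for p, m in sorted(marker_map.items()) if m is not None]
    for (pa, (ida, sa)), (pb, (idb, sb)) in itertools.combinations(present, 2):
        hit = local_align(sa, sb, params, ida, idb)
        if hit is None:
            continue
        if _pair_passes(sa, sb, hit, thresholds, len(sb), len(sa)):
            g.add_edge(pa, pb, weight=1, pairs=f"{ida}~{idb}")
    return g


def build_protein_identity_network(
    proteins: dict[str, str],
    identity_min: float = 80.0,
    coverage_min: float = 75.0,
    params: ScoringParams | None = None,
    labels: dict[str, dict] | None = None,
) -> nx.Graph:
    """Protein-level identity network (e.g. MTases by methylation target).

    An edge requires identity >= ``identity_min`` over an alignment
    covering at least ``coverage_min`` percent of the shorter sequence.
    """
    if not proteins:
        raise ValueError("protein set must be non-empty")
    params = params or ScoringParams.protein()
    g = nx.Graph()
    for pid in sorted(proteins):
        g.add_node(pid, **(labels or {}).get(pid, {}))
    for a, b in itertools.combinations(sorted(proteins), 2):
        hit = local_align(proteins[a], proteins[b], params, a, b)
        if hit is None or hit.identity_percent < identity_min:
            continue
        span_a = hit.query_end - hit.query_start + 1
        span_b = hit.subject_end - hit.subject_start + 1
        if len(proteins[a]) <= len(proteins[b]):  # coverage on the shorter side
            cov = 100.0 * span_a / len(proteins[a])
        else:
            cov = 100.0 * span_b / len(proteins[b])
        if cov >= coverage_min:
            g.add_edge(a, b, weight=1, identity=round(hit.identity_percent, 2))
    return g


def components_and_orphans(network: nx.Graph) -> tuple[list[set[str]], list[str]]:
    """Connected components (size >= 2) and degree-0 orphan nodes."""
    comps = [set(c) for c in nx.connected_components(network)]
    orphans = sorted(n for n in network.nodes if network.degree[n] == 0)
    clusters = sorted((c for c in comps if len(c) >= 2), key=lambda c: (-len(c), sorted(c)[0]))
    return clusters, orphans


_FORMATS = {"graphml", "gexf", "tsv"}


def export_network(network: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network; GraphML and GEXF round-trip losslessly."""
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "gexf":
        nx.write_gexf(network, path)
    elif fmt == "tsv":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\tpairs\n")
            for a, b, data in sorted(network.edges(data=True)):
                fh.write(f"{a}\t{b}\t{data.get('weight', 1)}\t{data.get('pairs', '')}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}; choose from {sorted(_FORMATS)}")


def load_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    fmt = fmt.lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gexf":
        g = nx.read_gexf(path)
        # GEXF serializes edge weights as floats; restore integral counts
        for _, _, data in g.edges(data=True):
            w = data.get("weight")
            if isinstance(w, float) and w.is_integer():
                data["weight"] = int(w)
        return g
    raise ValueError(f"cannot re-load format {fmt!r} (only graphml/gexf round-trip)")
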