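"""Attachment-site discovery: attL/attR direct repeats, attB/attP, site class.

An integrated temperate phage is flanked by short direct repeats, attL
and attR, whose common core is the crossover sequence of the
integrase.  Given a rough prophage interval, the caller scans a window
around each end for exact maximal direct repeats, prefers candidates
whose upstream copy reconstitutes an intact tRNA gene (the most common
integration target), and derives the post-excision host site (attB)
and the circularized phage site (attP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import GeneFeature

__all__ = [
    "AttCall",
    "AttParams",
    "find_direct_repeats",
    "call_att",
    "check_trna_reconstitution",
    "classify_site",
    "excise",
]


@dataclass(frozen=True)
class AttParams:
    """Search window and repeat constraints for att calling.

    ``flank_bp`` is the window scanned outward from each rough prophage
    end (att cores sit at prophage termini); ``inner_bp`` extends the
    window inward so that slightly over-trimmed rough intervals still
    contain the repeats.  Only exact repeats are considered.
    """

    flank_bp: int = 2000
    inner_bp: int = 500
    min_core_length: int = 12
    context_bp: int = 10


@dataclass
class AttCall:
    """A called attachment site (1-based inclusive genome coordinates)."""

    att_core: str
    attL_interval: tuple[int, int]
    attR_interval: tuple[int, int]
    core_length: int
    site_class: str
    target_feature_id: str | None
    attB_sequence: str
    attP_sequence: str
    score: tuple


def find_direct_repeats(
    left_flank: str, right_flank: str, min_core_length: int = 12
) -> list[tuple[str, int, int]]:
    """All maximal exact common substrings of the two flanks.

    Returns ``(core, left_offset, right_offset)`` with 0-based offsets,
    one entry per maximal occurrence pair (i.e. not extendable in
    either direction), sorted by core length descending then offsets.
    """
    if not left_flank or not right_flank:
        raise ValueError("flanks must be non-empty")
    if min_core_length < 1:
        raise ValueError("min_core_length must be >= 1")
    a = np.frombuffer(left_flank.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(right_flank.upper().encode(), dtype=np.uint8)
    eq = a[:, None] == b[None, :]
    n, m = eq.shape
    results: list[tuple[str, int, int]] = []
    # walk every diagonal and extract runs of consecutive matches
    for d in range(-(n - 1), m):
        diag = np.diagonal(eq, offset=d)
        if diag.size < min_core_length:
            continue
        padded = np.concatenate(([False], diag, [False]))
        changes = np.flatnonzero(padded[1:] != padded[:-1])
        for k in range(0, changes.size, 2):
            start, stop = int(changes[k]), int(changes[k + 1])
            length = stop - start
            if length < min_core_length:
                continue
            i = start if d >= 0 else start - d
            j = start + d if d >= 0 else start
            results.append((left_flank[i : i + length], i, j))
    results.sort(key=lambda r: (-len(r[0]), r[1], r[2]))
    return results


def check_trna_reconstitution(
    attL_interval: tuple[int, int],
    attR_interval: tuple[int, int],
    trna_feature: GeneFeature,
    prophage_interval: tuple[int, int],
) -> bool:
    """True iff excising [attL start, attR start) restores an intact tRNA.

    On the plus strand the upstream (attL) copy must overlap or
    immediately abut the tRNA 3' terminus; for a minus-strand tRNA the
    3' terminus is the genomic-left end and the downstream (attR) copy
    plays that role.
    """
    if trna_feature.feature_type != "tRNA":
        return False
    if trna_feature.strand == "+":
        ls, le = attL_interval
        return ls <= trna_feature.end + 1 and le >= trna_feature.end
    rs, re_ = attR_interval
    return rs <= trna_feature.start and re_ >= trna_feature.start - 1


def classify_site(
    att_call: "AttCall | None",
    features: list[GeneFeature],
    insertion_point: int | None = None,
) -> str:
    """tRNA / gene_disruption / intergenic classification of the target."""
    if att_call is not None:
        if att_call.site_class == "tRNA":
            return "tRNA"
        insertion_point = att_call.attL_interval[1]
    if insertion_point is None:
        raise ValueError("need an att call or an explicit insertion point")
    for f in features:
        if f.feature_type == "CDS" and f.start <= insertion_point <= f.end:
            return "gene_disruption"
    return "intergenic"


def call_att(
    sequence: str,
    prophage_interval: tuple[int, int],
    features: list[GeneFeature],
    params: AttParams = AttParams(),
) -> AttCall | None:
    """Best attL/attR direct-repeat call for a rough prophage interval.

    Candidates are ranked by (1) tRNA 3'-end reconstitution, (2) core
    length, (3) summed proximity of the repeat pair to the rough
    prophage ends, (4) leftmost position -- a total, deterministic
    order.  Returns ``None`` when no repeat of at least
    ``min_core_length`` exists in the windows.
    """
    p_start, p_end = prophage_interval
    n = len(sequence)
    if not (1 <= p_start <= p_end <= n):
        raise ValueError("prophage_interval outside the sequence")
    lw_start = max(1, p_start - params.flank_bp)
    lw_end = min(n, p_start + params.inner_bp - 1)
    rw_start = max(1, p_end - params.inner_bp + 1)
    rw_end = min(n, p_end + params.flank_bp)
    left = sequence[lw_start - 1 : lw_end]
    right = sequence[rw_start - 1 : rw_end]
    if not left or not right:
        return None
    trnas = [f for f in features if f.feature_type == "tRNA"]

    best: tuple | None = None
    for core, loff, roff in find_direct_repeats(left, right, params.min_core_length):
        attL = (lw_start + loff, lw_start + loff + len(core) - 1)
        attR = (rw_start + roff, rw_start + roff + len(core) - 1)
        if attL[1] >= attR[0]:  # windows may overlap; require attL strictly upstream
            continue
        recon = None
        for t in trnas:
            if check_trna_reconstitution(attL, attR, t, prophage_interval):
                recon = t
                break
        proximity = abs(attL[0] - p_start) + abs(attR[1] - p_end)
        key = (0 if recon else 1, -len(core), proximity, attL[0], attR[0])
        if best is None or key < best[0]:
            best = (key, core, attL, attR, recon)
    if best is None:
        return None
    _, core, attL, attR, recon = best

    site_class = "tRNA" if recon else classify_site(None, features, insertion_point=attL[1])
    c = params.context_bp
    # attB: the host site restored by excising [attL start, attR start)
    attB = sequence[max(0, attL[0] - 1 - c) : attL[0] - 1] + core + sequence[attR[1] : attR[1] + c]
    # attP: the junction of the circularized excised phage
    phage_left = sequence[attL[1] : attL[1] + c]  # first bases of the cassette interior
    phage_right = sequence[max(0, attR[0] - 1 - c) : attR[0] - 1]  # last interior bases
    attP = phage_right + core + phage_left

    return AttCall(
        att_core=core,
        attL_interval=attL,
        attR_interval=attR,
        core_length=len(core),
        site_class=site_class,
        target_feature_id=recon.id if recon else None,
        attB_sequence=attB,
        attP_sequence=attP,
        score=best[0],
    )


def excise(sequence: str, att_call: AttCall) -> tuple[str, str]:
    """Excise the prophage: returns (restored host sequence, phage circle).

    Removes ``[attL start, attR start)`` and rejoins, leaving exactly
    one copy of the att core at the junction; the excised segment is
    returned as the linearized phage circle (attP at its junction).
    """
    ls = att_call.attL_interval[0]
    rs = att_call.attR_interval[0]
    host = sequence[: ls - 1] + sequence[rs - 1 :]
    phage = sequence[ls - 1 : rs - 1]
    return host, phage
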