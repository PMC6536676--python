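"""Prophage completeness screening, GC boundary refinement, MTase locus context.

A candidate prophage region counts as complete when it carries at least
one gene from each of the five hallmark modules of a temperate phage:
integration, lysis/lysogeny switch, DNA packaging, head-tail assembly
and lysis.  Where att sites do not resolve the boundaries, the
prophage/host GC contrast is used instead: prophages typically sit a
few percentage points below their high-GC hosts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import GeneFeature

__all__ = [
    "REQUIRED_MODULES",
    "CompletenessReport",
    "GcProfile",
    "assess_completeness",
    "gc_content",
    "refine_boundaries_by_gc",
    "classify_mtase_locus",
]

REQUIRED_MODULES = frozenset(
    {"integration", "lysogeny_switch", "packaging", "head_tail", "lysis"}
)


@dataclass
class CompletenessReport:
    present_modules: frozenset[str]
    missing_modules: frozenset[str]

    @property
    def complete(self) -> bool:
        return not self.missing_modules


def assess_completeness(features: list[GeneFeature]) -> CompletenessReport:
    """Module-presence completeness over the genes of a candidate region."""
    present = frozenset(f.module_category for f in features) & REQUIRED_MODULES
    return CompletenessReport(present_modules=present, missing_modules=REQUIRED_MODULES - present)


def gc_content(sequence: str) -> float:
    """Percent G+C over unambiguous bases; raises if none are present."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / (gc + at)


@dataclass
class GcProfile:
    """Sliding-window GC track for plotting / export."""

    window_starts: np.ndarray  # 1-based start of each window
    gc_percent: np.ndarray
    background_gc: float
    window: int
    step: int


def _window_gc(sequence: str, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    s = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    is_gc = (s == ord("G")) | (s == ord("C"))
    is_at = (s == ord("A")) | (s == ord("T"))
    cgc = np.concatenate(([0], np.cumsum(is_gc)))
    cat = np.concatenate(([0], np.cumsum(is_at)))
    starts = np.arange(0, max(1, len(s) - window + 1), step)
    gc = cgc[starts + window] - cgc[starts]
    at = cat[starts + window] - cat[starts]
    denom = np.maximum(gc + at, 1)
    return starts + 1, 100.0 * gc / denom


def refine_boundaries_by_gc(
    sequence: str,
    rough_interval: tuple[int, int],
    window: int = 1000,
    step: int = 250,
    min_contrast: float = 2.5,
) -> tuple[tuple[int, int], bool, GcProfile]:
    """Refine prophage boundaries to the run of GC-contrasting windows.

    The host background GC is estimated from the sequence outside the
    rough interval; the refined interval is the maximal contiguous run
    of windows deviating from background by at least ``min_contrast``
    percentage points that contains the rough interval's midpoint.
    Returns ``(interval, refined_flag, profile)``; when no such run
    exists the rough interval is returned unchanged with the flag
    False.
    """
    r_start, r_end = rough_interval
    n = len(sequence)
    if not (1 <= r_start <= r_end <= n):
        raise ValueError("rough_interval outside the sequence")
    if window > r_end - r_start + 1:
        raise ValueError("window larger than the rough interval")
    if min_contrast <= 0:
        raise ValueError("min_contrast must be > 0 (0 would accept the whole sequence)")
    background_seq = sequence[: r_start - 1] + sequence[r_end:]
    if not background_seq:
        raise ValueError("rough interval covers the whole sequence; no background to estimate")
    background = gc_content(background_seq)
    starts, gc = _window_gc(sequence, window, step)
    profile = GcProfile(starts, gc, background, window, step)

    mid = (r_start + r_end) // 2
    # windows whose span contains the midpoint (centre-most if several)
    containing = np.flatnonzero((starts <= mid) & (starts + window - 1 >= mid))
    if containing.size == 0:
        return rough_interval, False, profile
    # direction of the prophage/host contrast, estimated at the midpoint;
    # signed deviation keeps opposite-direction host fluctuations from
    # extending the run
    centre_dev = float(np.mean(gc[containing]) - background)
    if abs(centre_dev) < min_contrast:
        return rough_interval, False, profile
    sign = 1.0 if centre_dev > 0 else -1.0
    deviates = sign * (gc - background) >= min_contrast
    if not deviates[containing].any():
        return rough_interval, False, profile
    seed = int(containing[deviates[containing]][containing[deviates[containing]].size // 2])
    lo = seed
    while lo > 0 and deviates[lo - 1]:
        lo -= 1
    hi = seed
    while hi < deviates.size - 1 and deviates[hi + 1]:
        hi += 1
    # A window straddling the true boundary still passes once roughly
    # min_contrast / contrast of it lies inside the prophage, so the
    # run's outer edges overshoot systematically; correct with the
    # contrast estimated from the run interior.
    run = np.arange(lo, hi + 1)
    interior = run[2:-2] if run.size > 6 else run
    contrast_hat = max(float(sign * (np.mean(gc[interior]) - background)), min_contrast)
    corr = int(round(window * (1.0 - min_contrast / contrast_hat)))
    left = int(starts[lo]) + corr
    right = int(min(n, starts[hi] + window - 1)) - corr
    if left > right:  # degenerate single-window run
        left, right = int(starts[lo]), int(min(n, starts[hi] + window - 1))
    return (left, right), True, profile


_MTASE_PRIORITY = (
    "ParB_Tls",
    "downstream_integrase",
    "upstream_integrase",
    "downstream_lysis",
    "near_replication",
)


def classify_mtase_locus(
    mtase_gene: GeneFeature,
    features: list[GeneFeature],
    proximity_genes: int = 2,
    parb_tls_span: int = 10,
) -> str:
    """Locus context of a DNA-methyltransferase gene within a (pro)phage.

    ``ParB_Tls`` when the MTase sits between a ParB-like gene and the
    terminase large subunit gene on the same strand (the ParB-Tls
    locus, upstream of the packaging module), within ``parb_tls_span``
    genes.  Otherwise the nearest-module rules apply in priority order
    with at most ``proximity_genes`` intervening genes: MTase
    downstream of the integrase, upstream of the integrase, downstream
    of the lysis module, or adjacent to the replication module.
    "Downstream" follows the MTase gene's own strand.
    """
    order = sorted(features, key=lambda f: (f.start, f.id))
    try:
        idx = next(i for i, f in enumerate(order) if f.id == mtase_gene.id)
    except StopIteration:
        raise ValueError(f"MTase gene {mtase_gene.id!r} not among the features")
    sign = 1 if mtase_gene.strand == "+" else -1

    def category_at(i: int) -> str | None:
        if 0 <= i < len(order):
            return order[i].module_category
        return None

    # ParB-Tls: a parB_like gene genomically before the MTase and the
    # terminase_large gene after it (or mirrored on the minus strand),
    # same strand, within the span.
    for back in range(1, parb_tls_span + 1):
        i = idx - back * sign
        if not (0 <= i < len(order)):
            break
        f = order[i]
        if f.module_category == "parB_like" and f.strand == mtase_gene.strand:
            for fwd in range(1, parb_tls_span + 1):
                j = idx + fwd * sign
                if not (0 <= j < len(order)):
                    break
                g = order[j]
                if g.module_category == "terminase_large" and g.strand == mtase_gene.strand:
                    return "ParB_Tls"
            break

    within = {}
    for d in range(1, proximity_genes + 2):  # d-1 intervening genes
        for rel, i in (("down", idx - d * sign), ("up", idx + d * sign)):
            cat = category_at(i)
            if cat is None:
                continue
            # "downstream_integrase" = MTase lies downstream of the
            # integrase, i.e. the integrase precedes it on its strand.
            if cat == "integration":
                label = "downstream_integrase" if rel == "down" else "upstream_integrase"
            elif cat == "lysis" and rel == "down":
                label = "downstream_lysis"
            elif cat == "replication":
                label = "near_replication"
            else:
                continue
            within.setdefault(label, d)
    for label in _MTASE_PRIORITY[1:]:
        if label in within:
            return label
    return "other"
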