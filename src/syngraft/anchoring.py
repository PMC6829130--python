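"""Scaffold anchoring onto reference chromosomes by CDS synteny.

Each scaffold with strictly more than ``min_cds_per_scaffold - 1`` mapped
CDSs passes through three stages:

1. majority-chromosome assignment — CDSs mapping to a chromosome other
   than the scaffold's modal chromosome are removed (a strict tie leaves
   the scaffold unplaced);
2. distant-region removal — CDSs whose reference position lies further
   from the scaffold's median reference position than
   ``max(distant_mad_multiplier * MAD, distant_min_bp)`` are removed;
3. anchoring and orientation — the anchor point is the mean reference
   position of the central ``anchor_window`` CDSs in scaffold order, and
   orientation is the sign of the Kendall rank correlation between
   scaffold coordinate order and reference position order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .homology import CdsHit

log = logging.getLogger(__name__)

UNPLACED = "UNPLACED"


@dataclass(frozen=True)
class AnchoringConfig:
    min_cds_per_scaffold: int = 11  # "more than 10" is strict
    distant_mad_multiplier: float = 5.0
    distant_min_bp: int = 2_000_000
    anchor_window: int = 5

    def __post_init__(self) -> None:
        if self.min_cds_per_scaffold < self.anchor_window:
            raise ValueError(
                "min_cds_per_scaffold must be >= anchor_window")
        if self.distant_mad_multiplier <= 0 or self.distant_min_bp <= 0:
            raise ValueError("distant thresholds must be positive")


@dataclass
class ScaffoldAnchor:
    scaffold_id: str
    assigned_chromosome: str  # UNPLACED when not anchored
    anchor_position: float | None
    orientation: str  # '+' or '-'
    orientation_statistic: float
    degenerate_orientation: bool
    n_cds_total: int
    n_cds_retained: int
    n_cds_removed_majority: int
    n_cds_removed_distant: int

    @property
    def placed(self) -> bool:
        return self.assigned_chromosome != UNPLACED


# ---------------------------------------------------------------------------
# stages


def assign_majority_chromosome(hits: Sequence[CdsHit]
                               ) -> tuple[str, list[CdsHit]]:
    """Modal reference chromosome; strict mode tie -> UNPLACED.

    Returns (chromosome or UNPLACED, removed hits).  On a tie nothing is
    removed: the CDSs are retained but unused.
    """
    if not hits:
        raise ValueError("assign_majority_chromosome requires >=1 hit")
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.ref_chromosome] = counts.get(h.ref_chromosome, 0) + 1
    top = max(counts.values())
    modal = [c for c, n in counts.items() if n == top]
    if len(modal) > 1:
        return UNPLACED, []
    chrom = modal[0]
    removed = [h for h in hits if h.ref_chromosome != chrom]
    return chrom, removed


def remove_distant_cds(hits: Sequence[CdsHit], config: AnchoringConfig
                       ) -> tuple[list[CdsHit], list[CdsHit]]:
    """Drop CDSs mapping to very distant regions of the same chromosome.

    A hit is removed iff |ref_position - median| exceeds
    max(distant_mad_multiplier * MAD, distant_min_bp), where MAD is the
    raw median absolute deviation of the reference positions.  With
    fewer than 3 hits the filter is degenerate and removes nothing.
    """
    chroms = {h.ref_chromosome for h in hits}
    if len(chroms) > 1:
        raise ValueError("remove_distant_cds requires hits on one chromosome")
    if len(hits) < 3:
        log.warning("distant-CDS filter skipped: only %d hits", len(hits))
        return list(hits), []
    pos = np.array([h.ref_position for h in hits], dtype=float)
    med = float(np.median(pos))
    mad = float(np.median(np.abs(pos - med)))
    threshold = max(config.distant_mad_multiplier * mad,
                    float(config.distant_min_bp))
    kept, removed = [], []
    for h in hits:
        (removed if abs(h.ref_position - med) > threshold else kept).append(h)
    return kept, removed


def compute_anchor_point(hits: Sequence[CdsHit], config: AnchoringConfig
                         ) -> float:
    """Mean reference position of the central window of CDSs.

    Hits are ordered by scaffold coordinate; the window of
    ``anchor_window`` consecutive hits starting at index
    floor((n - w) / 2) represents the scaffold's physical middle.
    """
    w = config.anchor_window
    if len(hits) < w:
        raise ValueError(
            f"need >= {w} hits to compute an anchor point, got {len(hits)}")
    ordered = sorted(hits, key=lambda h: (h.scaffold_start, h.cds_id))
    lo = (len(ordered) - w) // 2
    window = ordered[lo: lo + w]
    return float(np.mean([h.ref_position for h in window]))


def orient_scaffold(hits: Sequence[CdsHit]) -> tuple[str, float, bool]:
    """Orientation from the Kendall correlation of the two gene orders.

    Returns (orientation, statistic, degenerate_flag).  Positive
    correlation between scaffold order and reference order means the
    scaffold already runs in the reference direction; negative means it
    must be reverse-complemented.  A zero or undefined statistic yields
    '+' with the degenerate flag set.
    """
    if len(hits) < 2:
        return "+", 0.0, True
    sc = [h.scaffold_start for h in hits]
    rp = [h.ref_position for h in hits]
    if len(set(sc)) < 2 or len(set(rp)) < 2:
        return "+", 0.0, True
    tau = stats.kendalltau(sc, rp).statistic
    if np.isnan(tau) or tau == 0:
        return "+", 0.0, True
    # snap float jitter so perfectly (dis)concordant orders report +/-1
    tau = float(round(tau, 12))
    return ("+" if tau > 0 else "-"), tau, False


# ---------------------------------------------------------------------------
# driver


def anchor_all(hits: Sequence[CdsHit],
               config: AnchoringConfig | None = None) -> list[ScaffoldAnchor]:
    """Run the full anchoring procedure over best-hit-filtered placements."""
    config = config or AnchoringConfig()
    by_scaffold: dict[str, list[CdsHit]] = {}
    for h in hits:
        if h.ref_chromosome is None or h.ref_position is None:
            raise ValueError(f"hit for {h.cds_id} lacks reference coordinates")
        by_scaffold.setdefault(h.scaffold_id, []).append(h)

    anchors: list[ScaffoldAnchor] = []
    n_removed = n_considered = 0
    for sid in sorted(by_scaffold):
        shits = by_scaffold[sid]
        n = len(shits)
        if n < config.min_cds_per_scaffold:
            anchors.append(ScaffoldAnchor(sid, UNPLACED, None, "+", 0.0, True,
                                          n, n, 0, 0))
            continue
        n_considered += n
        chrom, rm_major = assign_majority_chromosome(shits)
        if chrom == UNPLACED:
            anchors.append(ScaffoldAnchor(sid, UNPLACED, None, "+", 0.0, True,
                                          n, n, 0, 0))
            continue
        same = [h for h in shits if h.ref_chromosome == chrom]
        kept, rm_dist = remove_distant_cds(same, config)
        n_removed += len(rm_major) + len(rm_dist)
        if len(kept) < config.anchor_window:
            anchors.append(ScaffoldAnchor(sid, UNPLACED, None, "+", 0.0, True,
                                          n, len(kept), len(rm_major),
                                          len(rm_dist)))
            continue
        anchor = compute_anchor_point(kept, config)
        ordered = sorted(kept, key=lambda h: (h.scaffold_start, h.cds_id))
        orientation, tau, degen = orient_scaffold(ordered)
        anchors.append(ScaffoldAnchor(sid, chrom, anchor, orientation, tau,
                                      degen, n, len(kept), len(rm_major),
                                      len(rm_dist)))

    n_placed = sum(a.placed for a in anchors)
    frac = (100.0 * n_removed / n_considered) if n_considered else 0.0
    log.info("anchored %d/%d scaffolds; %.1f%% of CDSs on threshold-passing "
             "scaffolds removed by the majority/distant filters",
             n_placed, len(anchors), frac)
    return anchors


def removal_fraction(anchors: Sequence[ScaffoldAnchor]) -> float:
    """Fraction of CDSs removed on scaffolds that met the CDS threshold."""
    tot = rem = 0
    for a in anchors:
        if a.n_cds_removed_majority or a.n_cds_removed_distant or a.placed:
            tot += a.n_cds_total
            rem += a.n_cds_removed_majority + a.n_cds_removed_distant
    return rem / tot if tot else 0.0


def anchors_to_frame(anchors: Sequence[ScaffoldAnchor]):
    import pandas as pd
    return pd.DataFrame([vars(a) for a in anchors])
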