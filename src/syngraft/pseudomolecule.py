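"""Pseudomolecule layout, FASTA/AGP emission and assembly reporting.

Anchored scaffolds are laid out per chromosome in anchor-position order
(ties: longer scaffold first, then lexicographic id), minus-oriented
scaffolds are reverse-complemented, and consecutive scaffolds are
separated by a fixed N spacer (AGP "scaffold" gap, linkage yes, evidence
align_genus — the convention for synteny-inferred joins of unknown
size).  Internal coordinates are 0-based half-open; emitted AGP rows are
1-based inclusive per AGP v2.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp
from .anchoring import ScaffoldAnchor
from .homology import CdsHit

DEFAULT_SPACER_BP = 100
AGP_HEADER = "##agp-version\t2.1"


@dataclass
class LayoutPart:
    scaffold_id: str
    orientation: str
    start: int  # 0-based half-open on the pseudomolecule
    end: int


@dataclass
class PseudomoleculeLayout:
    molecule_id: str
    parts: list[LayoutPart]
    gaps: list[tuple[int, int]]  # spacer intervals on the molecule
    sequence: str
    total_length_bp: int = 0
    gap_fraction: float = 0.0  # percent of N bases (spacers + internal runs)

    def __post_init__(self) -> None:
        self.total_length_bp = len(self.sequence)
        n = self.sequence.count("N")
        self.gap_fraction = (100.0 * n / self.total_length_bp
                             if self.total_length_bp else 0.0)


@dataclass
class AssemblyReport:
    per_molecule: pd.DataFrame  # molecule_id, size_bp, gap_pct
    total_size_bp: int
    total_gap_pct: float  # size-weighted mean of per-molecule gap percent
    anchored_fraction: float | None = None  # percent of assembly bases placed


# ---------------------------------------------------------------------------
# build


def _sorted_parts(anchors: Sequence[ScaffoldAnchor],
                  scaffolds: dict[str, str]) -> dict[str, list[ScaffoldAnchor]]:
    placed = [a for a in anchors if a.placed]
    seen: set[str] = set()
    for a in placed:
        if a.scaffold_id in seen:
            raise ValueError(f"scaffold {a.scaffold_id} placed twice")
        seen.add(a.scaffold_id)
        if a.scaffold_id not in scaffolds:
            raise ValueError(f"scaffold {a.scaffold_id} missing from FASTA")
    by_chrom: dict[str, list[ScaffoldAnchor]] = {}
    for a in placed:
        by_chrom.setdefault(a.assigned_chromosome, []).append(a)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda a: (a.anchor_position,
                                            -len(scaffolds[a.scaffold_id]),
                                            a.scaffold_id))
    return dict(sorted(by_chrom.items()))


def build_pseudomolecules(anchors: Sequence[ScaffoldAnchor],
                          scaffolds: dict[str, str],
                          spacer_bp: int = DEFAULT_SPACER_BP
                          ) -> list[PseudomoleculeLayout]:
    layouts = []
    for chrom, ordered in _sorted_parts(anchors, scaffolds).items():
        parts: list[LayoutPart] = []
        gaps: list[tuple[int, int]] = []
        pieces: list[str] = []
        pos = 0
        for i, a in enumerate(ordered):
            if i > 0 and spacer_bp > 0:
                gaps.append((pos, pos + spacer_bp))
                pieces.append("N" * spacer_bp)
                pos += spacer_bp
            seq = scaffolds[a.scaffold_id]
            if a.orientation == "-":
                seq = revcomp(seq)
            parts.append(LayoutPart(a.scaffold_id, a.orientation,
                                    pos, pos + len(seq)))
            pieces.append(seq)
            pos += len(seq)
        layouts.append(PseudomoleculeLayout(chrom, parts, gaps,
                                            "".join(pieces)))
    return layouts


# ---------------------------------------------------------------------------
# AGP


def layouts_to_agp(layouts: Sequence[PseudomoleculeLayout],
                   scaffolds: dict[str, str]) -> list[str]:
    """AGP v2.1 rows (tab-joined strings, 1-based inclusive)."""
    rows = [AGP_HEADER]
    for lay in layouts:
        events: list[tuple[int, tuple]] = []
        for p in lay.parts:
            events.append((p.start, ("W", p)))
        for g in lay.gaps:
            events.append((g[0], ("N", g)))
        events.sort(key=lambda e: e[0])
        for part_no, (_, (kind, item)) in enumerate(events, start=1):
            if kind == "W":
                comp_len = len(scaffolds[item.scaffold_id])
                rows.append("\t".join(map(str, [
                    lay.molecule_id, item.start + 1, item.end, part_no, "W",
                    item.scaffold_id, 1, comp_len, item.orientation])))
            else:
                s, e = item
                rows.append("\t".join(map(str, [
                    lay.molecule_id, s + 1, e, part_no, "N", e - s,
                    "scaffold", "yes", "align_genus"])))
    return rows


def write_agp(layouts: Sequence[PseudomoleculeLayout],
              scaffolds: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(layouts_to_agp(layouts, scaffolds)) + "\n")


def reconstruct_from_agp(agp_path: str | Path,
                         scaffolds: dict[str, str]) -> dict[str, str]:
    """Rebuild object sequences from an AGP file plus component FASTA."""
    pieces: dict[str, list[tuple[int, str]]] = {}
    with open(agp_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            obj, obeg = f[0], int(f[1])
            if f[4] in ("N", "U"):
                pieces.setdefault(obj, []).append((obeg, "N" * int(f[5])))
            else:
                cid, cbeg, cend, orient = f[5], int(f[6]), int(f[7]), f[8]
                seq = scaffolds[cid][cbeg - 1: cend]
                if orient == "-":
                    seq = revcomp(seq)
                pieces.setdefault(obj, []).append((obeg, seq))
    return {obj: "".join(s for _, s in sorted(parts))
            for obj, parts in pieces.items()}


# ---------------------------------------------------------------------------
# reporting


def compute_assembly_report(layouts: Sequence[PseudomoleculeLayout],
                            unplaced: dict[str, str] | None = None
                            ) -> AssemblyReport:
    rows = [(lay.molecule_id, lay.total_length_bp, lay.gap_fraction)
            for lay in layouts]
    return assembly_report_from_rows(
        pd.DataFrame(rows, columns=["molecule_id", "size_bp", "gap_pct"]),
        unplaced_bp=(sum(len(s) for s in unplaced.values())
                     if unplaced is not None else None))


def assembly_report_from_rows(per_molecule: pd.DataFrame,
                              unplaced_bp: int | None = None
                              ) -> AssemblyReport:
    """Totals from per-molecule (size, gap percent) rows.

    Accepts externally tabulated per-molecule summaries, so published
    assembly tables can be re-totalled with the same code path used for
    freshly built layouts.  The overall gap percentage is the
    size-weighted mean of the per-molecule values.
    """
    total = int(per_molecule["size_bp"].sum())
    if total > 0:
        weighted = float((per_molecule["size_bp"] * per_molecule["gap_pct"])
                         .sum() / total)
    else:
        weighted = 0.0
    anchored = None
    if unplaced_bp is not None:
        denom = total + unplaced_bp
        anchored = 100.0 * total / denom if denom else 0.0
    return AssemblyReport(per_molecule.reset_index(drop=True), total,
                          weighted, anchored)


def synteny_block_report(anchors: Sequence[ScaffoldAnchor],
                         hits: Sequence[CdsHit],
                         minority_min_cds: int = 2,
                         minority_min_fraction: float = 0.2
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Per-chromosome gene-order concordance plus rearrangement candidates.

    For each chromosome the Kendall tau between gene order along the
    laid-out pseudomolecule (scaffolds in anchor order, CDSs in scaffold
    order, reversed for '-' scaffolds) and reference gene order is
    reported.  Candidate translocation / assembly-error scaffolds are
    those carrying a substantial minority of CDSs mapping to a different
    chromosome than the scaffold's own majority (>= ``minority_min_cds``
    CDSs and >= ``minority_min_fraction`` of the scaffold's CDSs) — the
    truth-free signature of a breakpoint relative to the neighbouring
    gene order.
    """
    placed = {a.scaffold_id: a for a in anchors if a.placed}
    by_scaffold: dict[str, list[CdsHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.scaffold_id, []).append(h)

    candidates = []
    for a in anchors:
        shits = by_scaffold.get(a.scaffold_id, [])
        if not shits:
            continue
        counts: dict[str, int] = {}
        for h in shits:
            counts[h.ref_chromosome] = counts.get(h.ref_chromosome, 0) + 1
        modal = max(counts.values())
        minority = len(shits) - modal
        if (minority >= minority_min_cds
                and minority / len(shits) >= minority_min_fraction):
            candidates.append(a.scaffold_id)

    rows = []
    by_chrom: dict[str, list[ScaffoldAnchor]] = {}
    for a in placed.values():
        by_chrom.setdefault(a.assigned_chromosome, []).append(a)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom],
                         key=lambda a: (a.anchor_position, a.scaffold_id))
        pseudo_order: list[int] = []
        for a in ordered:
            shits = [h for h in by_scaffold.get(a.scaffold_id, [])
                     if h.ref_chromosome == chrom]
            shits.sort(key=lambda h: (h.scaffold_start, h.cds_id),
                       reverse=(a.orientation == "-"))
            pseudo_order.extend(h.ref_position for h in shits)
        if len(pseudo_order) >= 2 and len(set(pseudo_order)) >= 2:
            tau = float(round(stats.kendalltau(range(len(pseudo_order)),
                                               pseudo_order).statistic, 12))
        else:
            tau = float("nan")
        rows.append((chrom, len(ordered), len(pseudo_order), tau))
    report = pd.DataFrame(rows, columns=["chromosome", "n_scaffolds",
                                         "n_cds", "kendall_tau"])
    return report, sorted(candidates)
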