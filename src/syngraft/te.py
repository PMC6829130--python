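"""Transposable-element curation, annotation and repeat-space accounting.

The curation route mirrors manual TE-library construction: protein-seed
homology regions are harvested with 5000-9000 bp flanks, non-autonomous
deletion derivatives are recovered by DNA similarity outside coding
regions, family consensi are built by per-column majority over a star
alignment, and DNA transposon families are discovered de novo from
terminal-inverted-repeat (TIR) structure flanked by a target-site
duplication (TSD), retaining only candidates that recur in multiple
copies.  The resulting library is mapped back to the genome, and repeat
space from several annotation sources (manual, RepeatMasker-style,
RepeatRunner-style, TE-bearing genes) is merged with every base counted
once.

All intervals are 0-based half-open.  Genome-scale similarity search
uses an exact-k-mer-anchored, ungapped seed-and-extend matcher: planted
and real near-identical copies share abundant exact k-mers, and the
ungapped model keeps the matcher verifiable against brute-force oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._intervals import (clip_interval, coverage_at_least, merge_intervals,
                         union_bp)
from ._seq import revcomp

log = logging.getLogger(__name__)

SUPERFAMILY_CODES = {
    "Gypsy": "RLG", "Copia": "RLC", "CACTA": "DTC", "hAT": "DTA",
    "Mutator": "DTM", "Helitron": "DHH", "unknown_TIR": "DTX",
}

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class TeFamily:
    family_name: str
    superfamily: str  # Gypsy | Copia | CACTA | hAT | Mutator | Helitron | unknown_TIR
    te_class: str     # retrotransposon | DNA_subclass1 | DNA_subclass2
    consensus: str
    n_members: int
    autonomous: bool
    members: list[tuple[str, int, int, str]] = field(default_factory=list)
    tir_length_bp: int = 0
    tsd_length_bp: int = 0

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("family consensus must be non-empty")


@dataclass
class TeAnnotationSet:
    """Genome-wide TE intervals from one annotation source."""

    source: str  # manual | repeatmasker | repeatrunner | te_gene
    intervals: pd.DataFrame  # chrom, start, end, family_name, superfamily

    COLUMNS = ["chrom", "start", "end", "family_name", "superfamily"]

    @classmethod
    def from_records(cls, source: str, records: Iterable[tuple]) -> "TeAnnotationSet":
        df = pd.DataFrame(list(records), columns=cls.COLUMNS)
        return cls(source, df)

    @classmethod
    def from_bed(cls, path: str | Path, source: str,
                 superfamily: str = "unknown_TIR") -> "TeAnnotationSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else "."
                rows.append((f[0], int(f[1]), int(f[2]), name, superfamily))
        return cls.from_records(source, rows)

    def per_chrom(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for r in self.intervals.itertuples():
            out.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
        return out

    def union_bp(self) -> int:
        return sum(union_bp(ivs) for ivs in self.per_chrom().values())


@dataclass
class TeSpaceSummary:
    per_source: pd.DataFrame        # source, te_space_bp, te_space_pct
    superfamily_table: pd.DataFrame  # manual-source Table-style rows
    combined_bp: int
    combined_pct: float
    multi_source_overlap_bp: int
    multi_source_overlap_pct: float
    assembly_bp: int


# ---------------------------------------------------------------------------
# seed-and-extend similarity search


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    return table[np.frombuffer(seq.encode("ascii").upper(), dtype=np.uint8)]


def seed_extend_matches(query: str, subject: str, k: int = 13,
                        min_identity_pct: float = 80.0,
                        min_length_bp: int = 100,
                        both_strands: bool = True
                        ) -> list[tuple[int, int, str, float]]:
    """Ungapped local matches of ``query`` on ``subject``.

    Non-overlapping k-mers of the query (stride k) are located exactly on
    the subject; anchors sharing a diagonal define an ungapped candidate,
    which is trimmed to its first/last matching base and reported when it
    meets the identity and length thresholds.  Returns
    (start, end, strand, identity_pct) tuples in subject coordinates.
    """
    results: list[tuple[int, int, str, float]] = []
    if not query or not subject:
        return results
    sub_arr = _encode(subject)
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        qlen = len(q)
        kk = min(k, qlen)
        # cap the number of probes so search cost stays linear in the
        # subject even for multi-kb queries; anchors are redundant anyway
        stride = max(kk, (qlen - kk) // 64 + 1)
        diagonals: set[int] = set()
        for qpos in range(0, qlen - kk + 1, stride):
            probe = q[qpos: qpos + kk]
            if "N" in probe:
                continue
            start = 0
            while True:
                spos = subject.find(probe, start)
                if spos == -1:
                    break
                diagonals.add(spos - qpos)
                start = spos + 1
        q_arr = _encode(q)
        # mismatch penalty chosen so a segment scores positive only above
        # the identity threshold: p*1 - (1-p)*w > 0  <=>  p > w/(w+1)
        mm_penalty = min_identity_pct / (100.0 - min_identity_pct) \
            if min_identity_pct < 100 else 1e9
        for d in sorted(diagonals):
            q_lo = max(0, -d)
            q_hi = min(qlen, len(subject) - d)
            if q_hi - q_lo < min_length_bp:
                continue
            m = q_arr[q_lo:q_hi] == sub_arr[d + q_lo: d + q_hi]
            m &= q_arr[q_lo:q_hi] < 4
            if not m.any():
                continue
            # maximal-scoring segment on this diagonal (ungapped local
            # alignment): only the well-matching stretch is reported,
            # even when just part of the query occurs in the subject
            scores = np.where(m, 1.0, -mm_penalty)
            c = np.concatenate([[0.0], np.cumsum(scores)])
            run_min = np.minimum.accumulate(c[:-1])
            gains = c[1:] - run_min
            b = int(np.argmax(gains)) + 1
            a = int(np.argmin(c[:b]))
            idx = np.flatnonzero(m[a:b])
            if idx.size == 0:
                continue
            a2, b2 = a + int(idx[0]), a + int(idx[-1]) + 1
            length = b2 - a2
            if length < min_length_bp:
                continue
            identity = 100.0 * float(m[a2:b2].mean())
            if identity < min_identity_pct:
                continue
            s0, s1 = d + q_lo + a2, d + q_lo + b2
            results.append((s0, s1, strand, identity))
    # collapse duplicate/contained reports from adjacent diagonals
    results.sort(key=lambda r: (r[0], -(r[1] - r[0])))
    pruned: list[tuple[int, int, str, float]] = []
    for r in results:
        if pruned and r[0] >= pruned[-1][0] and r[1] <= pruned[-1][1]:
            continue
        pruned.append(r)
    return pruned


# ---------------------------------------------------------------------------
# curation: homology harvesting, derivatives, consensus


def harvest_homology_regions(protein_hits: pd.DataFrame,
                             genome: dict[str, str],
                             flank_bp: int
                             ) -> list[tuple[str, int, int, str]]:
    """Candidate element regions around TE-protein homology hits.

    ``protein_hits`` needs columns chrom, start, end (genomic intervals
    of TBLASTN-style hits).  Each interval is extended by ``flank_bp``
    on both sides (the 5000-9000 bp window in which full-length elements
    and their termini are expected), clipped at sequence ends, and
    overlapping extended intervals are merged into a single candidate.
    Returns (chrom, start, end, sequence) tuples.
    """
    if not 5000 <= flank_bp <= 9000:
        raise ValueError(
            f"flank_bp must be within [5000, 9000], got {flank_bp}")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in protein_hits.itertuples():
        length = len(genome[r.chrom])
        s, e = clip_interval(int(r.start) - flank_bp, int(r.end) + flank_bp,
                             length)
        per_chrom.setdefault(r.chrom, []).append((s, e))
    out = []
    for chrom in sorted(per_chrom):
        for s, e in merge_intervals(per_chrom[chrom]):
            out.append((chrom, s, e, genome[chrom][s:e]))
    return out


def find_nonautonomous_derivatives(member_seqs: Sequence[str],
                                   genome: dict[str, str],
                                   protein_hit_intervals: pd.DataFrame,
                                   min_identity_pct: float = 80.0,
                                   min_length_bp: int = 100,
                                   merge_gap_bp: int = 30
                                   ) -> list[tuple[str, int, int]]:
    """Genomic intervals DNA-similar to family members but non-coding.

    Matches of the autonomous members across the genome are merged
    (matches separated by <= ``merge_gap_bp`` collapse into one insertion,
    which is how internal-deletion derivatives present); any interval
    overlapping a protein-coding hit is excluded, so full-length
    autonomous copies are never double-reported.
    """
    coding: dict[str, list[tuple[int, int]]] = {}
    for r in protein_hit_intervals.itertuples():
        coding.setdefault(r.chrom, []).append((int(r.start), int(r.end)))

    found: dict[str, list[tuple[int, int]]] = {}
    for seq in member_seqs:
        for chrom, subject in genome.items():
            for s, e, _strand, _ident in seed_extend_matches(
                    seq, subject, min_identity_pct=min_identity_pct,
                    min_length_bp=min_length_bp):
                found.setdefault(chrom, []).append((s, e))

    out: list[tuple[str, int, int]] = []
    for chrom in sorted(found):
        merged = merge_intervals(found[chrom])
        glued: list[tuple[int, int]] = []
        for s, e in merged:
            if glued and s - glued[-1][1] <= merge_gap_bp:
                glued[-1] = (glued[-1][0], e)
            else:
                glued.append((s, e))
        code = merge_intervals(coding.get(chrom, []))
        for s, e in glued:
            overlaps = any(s < ce and cs < e for cs, ce in code)
            if not overlaps:
                out.append((chrom, s, e))
    return out


def build_consensus(members: Sequence[str]) -> str:
    """Per-column majority consensus over a star alignment of the members.

    The longest member is the alignment backbone; every other member is
    globally aligned to it (insertions relative to the backbone are
    dropped).  Columns where most members have a gap are removed; ties
    among bases become IUPAC ambiguity codes.
    """
    if len(members) < 2:
        raise ValueError("consensus requires >= 2 member sequences")
    from Bio import Align
    backbone = max(members, key=len)
    ncol = len(backbone)
    columns: list[list[str]] = [[] for _ in range(ncol)]
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=-1, open_gap_score=-4,
                                    extend_gap_score=-0.5)
    for mem in members:
        if mem == backbone and mem is backbone:
            for i, b in enumerate(backbone):
                columns[i].append(b)
            continue
        aln = aligner.align(backbone, mem)[0]
        row = ["-"] * ncol
        for (b0, b1), (m0, m1) in zip(*aln.aligned):
            for off in range(b1 - b0):
                row[b0 + off] = mem[m0 + off]
        for i, b in enumerate(row):
            columns[i].append(b)
    out = []
    n = len(members)
    for col in columns:
        gaps = col.count("-")
        if gaps * 2 > n:
            continue
        bases = [b for b in col if b != "-"]
        counts: dict[str, int] = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        winners = frozenset(b for b, c in counts.items() if c == top)
        out.append(_IUPAC.get(winners, "N") if len(winners) > 1
                   else next(iter(winners)))
    return "".join(out)


# ---------------------------------------------------------------------------
# de novo TIR discovery


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement integer codes of all k-mers.

    Windows containing N get the sentinel code -1.
    """
    n = arr.size - k + 1
    fwd = np.zeros(n, dtype=np.int64)
    rc = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        win = arr[j: n + j].astype(np.int64)
        fwd = fwd * 4 + win
        rcw = arr[k - 1 - j: n + k - 1 - j].astype(np.int64)
        rc = rc * 4 + (3 - rcw)
        bad |= win == 4
    fwd[bad] = -1
    rc[bad] = -2
    return fwd, rc


def _tir_pairs(arr: np.ndarray, k: int, min_element_bp: int,
               max_element_bp: int) -> list[tuple[int, int]]:
    """Positions (i, j) where the k-mer at j is the reverse complement of
    the k-mer at i and the implied element [i, j + k) has admissible size."""
    n = arr.size - k + 1
    if n <= 0:
        return []
    fwd, rc = _kmer_codes(arr, k)
    valid = fwd >= 0
    pos = np.flatnonzero(valid)
    codes = fwd[pos]
    order = np.argsort(codes, kind="stable")
    pos_sorted = pos[order].astype(np.int64)
    code_sorted = codes[order]
    span = np.int64(arr.size + 1)
    comp = code_sorted * span + pos_sorted

    lo = max(min_element_bp - k, 1)
    hi = max_element_bp - k
    pairs: list[tuple[int, int]] = []
    chunk = 500_000
    for c0 in range(0, n, chunk):
        c1 = min(n, c0 + chunk)
        i_idx = np.arange(c0, c1, dtype=np.int64)
        q = rc[c0:c1]
        ok = q >= 0
        i_idx, q = i_idx[ok], q[ok]
        kl = np.searchsorted(comp, q * span + (i_idx + lo))
        kr = np.searchsorted(comp, q * span + (i_idx + hi + 1))
        counts = kr - kl
        nz = counts > 0
        i_idx, kl, counts = i_idx[nz], kl[nz], counts[nz]
        if i_idx.size == 0:
            continue
        total = int(counts.sum())
        rep = np.repeat(np.arange(i_idx.size), counts)
        within = np.arange(total) - np.repeat(
            np.concatenate([[0], np.cumsum(counts)[:-1]]), counts)
        j_vals = pos_sorted[kl[rep] + within]
        i_vals = i_idx[rep]
        pairs.extend(zip(i_vals.tolist(), j_vals.tolist()))
    return pairs


def _find_tsd(seq: str, i: int, e: int, tsd_lengths: Sequence[int]
              ) -> int | None:
    """Longest TSD length whose direct repeat flanks [i, e) exactly."""
    for L in sorted(tsd_lengths, reverse=True):
        if i - L < 0 or e + L > len(seq):
            continue
        left = seq[i - L: i]
        right = seq[e: e + L]
        if "N" in left or len(set(left)) == 1:
            continue
        if left == right:
            return L
    return None


def _tir_length(seq: str, i: int, e: int, min_identity_pct: float) -> int:
    """Maximal inverted-terminal-repeat length of the element [i, e)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    limit = (e - i) // 2
    best = t = matches = consec_mm = 0
    while t < limit:
        a = seq[i + t]
        b = seq[e - 1 - t]
        if a in comp and comp[a] == b:
            matches += 1
            consec_mm = 0
        else:
            consec_mm += 1
        t += 1
        if consec_mm == 0 and 100.0 * matches / t >= min_identity_pct:
            best = t
        if consec_mm >= 3:  # repeat has clearly ended
            break
    return best


def detect_tir_elements(genome: dict[str, str],
                        min_tir_bp: int = 10,
                        min_tir_identity_pct: float = 80.0,
                        tsd_lengths: Sequence[int] = tuple(range(2, 12)),
                        min_copies: int = 3,
                        min_element_bp: int = 100,
                        max_element_bp: int = 20_000,
                        member_min_identity_pct: float = 80.0,
                        member_min_coverage: float = 0.8
                        ) -> list[TeFamily]:
    """De novo DNA-transposon families from TIR + TSD structure.

    Candidate elements are spans whose termini are reverse-complement
    repeats of >= ``min_tir_bp`` flanked by an exact direct repeat whose
    length is in ``tsd_lengths``.  Candidates are searched genome-wide
    (a fast shared-k-mer count prefilter removes one-off candidates
    before the full search) and retained as families iff they occur in
    >= ``min_copies`` copies at >= ``member_min_identity_pct`` identity
    over >= ``member_min_coverage`` of the element length.
    """
    # candidate discovery
    candidates: list[tuple[str, int, int, int]] = []  # chrom, start, end, tsd
    arrays = {c: _encode(s) for c, s in genome.items()}
    for chrom in sorted(genome):
        seq = genome[chrom]
        for i, j in _tir_pairs(arrays[chrom], min_tir_bp, min_element_bp,
                               max_element_bp):
            e = j + min_tir_bp
            tsd = _find_tsd(seq, i, e, tsd_lengths)
            if tsd is None:
                continue
            if _tir_length(seq, i, e, min_tir_identity_pct) < min_tir_bp:
                continue
            candidates.append((chrom, i, e, tsd))

    if not candidates:
        return []

    # multi-copy prefilter: count exact occurrences of probe k-mers
    pk = 16
    probe_index: dict[str, np.ndarray] = {}
    for chrom, arr in arrays.items():
        if arr.size >= pk:
            fwd, _ = _kmer_codes(arr, pk)
            probe_index[chrom] = np.sort(fwd[fwd >= 0])

    def _probe_count(s: str) -> int:
        arr = _encode(s)
        if arr.size < pk:
            return 0
        fwd, rc = _kmer_codes(arr, pk)
        picks = np.linspace(0, fwd.size - 1, num=min(5, fwd.size),
                            dtype=int)
        counts = []
        for p in picks:
            c = 0
            for code in (fwd[p], rc[p]):
                if code < 0:
                    continue
                for idx in probe_index.values():
                    c += int(np.searchsorted(idx, code, "right")
                             - np.searchsorted(idx, code, "left"))
            counts.append(c)
        return int(np.median(counts)) if counts else 0

    # Rank candidate spans by TSD consistency across loci.  A true
    # insertion boundary shows a direct repeat of the same length at
    # every copy, whereas spans nudged off the boundary pick up only
    # coincidental (locus-specific, usually shorter) repeats.
    from collections import Counter
    info: dict[str, dict] = {}
    for chrom, s, e, tsd in candidates:
        d = info.setdefault(genome[chrom][s:e],
                            {"loci": set(), "tsds": Counter(),
                             "meta": (chrom, s, e, tsd)})
        d["loci"].add((chrom, s))
        d["tsds"][tsd] += 1

    def _rank(seq: str) -> tuple[int, int, int]:
        tsds = info[seq]["tsds"]
        support = max(tsds.values())
        modal_tsd = max(L for L, c in tsds.items() if c == support)
        return (support, modal_tsd, len(seq))

    survivors = [(seq, d["meta"]) for seq, d in info.items()
                 if _probe_count(seq) >= min_copies]

    # one representative per genomic locus: overlapping candidate spans
    # describe the same putative element, so only the best-ranked one
    # is searched genome-wide
    survivors.sort(key=lambda x: (x[1][0], x[1][1], x[1][2]))
    reps: list[tuple[str, tuple[str, int, int, int]]] = []
    cur_chrom, cur_end = None, -1
    for seq, meta in survivors:
        chrom, s, e, _tsd = meta
        if chrom == cur_chrom and s < cur_end:
            if _rank(seq) > _rank(reps[-1][0]):
                reps[-1] = (seq, meta)
            cur_end = max(cur_end, e)
        else:
            reps.append((seq, meta))
            cur_chrom, cur_end = chrom, e
    reps.sort(key=lambda x: (tuple(-v for v in _rank(x[0])), x[1]))
    survivors = reps

    # full verification and clustering by member-interval overlap
    families: list[TeFamily] = []
    claimed: dict[str, list[tuple[int, int]]] = {}
    for seq, (chrom, s, e, tsd) in survivors:
        # sub-spans of an already reported element need no genome search
        if any(s < ce and cs < e for cs, ce in claimed.get(chrom, [])):
            continue
        members: list[tuple[str, int, int, str]] = []
        for sub_chrom, subject in genome.items():
            for ms, me, strand, ident in seed_extend_matches(
                    seq, subject, min_identity_pct=member_min_identity_pct,
                    min_length_bp=int(member_min_coverage * len(seq))):
                members.append((sub_chrom, ms, me, strand))
        if len(members) < min_copies:
            continue
        overlap = sum(
            1 for (mc, ms, me, _st) in members
            if any(ms < ce and cs < me for cs, ce in claimed.get(mc, [])))
        if overlap * 2 > len(members):
            continue  # same family, already reported from another copy
        for mc, ms, me, _st in members:
            claimed.setdefault(mc, []).append((ms, me))
        name = f"{SUPERFAMILY_CODES['unknown_TIR']}_{len(families) + 1}"
        families.append(TeFamily(
            family_name=name, superfamily="unknown_TIR",
            te_class="DNA_subclass1", consensus=seq,
            n_members=len(members), autonomous=False, members=members,
            tir_length_bp=_tir_length(genome[chrom], s, e,
                                      min_tir_identity_pct),
            tsd_length_bp=_rank(seq)[1]))
    log.info("TIR discovery: %d raw candidates, %d multi-copy, %d families",
             len(candidates), len(survivors), len(families))
    return families


# ---------------------------------------------------------------------------
# library map-back


def annotate_with_library(genome: dict[str, str],
                          library: Sequence[TeFamily],
                          min_identity_pct: float = 80.0,
                          min_length_bp: int = 100) -> TeAnnotationSet:
    """Map family consensi back to the genome (source "manual").

    Overlapping matches of the same family are merged; nested matches of
    different families are both kept.
    """
    if not library:
        return TeAnnotationSet.from_records("manual", [])
    rows = []
    for fam in library:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, subject in genome.items():
            for s, e, _strand, _ident in seed_extend_matches(
                    fam.consensus, subject,
                    min_identity_pct=min_identity_pct,
                    min_length_bp=min(min_length_bp, len(fam.consensus))):
                per_chrom.setdefault(chrom, []).append((s, e))
        for chrom in sorted(per_chrom):
            for s, e in merge_intervals(per_chrom[chrom]):
                rows.append((chrom, s, e, fam.family_name, fam.superfamily))
    return TeAnnotationSet.from_records("manual", rows)


# ---------------------------------------------------------------------------
# accounting


def merge_te_sources(sets: Sequence[TeAnnotationSet], assembly_bp: int,
                     chrom_lengths: dict[str, int] | None = None
                     ) -> TeSpaceSummary:
    """Multi-source repeat-space accounting with every base counted once.

    Per-source bp is the union of that source's intervals; combined bp
    is the union over all sources; multi-source overlap is the bases
    annotated by two or more distinct sources.  Percentages are relative
    to ``assembly_bp``.  A Table-style per-superfamily breakdown is
    produced for the manual source.
    """
    if not sets:
        raise ValueError("merge_te_sources requires >= 1 annotation set")
    if chrom_lengths is not None:
        for s in sets:
            for r in s.intervals.itertuples():
                if r.start < 0 or r.end > chrom_lengths.get(r.chrom, -1):
                    raise ValueError(
                        f"interval {r.chrom}:{r.start}-{r.end} in source "
                        f"{s.source} exceeds chromosome bounds")

    def pct(bp: int) -> float:
        return 100.0 * bp / assembly_bp if assembly_bp else 0.0

    src_rows = [(s.source, s.union_bp(), pct(s.union_bp())) for s in sets]
    per_source = pd.DataFrame(src_rows,
                              columns=["source", "te_space_bp",
                                       "te_space_pct"])

    chroms = sorted({c for s in sets for c in s.per_chrom()})
    combined = 0
    multi = 0
    for chrom in chroms:
        per_src = [s.per_chrom().get(chrom, []) for s in sets]
        combined += coverage_at_least(per_src, 1)
        multi += coverage_at_least(per_src, 2)

    fam_rows = []
    for s in sets:
        if s.source != "manual" or s.intervals.empty:
            continue
        for sf, grp in s.intervals.groupby("superfamily", sort=True):
            per_chrom: dict[str, list[tuple[int, int]]] = {}
            for r in grp.itertuples():
                per_chrom.setdefault(r.chrom, []).append((int(r.start),
                                                          int(r.end)))
            bp = sum(union_bp(iv) for iv in per_chrom.values())
            fam_rows.append((sf, grp["family_name"].nunique(), len(grp),
                             bp, pct(bp)))
    superfamily_table = pd.DataFrame(
        fam_rows, columns=["superfamily", "n_families", "n_elements",
                           "te_space_bp", "te_space_pct"])

    return TeSpaceSummary(per_source, superfamily_table, combined,
                          pct(combined), multi, pct(multi), assembly_bp)


# ---------------------------------------------------------------------------
# windowed density / centromere candidates


def te_density_profile(annotation: TeAnnotationSet,
                       chrom_lengths: dict[str, int],
                       window_bp: int = 1_000_000,
                       enriched_window_fraction: float = 0.05,
                       run_max_windows: int = 3,
                       run_coverage_fraction: float = 0.9
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-family windowed coverage and centromere-candidate calls.

    A family marks a candidate centromeric region on a chromosome when
    >= ``run_coverage_fraction`` of its covered bases lie inside at most
    two runs of <= ``run_max_windows`` consecutive enriched windows
    (windows holding >= ``enriched_window_fraction`` of the family's
    coverage).  Chromosomes showing two disjoint runs are flagged, since
    a doubled centromeric signal can indicate orientation problems or
    redundant scaffolds.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    dens_rows = []
    call_rows = []
    groups = annotation.intervals.groupby(["family_name", "chrom"],
                                          sort=True)
    for (family, chrom), grp in groups:
        clen = chrom_lengths[chrom]
        nwin = max(1, -(-clen // window_bp))
        cov = np.zeros(nwin, dtype=np.int64)
        for r in grp.itertuples():
            for s, e in [(int(r.start), int(r.end))]:
                w0, w1 = s // window_bp, (e - 1) // window_bp
                for w in range(w0, w1 + 1):
                    ws, we = w * window_bp, min((w + 1) * window_bp, clen)
                    cov[w] += max(0, min(e, we) - max(s, ws))
        total = int(cov.sum())
        for w in range(nwin):
            wlen = min((w + 1) * window_bp, clen) - w * window_bp
            dens_rows.append((family, chrom, w, int(cov[w]),
                              cov[w] / wlen if wlen else 0.0))
        if total == 0:
            continue
        enriched = cov >= enriched_window_fraction * total
        runs = []
        w = 0
        while w < nwin:
            if enriched[w]:
                start = w
                while w < nwin and enriched[w]:
                    w += 1
                runs.append((start, w))
            else:
                w += 1
        run_cov = sum(int(cov[a:b].sum()) for a, b in runs)
        is_marker = (1 <= len(runs) <= 2
                     and all(b - a <= run_max_windows for a, b in runs)
                     and run_cov >= run_coverage_fraction * total)
        call_rows.append((family, chrom, len(runs),
                          ";".join(f"{a}-{b}" for a, b in runs),
                          bool(is_marker),
                          bool(is_marker and len(runs) == 2)))
    density = pd.DataFrame(dens_rows, columns=["family_name", "chrom",
                                               "window", "covered_bp",
                                               "covered_fraction"])
    calls = pd.DataFrame(call_rows, columns=["family_name", "chrom",
                                             "n_runs", "runs", "is_marker",
                                             "two_regions"])
    return density, calls
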