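"""Placement of reference CDSs on target scaffolds.

Two routes produce the same ``CdsHit`` records: ingesting a standard
12-column tabular hit file (BLAST outfmt-6 compatible) produced by an
external aligner, or the built-in exact matcher, which reports every
exact occurrence of a CDS (forward or reverse complement) on the
scaffolds.  The built-in matcher is intentionally exact-only: it is
verifiable against a brute-force substring oracle, and divergence
handling is delegated to external hit tables.

Reference-side coordinates attached to each hit use the midpoint of the
gene's annotated span as its representative position (orientation
neutral).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._seq import revcomp

log = logging.getLogger(__name__)

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


@dataclass(frozen=True)
class CdsHit:
    """One placement of a reference CDS on a target scaffold."""

    cds_id: str
    scaffold_id: str
    scaffold_start: int  # 0-based half-open on the scaffold
    scaffold_end: int
    strand: str
    evalue: float
    bitscore: float
    identity_pct: float
    ref_chromosome: str | None = None
    ref_position: int | None = None  # midpoint of the gene's reference span

    def __post_init__(self) -> None:
        if self.scaffold_start >= self.scaffold_end:
            raise ValueError("scaffold_start must be < scaffold_end")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class HitFilterConfig:
    max_evalue: float = 1.0e-3  # inclusive: hits at exactly the cutoff pass
    min_identity_pct: float | None = None

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")


# ---------------------------------------------------------------------------
# gene coordinate tables


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read gene coordinates from a 4+ column TSV or a GFF3 file.

    Returns columns gene_id, chrom, start, end (0-based half-open).
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff") or path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils
        db = gffutils.create_db(str(path), ":memory:", merge_strategy="error",
                                keep_order=True)
        rows = [(f.id, f.seqid, f.start - 1, f.end)
                for f in db.features_of_type("gene")]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    tab = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(tab.columns):
        raise ValueError(f"gene table must contain columns {sorted(required)}")
    return tab[["gene_id", "chrom", "start", "end"]]


def _gene_lookup(gene_table: pd.DataFrame) -> dict[str, tuple[str, int]]:
    return {r.gene_id: (r.chrom, (int(r.start) + int(r.end)) // 2)
            for r in gene_table.itertuples()}


def annotate_ref_positions(hits: Iterable[CdsHit],
                           gene_table: pd.DataFrame) -> list[CdsHit]:
    """Attach reference chromosome/midpoint to hits; error on unknown ids."""
    lookup = _gene_lookup(gene_table)
    out, missing = [], []
    for h in hits:
        if h.cds_id not in lookup:
            missing.append(h.cds_id)
            continue
        chrom, mid = lookup[h.cds_id]
        out.append(replace(h, ref_chromosome=chrom, ref_position=mid))
    if missing:
        raise ValueError("query ids missing from gene coordinate table: "
                         + ", ".join(sorted(set(missing))[:20]))
    return out


# ---------------------------------------------------------------------------
# external hit-table ingestion


def ingest_hit_table(path: str | Path,
                     config: HitFilterConfig,
                     gene_table: pd.DataFrame) -> list[CdsHit]:
    """Parse a 12-column tabular hit file, filter, annotate.

    Rows with e-value above ``max_evalue`` are dropped (the cutoff itself
    is retained).  Subject coordinates are converted from the aligner's
    1-based inclusive convention (sstart > send encodes the minus strand)
    to 0-based half-open.
    """
    lookup = _gene_lookup(gene_table)
    hits: list[CdsHit] = []
    n_total = n_dropped = 0
    missing: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"malformed hit row at line {lineno}: expected 12 "
                    f"columns, got {len(fields)}")
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                sstart, send = int(fields[8]), int(fields[9])
                evalue, bitscore = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise ValueError(
                    f"malformed hit row at line {lineno}: {exc}") from exc
            n_total += 1
            if evalue > config.max_evalue:
                n_dropped += 1
                continue
            if (config.min_identity_pct is not None
                    and pident < config.min_identity_pct):
                n_dropped += 1
                continue
            if qseqid not in lookup:
                missing.add(qseqid)
                continue
            if sstart <= send:
                start, end, strand = sstart - 1, send, "+"
            else:
                start, end, strand = send - 1, sstart, "-"
            chrom, mid = lookup[qseqid]
            hits.append(CdsHit(qseqid, sseqid, start, end, strand,
                               evalue, bitscore, pident,
                               ref_chromosome=chrom, ref_position=mid))
    if missing:
        raise ValueError("query ids missing from gene coordinate table: "
                         + ", ".join(sorted(missing)[:20]))
    if n_total == 0:
        log.warning("hit table %s is empty", path)
    log.info("ingested %d hits (%d dropped by filters) from %s",
             len(hits), n_dropped, path)
    return hits


# ---------------------------------------------------------------------------
# built-in exact matcher


def _read_fasta(path_or_dict) -> dict[str, str]:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path_or_dict), "fasta")}


def match_cds_builtin(cds_fasta, scaffold_fasta, k: int = 21,
                      gene_table: pd.DataFrame | None = None
                      ) -> list[CdsHit]:
    """Report every exact occurrence of each CDS on the scaffolds.

    Seeds of length ``k`` (the leading k-mer of each CDS and of its
    reverse complement) are looked up along every scaffold and extended
    to the full-length exact match before a hit is reported.  Matches are
    reported with identity 100, e-value 0 and a length-proportional
    score.  ``k`` larger than the shortest CDS is a configuration error.
    """
    cds = _read_fasta(cds_fasta)
    scaffolds = _read_fasta(scaffold_fasta)
    if not cds:
        return []
    shortest = min(len(s) for s in cds.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest CDS ({shortest} bp)")
    if k < 4:
        raise ValueError("k must be >= 4")

    seeds: dict[str, list[tuple[str, str, str]]] = {}
    for cid, seq in cds.items():
        rc = revcomp(seq)
        seeds.setdefault(seq[:k], []).append((cid, seq, "+"))
        seeds.setdefault(rc[:k], []).append((cid, rc, "-"))

    hits: list[CdsHit] = []
    for sid in sorted(scaffolds):
        s = scaffolds[sid]
        n = len(s)
        for i in range(n - k + 1):
            cand = seeds.get(s[i: i + k])
            if cand is None:
                continue
            for cid, full, strand in cand:
                if s.startswith(full, i):
                    hits.append(CdsHit(cid, sid, i, i + len(full), strand,
                                       evalue=0.0,
                                       bitscore=2.0 * len(full),
                                       identity_pct=100.0))
    if gene_table is not None:
        hits = annotate_ref_positions(hits, gene_table)
    return hits


# ---------------------------------------------------------------------------
# best-hit reduction


def best_hit_per_cds(hits: Sequence[CdsHit]) -> list[CdsHit]:
    """Keep one placement per cds_id.

    Policy (the upstream study does not state its multi-hit handling, so
    this is an explicit, logged choice): minimum e-value, ties broken by
    maximum bitscore, then lexicographically smallest scaffold_id, then
    smallest scaffold_start.  Idempotent.
    """
    best: dict[str, CdsHit] = {}
    n_discarded = 0
    for h in hits:
        cur = best.get(h.cds_id)
        if cur is None:
            best[h.cds_id] = h
            continue
        n_discarded += 1
        key_new = (h.evalue, -h.bitscore, h.scaffold_id, h.scaffold_start)
        key_cur = (cur.evalue, -cur.bitscore, cur.scaffold_id,
                   cur.scaffold_start)
        if key_new < key_cur:
            best[h.cds_id] = h
    if n_discarded:
        log.info("best-hit reduction: kept %d placements, discarded %d "
                 "secondary hits", len(best), n_discarded)
    return [best[c] for c in sorted(best)]


def hits_to_frame(hits: Sequence[CdsHit]) -> pd.DataFrame:
    return pd.DataFrame([vars(h) for h in hits])


def write_hits(hits: Sequence[CdsHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
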