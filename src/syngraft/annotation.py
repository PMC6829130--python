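"""Gene-annotation quality metrics.

Parses a gene -> mRNA -> exon/CDS hierarchy from GFF3, computes the
standard gene-model summary statistics (gene counts, gene space, mean
gene/exon/intron sizes, isoform counts), the annotation edit distance
(AED) of each isoform against transcript evidence, and the cumulative
AED concordance curve used to compare two annotations.

AED here is computed at nucleotide granularity against the single
best-overlapping evidence item: sensitivity is the overlapping bases
over the evidence footprint, specificity the overlapping bases over the
model footprint, and AED = 1 - (sn + sp) / 2, so 0 means an identical
footprint and 1 means no evidence support at all.  This is a
simplification of the full multi-evidence metric but preserves its
thresholding behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._intervals import intersect_bp, merge_intervals, union_bp

Interval = tuple[int, int]


@dataclass
class AedScore:
    mrna_id: str
    aed: float
    sensitivity: float
    specificity: float


@dataclass
class AnnotationSummary:
    n_genes: int
    total_gene_space_bp: int
    gene_space_pct: float | None
    mean_gene_size_bp: float | None
    mean_exons_per_mrna: float | None
    mean_exon_size_bp: float | None
    mean_intron_size_bp: float | None
    n_isoforms: int
    mean_isoforms_per_gene: float | None

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


@dataclass
class GeneModelSet:
    """Validated gene/mRNA/exon hierarchy, 0-based half-open internally."""

    genes: pd.DataFrame   # gene_id, chrom, start, end, strand
    mrnas: pd.DataFrame   # mrna_id, gene_id, chrom, start, end
    exons: pd.DataFrame   # mrna_id, chrom, start, end

    @classmethod
    def from_gff3(cls, path_or_text: str | Path) -> "GeneModelSet":
        import gffutils
        from gffutils.exceptions import EmptyInputError
        text = str(path_or_text)
        empty_cols = {
            "genes": ["gene_id", "chrom", "start", "end", "strand"],
            "mrnas": ["mrna_id", "gene_id", "chrom", "start", "end"],
            "exons": ["mrna_id", "chrom", "start", "end"],
        }
        try:
            if "\n" in text or text.startswith("##gff"):
                db = gffutils.create_db(text, ":memory:", from_string=True,
                                        merge_strategy="create_unique",
                                        keep_order=True)
            else:
                db = gffutils.create_db(text, ":memory:",
                                        merge_strategy="create_unique",
                                        keep_order=True)
        except EmptyInputError:
            return cls(*(pd.DataFrame(columns=c) for c in empty_cols.values()))
        genes, mrnas, exons = [], [], []
        gene_ids = set()
        for g in db.features_of_type("gene"):
            gene_ids.add(g.id)
            genes.append((g.id, g.seqid, g.start - 1, g.end, g.strand))
        orphans = []
        for m in db.features_of_type("mRNA"):
            parents = m.attributes.get("Parent", [])
            if not parents or parents[0] not in gene_ids:
                orphans.append(m.id)
                continue
            mrnas.append((m.id, parents[0], m.seqid, m.start - 1, m.end))
            m_exons = sorted(db.children(m, featuretype="exon"),
                             key=lambda f: f.start)
            if not m_exons:
                orphans.append(m.id)
                continue
            for ex in m_exons:
                exons.append((m.id, ex.seqid, ex.start - 1, ex.end))
        if orphans:
            raise ValueError("malformed gene hierarchy; orphan or exon-less "
                             "mRNAs: " + ", ".join(sorted(orphans)))
        return cls(
            pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                         "strand"]),
            pd.DataFrame(mrnas, columns=["mrna_id", "gene_id", "chrom",
                                         "start", "end"]),
            pd.DataFrame(exons, columns=["mrna_id", "chrom", "start", "end"]),
        )

    def mrna_footprints(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for r in self.exons.itertuples():
            out.setdefault(r.mrna_id, []).append((int(r.start), int(r.end)))
        return {m: merge_intervals(iv) for m, iv in out.items()}


# ---------------------------------------------------------------------------
# summary statistics


def summarize_annotation(models: GeneModelSet,
                         assembly_bp: int | None = None
                         ) -> AnnotationSummary:
    """Gene-model summary table.

    Gene space is the union of gene spans per chromosome (overlapping
    genes counted once); intron sizes are the gaps between consecutive
    exons within each mRNA; means use the natural denominators (exons
    over all exons, introns over all introns).  An empty annotation
    reports zero counts and absent (None) means.
    """
    n_genes = len(models.genes)
    if n_genes == 0:
        return AnnotationSummary(0, 0, None, None, None, None, None, 0, None)

    per_chrom: dict[str, list[Interval]] = {}
    for r in models.genes.itertuples():
        per_chrom.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    gene_space = sum(union_bp(iv) for iv in per_chrom.values())

    gene_sizes = (models.genes["end"] - models.genes["start"]).to_numpy()
    exon_sizes = (models.exons["end"] - models.exons["start"]).to_numpy()

    intron_sizes: list[int] = []
    exon_counts: list[int] = []
    for _mid, grp in models.exons.groupby("mrna_id", sort=False):
        ivs = sorted(zip(grp["start"], grp["end"]))
        exon_counts.append(len(ivs))
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError("overlapping exons within one mRNA")
            intron_sizes.append(s1 - e0)

    n_isoforms = len(models.mrnas)
    return AnnotationSummary(
        n_genes=n_genes,
        total_gene_space_bp=int(gene_space),
        gene_space_pct=(100.0 * gene_space / assembly_bp
                        if assembly_bp else None),
        mean_gene_size_bp=float(np.mean(gene_sizes)),
        mean_exons_per_mrna=float(np.mean(exon_counts)) if exon_counts else None,
        mean_exon_size_bp=float(np.mean(exon_sizes)) if len(exon_sizes) else None,
        mean_intron_size_bp=(float(np.mean(intron_sizes))
                             if intron_sizes else None),
        n_isoforms=n_isoforms,
        mean_isoforms_per_gene=n_isoforms / n_genes,
    )


# ---------------------------------------------------------------------------
# AED


def compute_aed(mrna_id: str, model_footprint: Sequence[Interval],
                evidence_footprints: Sequence[Sequence[Interval]]
                ) -> AedScore:
    """Annotation edit distance against the best-overlapping evidence.

    AED = 1 - (sensitivity + specificity) / 2 where, for the evidence
    item maximizing nucleotide overlap with the model, sensitivity is
    overlap / evidence bases and specificity is overlap / model bases.
    With no overlapping evidence AED is 1.
    """
    model = merge_intervals(model_footprint)
    model_bp = union_bp(model)
    if model_bp == 0:
        raise ValueError(f"empty model footprint for {mrna_id}")
    best = (0, 0)  # (overlap, evidence_bp)
    for ev in evidence_footprints:
        ev_bp = union_bp(ev)
        if ev_bp == 0:
            continue
        ov = intersect_bp(model, ev)
        if ov > best[0]:
            best = (ov, ev_bp)
    if best[0] == 0:
        return AedScore(mrna_id, 1.0, 0.0, 0.0)
    sn = best[0] / best[1]
    sp = best[0] / model_bp
    return AedScore(mrna_id, 1.0 - (sn + sp) / 2.0, sn, sp)


def score_annotation(models: GeneModelSet,
                     evidence: GeneModelSet) -> list[AedScore]:
    """AED of every isoform against evidence transcripts on its chromosome."""
    ev_by_chrom: dict[str, list[list[Interval]]] = {}
    ev_foot = evidence.mrna_footprints()
    chrom_of = dict(zip(evidence.mrnas["mrna_id"], evidence.mrnas["chrom"]))
    for mid, fp in ev_foot.items():
        ev_by_chrom.setdefault(chrom_of[mid], []).append(fp)
    scores = []
    model_foot = models.mrna_footprints()
    mchrom = dict(zip(models.mrnas["mrna_id"], models.mrnas["chrom"]))
    for mid in models.mrnas["mrna_id"]:
        scores.append(compute_aed(mid, model_foot[mid],
                                  ev_by_chrom.get(mchrom[mid], [])))
    return scores


def aed_fraction_below(scores: Sequence[AedScore], threshold: float,
                       strict: bool = True) -> float:
    """Percent of isoforms with AED < threshold (or <= when strict=False)."""
    if not scores:
        raise ValueError("no AED scores")
    if strict:
        n = sum(1 for s in scores if s.aed < threshold)
    else:
        n = sum(1 for s in scores if s.aed <= threshold)
    return 100.0 * n / len(scores)


def cumulative_aed_curve(scores: Sequence[AedScore],
                         thresholds: Iterable[float] | None = None
                         ) -> pd.DataFrame:
    """Cumulative fraction of isoforms with AED <= t for each threshold.

    Monotone non-decreasing; reaches exactly 1.0 at t = 1 since AED is
    bounded by 1.
    """
    if not scores:
        raise ValueError("cumulative curve requires >= 1 score")
    if thresholds is None:
        thresholds = np.round(np.linspace(0.0, 1.0, 21), 3)
    aeds = np.array([s.aed for s in scores])
    rows = [(float(t), float((aeds <= t).mean())) for t in thresholds]
    return pd.DataFrame(rows, columns=["threshold", "cumulative_fraction"])


# ---------------------------------------------------------------------------
# comparison


def compare_annotations(summary_a: AnnotationSummary,
                        summary_b: AnnotationSummary,
                        labels: tuple[str, str] = ("a", "b")) -> pd.DataFrame:
    """Side-by-side table with signed deltas; absent values stay absent."""
    sa, sb = summary_a.to_series(), summary_b.to_series()
    rows = []
    for key in sa.index:
        va, vb = sa[key], sb[key]
        delta = (vb - va) if (va is not None and vb is not None) else None
        rows.append((key, va, vb, delta))
    return pd.DataFrame(rows, columns=["metric", labels[0], labels[1],
                                       "delta"])
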