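"""Synthetic reference/target genome pairs with known truth.

The simulator emulates the situation faced when lifting a fragmented
assembly onto the chromosome structure of a syntenic relative: a
reference genome carrying ordered genes, a target genome that is largely
collinear but carries a configurable fraction of translocated genes and
inverted segments, fragmentation of the target into scaffolds of mixed
sizes (some with too few genes to anchor), N-gap runs inside scaffolds,
random scaffold orientation, and planted transposable-element families
with the hallmark structural features (terminal inverted repeats, target
site duplications, LTR-like direct terminal repeats).

Every stage emits machine-readable truth tables so downstream anchoring,
pseudomolecule construction and TE detection can be scored exactly.

Internally a chromosome is a list of typed blocks (background sequence,
gene, planted TE, N-gap).  All rearrangement and insertion operators work
at block granularity, which makes conservation invariants (the scaffold
partition reconstructs the target byte-for-byte; gene content is
conserved reference -> target) hold by construction rather than by
bookkeeping.  Coordinates in all truth tables are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import random_sequence, revcomp

_MIN_INTERGENIC = 20  # bp floor between consecutive genes


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TeSeedSpec:
    """One transposable-element family to plant in the genome.

    te_class "TIR" elements carry exact reverse-complement termini of
    ``tir_length_bp`` flanked by a ``tsd_length_bp`` target-site
    duplication; "LTR" elements carry direct terminal repeats; "Helitron"
    elements are plain insertions.  ``clustered`` confines every copy to
    one narrow window (centromere-like distribution).
    """

    family_name: str
    te_class: str  # LTR | TIR | Helitron
    element_length_bp: int
    tir_length_bp: int = 0
    tsd_length_bp: int = 0
    copy_number: int = 1
    clustered: bool = False
    cluster_window_bp: int = 2_000_000

    def __post_init__(self) -> None:
        if self.te_class not in {"LTR", "TIR", "Helitron"}:
            raise ValueError(f"unknown te_class {self.te_class!r}")
        if self.te_class == "TIR" and self.tir_length_bp < 10:
            raise ValueError("TIR families require tir_length_bp >= 10")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if self.element_length_bp <= 2 * self.tir_length_bp:
            raise ValueError("element_length_bp must exceed both termini")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic reference/target pair."""

    seed: int
    n_chromosomes: int = 11
    chrom_length_bp: int = 1_000_000
    n_genes_per_chrom: int = 100
    gene_length_bp: int = 400
    translocation_fraction: float = 0.0
    inversion_fraction: float = 0.0
    n_scaffolds_per_chrom: int = 20
    small_scaffold_fraction: float = 0.3
    gap_run_length_bp: int = 100
    te_families: tuple[TeSeedSpec, ...] = ()
    inversion_segment_genes: int = 5

    def __post_init__(self) -> None:
        for name in ("translocation_fraction", "inversion_fraction",
                     "small_scaffold_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes", "chrom_length_bp", "n_genes_per_chrom",
                     "gene_length_bp", "n_scaffolds_per_chrom"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        object.__setattr__(self, "te_families", tuple(self.te_families))


# ---------------------------------------------------------------------------
# block genome


@dataclass
class Block:
    kind: str  # bg | gene | te | gap
    seq: str
    label: str = ""
    strand: str = "+"

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


@dataclass
class BlockGenome:
    """A genome as per-chromosome block lists plus materialised views."""

    chroms: dict[str, list[Block]]
    discordant: dict[str, bool] = field(default_factory=dict)

    def sequences(self) -> dict[str, str]:
        return {c: "".join(b.seq for b in blocks)
                for c, blocks in self.chroms.items()}

    def chrom_lengths(self) -> dict[str, int]:
        return {c: sum(len(b.seq) for b in blocks)
                for c, blocks in self.chroms.items()}

    def gene_table(self) -> pd.DataFrame:
        rows = []
        for chrom, blocks in self.chroms.items():
            pos = 0
            for b in blocks:
                if b.kind == "gene":
                    rows.append((b.label, chrom, pos, pos + len(b.seq),
                                 b.strand))
                pos += len(b.seq)
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start",
                                           "end", "strand"])

    def te_table(self) -> pd.DataFrame:
        rows = []
        for chrom, blocks in self.chroms.items():
            pos = 0
            for b in blocks:
                if b.kind == "te":
                    rows.append((b.label, chrom, pos, pos + len(b.seq),
                                 b.strand))
                pos += len(b.seq)
        return pd.DataFrame(rows, columns=["family_name", "chrom", "start",
                                           "end", "strand"])

    def gene_sequences(self) -> dict[str, str]:
        out = {}
        for blocks in self.chroms.values():
            for b in blocks:
                if b.kind == "gene":
                    # always reported on the forward strand of the gene
                    out[b.label] = b.seq if b.strand == "+" else revcomp(b.seq)
        return out

    def copy(self) -> "BlockGenome":
        return BlockGenome(
            {c: [dataclasses.replace(b) for b in blocks]
             for c, blocks in self.chroms.items()},
            dict(self.discordant),
        )


def random_genome(lengths: dict[str, int], seed: int) -> BlockGenome:
    """Uniform-background genome with no genes (clean TE-detection null)."""
    rng = np.random.default_rng([int(seed), 99])
    return BlockGenome({c: [Block("bg", random_sequence(n, rng))]
                        for c, n in lengths.items()})


# ---------------------------------------------------------------------------
# reference


def _chrom_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def simulate_reference(config: SimulationConfig) -> BlockGenome:
    """Reference genome: ordered, non-overlapping genes on uniform background.

    Raises a sizing error naming the offending chromosome when the
    requested genes cannot fit inside ``chrom_length_bp``.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    chroms: dict[str, list[Block]] = {}
    for ci in range(config.n_chromosomes):
        chrom = _chrom_name(ci)
        n = config.n_genes_per_chrom
        lo = max(30, int(config.gene_length_bp * 0.8))
        hi = max(lo + 1, int(config.gene_length_bp * 1.2) + 1)
        lengths = rng.integers(lo, hi, size=n)
        need = int(lengths.sum()) + (n + 1) * _MIN_INTERGENIC
        if need > config.chrom_length_bp:
            raise ValueError(
                f"cannot fit {n} genes of ~{config.gene_length_bp} bp into "
                f"{config.chrom_length_bp} bp on {chrom} "
                f"(minimum {need} bp required)")
        spare = config.chrom_length_bp - need
        gaps = rng.multinomial(spare, np.full(n + 1, 1.0 / (n + 1)))
        gaps = gaps + _MIN_INTERGENIC
        blocks: list[Block] = []
        for gi in range(n):
            blocks.append(Block("bg", random_sequence(int(gaps[gi]), rng)))
            gid = f"{chrom}g{gi:04d}"
            blocks.append(Block("gene", random_sequence(int(lengths[gi]), rng),
                                label=gid, strand="+"))
        blocks.append(Block("bg", random_sequence(int(gaps[n]), rng)))
        chroms[chrom] = blocks
    return BlockGenome(chroms)


# ---------------------------------------------------------------------------
# target derivation


def derive_target(reference: BlockGenome, config: SimulationConfig) -> BlockGenome:
    """Collinear target genome with planted translocations and inversions.

    Every reference gene is carried over exactly once.  A fraction
    ``translocation_fraction`` of genes (rounded to the nearest count) is
    moved to a uniformly chosen *different* chromosome and flagged
    discordant; ``inversion_fraction`` of multi-gene segments (runs of
    ``inversion_segment_genes`` consecutive genes) is reversed in order
    and strand.  Intergenic background is redrawn, so only the genes are
    shared sequence between reference and target.
    """
    rng = np.random.default_rng([int(config.seed), 2])
    ref_genes = reference.gene_sequences()
    order: dict[str, list[str]] = {
        c: [b.label for b in blocks if b.kind == "gene"]
        for c, blocks in reference.chroms.items()
    }
    chrom_names = list(order)
    all_ids = [g for c in chrom_names for g in order[c]]
    n_total = len(all_ids)

    # translocations
    n_move = int(round(config.translocation_fraction * n_total))
    moved = set()
    if n_move:
        moved_ids = rng.choice(np.array(all_ids), size=n_move, replace=False)
        src_of = {g: c for c in chrom_names for g in order[c]}
        for gid in moved_ids:
            gid = str(gid)
            src = src_of[gid]
            order[src].remove(gid)
            choices = [c for c in chrom_names if c != src]
            dest = choices[int(rng.integers(0, len(choices)))]
            pos = int(rng.integers(0, len(order[dest]) + 1))
            order[dest].insert(pos, gid)
            moved.add(gid)

    # inversions
    strand_flip: set[str] = set()
    seg = max(2, int(config.inversion_segment_genes))
    segments = []
    for c in chrom_names:
        ids = order[c]
        for s in range(0, len(ids) - 1, seg):
            e = min(s + seg, len(ids))
            if e - s >= 2:
                segments.append((c, s, e))
    n_inv = int(round(config.inversion_fraction * len(segments)))
    if n_inv:
        picks = rng.choice(len(segments), size=n_inv, replace=False)
        for k in sorted(int(p) for p in picks):
            c, s, e = segments[k]
            order[c][s:e] = order[c][s:e][::-1]
            strand_flip.update(order[c][s:e])

    # materialise with fresh background
    chroms: dict[str, list[Block]] = {}
    for c in chrom_names:
        ids = order[c]
        n = len(ids)
        glen = sum(len(ref_genes[g]) for g in ids)
        spare = max(0, config.chrom_length_bp - glen - (n + 1) * _MIN_INTERGENIC)
        gaps = rng.multinomial(spare, np.full(n + 1, 1.0 / (n + 1))) \
            + _MIN_INTERGENIC
        blocks: list[Block] = []
        for gi, gid in enumerate(ids):
            blocks.append(Block("bg", random_sequence(int(gaps[gi]), rng)))
            if gid in strand_flip:
                blocks.append(Block("gene", revcomp(ref_genes[gid]),
                                    label=gid, strand="-"))
            else:
                blocks.append(Block("gene", ref_genes[gid], label=gid,
                                    strand="+"))
        blocks.append(Block("bg", random_sequence(int(gaps[n]), rng)))
        chroms[c] = blocks
    return BlockGenome(chroms, {g: (g in moved) for g in all_ids})


def gene_truth_table(target: BlockGenome) -> pd.DataFrame:
    """Per-gene truth records for the (current) target genome."""
    tab = target.gene_table().rename(columns={"chrom": "chromosome"})
    tab["discordant"] = tab["gene_id"].map(
        lambda g: bool(target.discordant.get(g, False)))
    return tab[["gene_id", "chromosome", "start", "end", "strand",
                "discordant"]]


# ---------------------------------------------------------------------------
# TE planting


def _family_element(spec: TeSeedSpec, rng: np.random.Generator) -> str:
    if spec.te_class == "TIR":
        tir = random_sequence(spec.tir_length_bp, rng)
        core = random_sequence(spec.element_length_bp - 2 * spec.tir_length_bp,
                               rng)
        return tir + core + revcomp(tir)
    if spec.te_class == "LTR":
        ltr_len = min(200, max(10, spec.element_length_bp // 5))
        ltr = random_sequence(ltr_len, rng)
        core = random_sequence(spec.element_length_bp - 2 * ltr_len, rng)
        return ltr + core + ltr
    return random_sequence(spec.element_length_bp, rng)


def plant_te_copies(genome: BlockGenome,
                    te_families: Sequence[TeSeedSpec],
                    seed: int,
                    max_attempts: int = 200) -> BlockGenome:
    """Insert TE family copies into intergenic background.

    Each TIR-class copy is physically flanked by an exact target-site
    duplication of ``tsd_length_bp`` (the insertion-site bases duplicated
    on both sides of the element) and begins/ends with exact
    reverse-complement termini of ``tir_length_bp``.  Clustered families
    confine all copies to one window of ``cluster_window_bp`` on a single
    chromosome.  Insertion only ever splits background blocks, so gene
    and previously planted TE intervals are never disrupted; if no
    background block can host a copy after ``max_attempts`` draws a
    RuntimeError is raised.
    """
    rng = np.random.default_rng([int(seed), 3])
    out = genome.copy()
    chrom_names = list(out.chroms)
    for spec in te_families:
        if spec.copy_number == 0:
            continue
        element = _family_element(spec, rng)
        window = None
        if spec.clustered:
            lens = out.chrom_lengths()
            cands = [c for c in chrom_names
                     if lens[c] >= min(spec.cluster_window_bp, lens[c])]
            chrom = cands[int(rng.integers(0, len(cands)))]
            clen = lens[chrom]
            wlen = min(spec.cluster_window_bp, clen)
            w0 = int(rng.integers(0, max(1, clen - wlen + 1)))
            window = (chrom, w0, w0 + wlen)
        for _copy in range(spec.copy_number):
            placed = False
            for _try in range(max_attempts):
                if window is not None:
                    chrom = window[0]
                else:
                    chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
                blocks = out.chroms[chrom]
                pos = 0
                slots = []
                for bi, b in enumerate(blocks):
                    if b.kind == "bg" and len(b.seq) >= spec.tsd_length_bp + 2:
                        slots.append((bi, pos))
                    pos += len(b.seq)
                if not slots:
                    continue
                bi, bstart = slots[int(rng.integers(0, len(slots)))]
                b = blocks[bi]
                off = int(rng.integers(1, len(b.seq) - spec.tsd_length_bp))
                if window is not None:
                    abspos = bstart + off
                    if not (window[1] <= abspos < window[2]):
                        continue
                strand = "+" if rng.random() < 0.5 else "-"
                ins = element if strand == "+" else revcomp(element)
                left = Block("bg", b.seq[: off + spec.tsd_length_bp])
                right = Block("bg", b.seq[off:])
                te = Block("te", ins, label=spec.family_name, strand=strand)
                blocks[bi: bi + 1] = [left, te, right]
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not place copy of {spec.family_name} after "
                    f"{max_attempts} attempts")
    return out


# ---------------------------------------------------------------------------
# fragmentation


@dataclass
class FragmentationResult:
    """Scaffold set plus the (N-gap bearing) target it partitions.

    ``target`` supersedes the genome passed in: N-gap runs are inserted
    into intergenic background during fragmentation, and the returned
    target is exactly the concatenation of the emitted scaffolds (after
    undoing per-scaffold orientation flips).
    """

    scaffolds: dict[str, str]
    truth_scaffolds: pd.DataFrame
    target: BlockGenome


def _gene_counts_for_chrom(n_genes: int, n_scaffolds: int,
                           small_fraction: float,
                           rng: np.random.Generator) -> list[int]:
    s = n_scaffolds
    k_small = int(round(small_fraction * s))
    if k_small >= s:
        if n_genes > 10 * s:
            raise ValueError(
                f"small_scaffold_fraction=1 infeasible: {n_genes} genes "
                f"cannot fit in {s} scaffolds of <=10 genes")
        counts = list(rng.multinomial(n_genes, np.full(s, 1.0 / s)))
        # rebalance anything over the 10-gene cap
        for i in range(s):
            while counts[i] > 10:
                j = int(np.argmin(counts))
                counts[i] -= 1
                counts[j] += 1
        return [int(c) for c in rng.permutation(counts)]
    small = [int(rng.integers(1, 9)) for _ in range(k_small)]
    while sum(small) > max(0, n_genes - (s - k_small)):
        small[int(np.argmax(small))] -= 1
    rest = n_genes - sum(small)
    n_big = s - k_small
    weights = rng.lognormal(0.0, 1.0, size=n_big)
    big = list(rng.multinomial(rest, weights / weights.sum()))
    counts = small + [int(c) for c in big]
    return [int(c) for c in rng.permutation(counts)]


def fragment_into_scaffolds(target: BlockGenome,
                            config: SimulationConfig) -> FragmentationResult:
    """Partition the target into scaffolds with N-gaps and random flips.

    Every target base lands in exactly one scaffold.  At least
    ``small_scaffold_fraction`` of scaffolds are constructed to carry
    <=10 genes (others may fall below that threshold as well when the
    gene/scaffold ratio is low).  Each scaffold is independently
    reverse-complemented with probability 0.5; truth records the
    orientation and the scaffold's interval on the target chromosome.
    """
    rng = np.random.default_rng([int(config.seed), 4])
    work = target.copy()
    scaffolds: dict[str, str] = {}
    rows = []
    counter = 0
    for chrom in list(work.chroms):
        blocks = work.chroms[chrom]
        gene_total = sum(1 for b in blocks if b.kind == "gene")
        counts = _gene_counts_for_chrom(gene_total, config.n_scaffolds_per_chrom,
                                        config.small_scaffold_fraction, rng)
        boundaries = list(np.cumsum(counts))  # genes seen at each cut
        scaffold_blocks: list[list[Block]] = [[]]
        genes_seen = 0
        cut_idx = 0
        for b in blocks:
            if (b.kind == "bg" and cut_idx < len(boundaries) - 1
                    and genes_seen == boundaries[cut_idx]):
                remaining = b
                # several cuts may fall in the same intergenic stretch
                while (cut_idx < len(boundaries) - 1
                        and genes_seen == boundaries[cut_idx]
                        and len(remaining.seq) >= 2):
                    off = int(rng.integers(1, len(remaining.seq)))
                    scaffold_blocks[-1].append(Block("bg",
                                                     remaining.seq[:off]))
                    scaffold_blocks.append([])
                    remaining = Block("bg", remaining.seq[off:])
                    cut_idx += 1
                scaffold_blocks[-1].append(remaining)
            else:
                if b.kind == "gene":
                    genes_seen += 1
                scaffold_blocks[-1].append(b)

        # insert one N run per scaffold into background (where possible)
        if config.gap_run_length_bp > 0:
            for sb in scaffold_blocks:
                bg_idx = [i for i, b in enumerate(sb)
                          if b.kind == "bg" and len(b.seq) >= 2]
                if not bg_idx:
                    continue
                bi = bg_idx[int(rng.integers(0, len(bg_idx)))]
                b = sb[bi]
                off = int(rng.integers(1, len(b.seq)))
                sb[bi: bi + 1] = [Block("bg", b.seq[:off]),
                                  Block("gap", "N" * config.gap_run_length_bp),
                                  Block("bg", b.seq[off:])]

        # rebuild the chromosome and record truth
        new_blocks: list[Block] = []
        pos = 0
        for sb in scaffold_blocks:
            seq = "".join(b.seq for b in sb)
            if not seq:
                continue
            counter += 1
            sid = f"scaf{counter:05d}"
            flip = bool(rng.random() < 0.5)
            scaffolds[sid] = revcomp(seq) if flip else seq
            n_genes = sum(1 for b in sb if b.kind == "gene")
            rows.append((sid, chrom, pos, pos + len(seq),
                         "-" if flip else "+", n_genes))
            new_blocks.extend(sb)
            pos += len(seq)
        work.chroms[chrom] = new_blocks
    truth = pd.DataFrame(rows, columns=["scaffold_id", "chromosome", "start",
                                        "end", "orientation", "n_genes"])
    return FragmentationResult(scaffolds, truth, work)


# ---------------------------------------------------------------------------
# orchestration + file output


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: BlockGenome
    target: BlockGenome
    scaffolds: dict[str, str]
    truth_scaffolds: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_tes: pd.DataFrame

    @property
    def reference_genes(self) -> pd.DataFrame:
        return self.reference.gene_table()

    @property
    def cds_sequences(self) -> dict[str, str]:
        return self.reference.gene_sequences()


def simulate(config: SimulationConfig, outdir: str | Path | None = None
             ) -> SimulatedDataset:
    """Run the full generator and optionally write the standard file set.

    Files written: reference.fasta, reference_genes.gff3,
    reference_genes.tsv, reference_cds.fasta, target_scaffolds.fasta,
    truth_scaffolds.tsv, truth_genes.tsv, truth_tes.bed.
    """
    reference = simulate_reference(config)
    target = derive_target(reference, config)
    if config.te_families:
        target = plant_te_copies(target, config.te_families, config.seed)
    frag = fragment_into_scaffolds(target, config)
    ds = SimulatedDataset(
        config=config,
        reference=reference,
        target=frag.target,
        scaffolds=frag.scaffolds,
        truth_scaffolds=frag.truth_scaffolds,
        truth_genes=gene_truth_table(frag.target),
        truth_tes=frag.target.te_table(),
    )
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.reference.sequences(), outdir / "reference.fasta")
    write_fasta(ds.cds_sequences, outdir / "reference_cds.fasta")
    write_fasta(ds.scaffolds, outdir / "target_scaffolds.fasta")
    genes = ds.reference_genes
    with open(outdir / "reference_genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples():
            fh.write(f"{r.chrom}\tsyngraft\tgene\t{r.start + 1}\t{r.end}\t."
                     f"\t{r.strand}\t.\tID={r.gene_id}\n")
    genes.to_csv(outdir / "reference_genes.tsv", sep="\t", index=False)
    ds.truth_scaffolds.to_csv(outdir / "truth_scaffolds.tsv", sep="\t",
                              index=False)
    ds.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    with open(outdir / "truth_tes.bed", "w") as fh:
        for r in ds.truth_tes.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.family_name}\t0"
                     f"\t{r.strand}\n")
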