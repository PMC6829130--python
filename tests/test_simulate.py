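"""Synthetic-genome generator: counts, determinism, conservation, TE structure."""

import numpy as np
import pytest

import syngraft as sg
from syngraft._seq import revcomp
from syngraft.simulate import (TeSeedSpec, derive_target,
                               fragment_into_scaffolds, gene_truth_table,
                               plant_te_copies, random_genome,
                               simulate_reference)


def small_cfg(**kw):
    base = dict(seed=1, n_chromosomes=2, chrom_length_bp=60_000,
                n_genes_per_chrom=20, n_scaffolds_per_chrom=4,
                small_scaffold_fraction=0.25)
    base.update(kw)
    return sg.SimulationConfig(**base)


class TestReference:
    def test_counts_follow_config(self):
        ref = simulate_reference(small_cfg())
        assert len(ref.sequences()) == 2
        assert len(ref.gene_table()) == 40

    def test_genes_ordered_nonoverlapping_unique(self):
        genes = simulate_reference(small_cfg()).gene_table()
        assert genes["gene_id"].is_unique
        for _, grp in genes.groupby("chrom"):
            starts, ends = grp["start"].values, grp["end"].values
            assert (starts[1:] >= ends[:-1]).all()

    def test_determinism_byte_identical(self):
        a = simulate_reference(small_cfg())
        b = simulate_reference(small_cfg())
        assert a.sequences() == b.sequences()
        assert a.gene_table().equals(b.gene_table())

    def test_infeasible_packing_names_chromosome(self):
        with pytest.raises(ValueError, match="chr01"):
            simulate_reference(small_cfg(chrom_length_bp=5_000,
                                         gene_length_bp=400))

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="translocation_fraction"):
            small_cfg(translocation_fraction=1.2)


class TestTarget:
    def test_identity_case_no_discordance(self):
        cfg = small_cfg()
        ref = simulate_reference(cfg)
        tgt = derive_target(ref, cfg)
        truth = gene_truth_table(tgt)
        assert truth["discordant"].sum() == 0
        ref_order = ref.gene_table().groupby("chrom")["gene_id"].apply(list)
        tgt_order = tgt.gene_table().groupby("chrom")["gene_id"].apply(list)
        for chrom in ref_order.index:
            assert ref_order[chrom] == tgt_order[chrom]

    def test_translocation_count_exact(self):
        # 12% of 400 genes -> exactly 48 discordant flags
        cfg = sg.SimulationConfig(seed=3, n_chromosomes=4,
                                  chrom_length_bp=60_000,
                                  n_genes_per_chrom=100, gene_length_bp=100,
                                  n_scaffolds_per_chrom=4,
                                  translocation_fraction=0.12)
        tgt = derive_target(simulate_reference(cfg), cfg)
        truth = gene_truth_table(tgt)
        assert truth["discordant"].sum() == round(0.12 * 400) == 48
        # every discordant gene really is on a different chromosome
        ref_chrom = simulate_reference(cfg).gene_table().set_index(
            "gene_id")["chrom"]
        moved = truth[truth["discordant"]]
        assert (moved["chromosome"].values
                != ref_chrom.loc[moved["gene_id"]].values).all()

    def test_gene_content_conserved(self):
        cfg = small_cfg(translocation_fraction=0.2, inversion_fraction=0.3)
        ref = simulate_reference(cfg)
        tgt = derive_target(ref, cfg)
        assert set(ref.gene_sequences()) == set(tgt.gene_sequences())
        assert ref.gene_sequences() == tgt.gene_sequences()

    def test_inversion_reverses_a_segment(self):
        cfg = small_cfg(inversion_fraction=0.5)
        ref = simulate_reference(cfg)
        tgt = derive_target(ref, cfg)
        ref_order = {c: list(g["gene_id"])
                     for c, g in ref.gene_table().groupby("chrom")}
        found_reversed = False
        for chrom, grp in tgt.gene_table().groupby("chrom"):
            ids = list(grp["gene_id"])
            ro = ref_order[chrom]
            for i in range(len(ids) - 1):
                a, b = ids[i], ids[i + 1]
                if a in ro and b in ro and ro.index(a) == ro.index(b) + 1:
                    found_reversed = True
        assert found_reversed
        assert (tgt.gene_table()["strand"] == "-").any()


class TestFragmentation:
    def test_partition_reconstructs_target(self, tiny_dataset):
        ds = tiny_dataset
        target = ds.target.sequences()
        for chrom, grp in ds.truth_scaffolds.groupby("chromosome"):
            grp = grp.sort_values("start")
            rebuilt = "".join(
                revcomp(ds.scaffolds[r.scaffold_id]) if r.orientation == "-"
                else ds.scaffolds[r.scaffold_id] for r in grp.itertuples())
            assert rebuilt == target[chrom]

    def test_every_scaffold_has_one_truth_record(self, tiny_dataset):
        ds = tiny_dataset
        assert set(ds.scaffolds) == set(ds.truth_scaffolds["scaffold_id"])
        assert ds.truth_scaffolds["scaffold_id"].is_unique

    def test_all_small_scaffolds_forced(self):
        cfg = small_cfg(small_scaffold_fraction=1.0)
        frag = fragment_into_scaffolds(
            derive_target(simulate_reference(cfg), cfg), cfg)
        assert (frag.truth_scaffolds["n_genes"] <= 10).all()

    def test_small_fraction_respected(self, tiny_dataset):
        truth = tiny_dataset.truth_scaffolds
        frac_small = (truth["n_genes"] <= 10).mean()
        assert frac_small >= tiny_dataset.config.small_scaffold_fraction

    def test_determinism(self):
        cfg = small_cfg()
        tgt = derive_target(simulate_reference(cfg), cfg)
        a = fragment_into_scaffolds(tgt, cfg)
        b = fragment_into_scaffolds(tgt, cfg)
        assert a.scaffolds == b.scaffolds
        assert a.truth_scaffolds.equals(b.truth_scaffolds)

    def test_gap_runs_inserted(self, tiny_dataset):
        n_with_gap = sum("N" * tiny_dataset.config.gap_run_length_bp in s
                         for s in tiny_dataset.scaffolds.values())
        assert n_with_gap > len(tiny_dataset.scaffolds) // 2


class TestTePlanting:
    def test_tir_structure_by_string_inspection(self):
        g = random_genome({"c": 200_000}, seed=4)
        spec = TeSeedSpec("fam", "TIR", 600, tir_length_bp=15,
                          tsd_length_bp=9, copy_number=3)
        g2 = plant_te_copies(g, [spec], seed=4)
        seq = g2.sequences()["c"]
        truth = g2.te_table()
        assert len(truth) == 3
        for r in truth.itertuples():
            el = seq[r.start:r.end]
            assert len(el) == 600
            assert el[:15] == revcomp(el[-15:])          # inverted termini
            assert seq[r.start - 9:r.start] == seq[r.end:r.end + 9]  # TSD

    def test_zero_copies_leaves_genome_unchanged(self):
        g = random_genome({"c": 50_000}, seed=4)
        spec = TeSeedSpec("fam", "TIR", 600, tir_length_bp=15,
                          tsd_length_bp=9, copy_number=0)
        g2 = plant_te_copies(g, [spec], seed=4)
        assert g2.sequences() == g.sequences()

    def test_clustered_family_confined_to_window(self):
        g = random_genome({"c": 3_000_000}, seed=4)
        spec = TeSeedSpec("fam", "LTR", 2_000, tsd_length_bp=5,
                          copy_number=8, clustered=True,
                          cluster_window_bp=500_000)
        truth = plant_te_copies(g, [spec], seed=4).te_table()
        span = truth["end"].max() - truth["start"].min()
        assert span <= 500_000

    def test_insertion_never_disrupts_genes(self):
        cfg = small_cfg()
        tgt = derive_target(simulate_reference(cfg), cfg)
        before = tgt.gene_sequences()
        spec = TeSeedSpec("fam", "Helitron", 500, copy_number=10)
        after = plant_te_copies(tgt, [spec], seed=9).gene_sequences()
        assert before == after

    def test_impossible_placement_raises(self):
        g = random_genome({"c": 1_000}, seed=4)
        spec = TeSeedSpec("fam", "Helitron", 5_000, copy_number=1)
        g2 = plant_te_copies(g, [spec], seed=4)  # fits: bg is one block
        assert len(g2.te_table()) == 1
        small = random_genome({"c": 3}, seed=4)
        with pytest.raises(RuntimeError, match="could not place"):
            plant_te_copies(small, [TeSeedSpec("f", "TIR", 600,
                                               tir_length_bp=15,
                                               tsd_length_bp=9,
                                               copy_number=1)], seed=4)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            TeSeedSpec("f", "TIR", 600, tir_length_bp=5, tsd_length_bp=9)
        with pytest.raises(ValueError):
            TeSeedSpec("f", "Alu", 600)


class TestWriterDeterminism:
    def test_full_pipeline_outputs_byte_identical(self, tmp_path):
        cfg = small_cfg(te_families=(TeSeedSpec("fam", "TIR", 400,
                                                tir_length_bp=12,
                                                tsd_length_bp=5,
                                                copy_number=3),))
        sg.simulate(cfg, tmp_path / "a")
        sg.simulate(cfg, tmp_path / "b")
        for name in ("reference.fasta", "target_scaffolds.fasta",
                     "truth_scaffolds.tsv", "truth_genes.tsv",
                     "truth_tes.bed", "reference_genes.gff3"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes()), name
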