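"""TE curation, de-novo TIR discovery, map-back, accounting, density."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import syngraft as sg
import syngraft.te as te
from syngraft._intervals import coverage_at_least, merge_intervals, union_bp
from syngraft._seq import random_sequence, revcomp, seq_identity
from syngraft.simulate import TeSeedSpec, plant_te_copies, random_genome


def mutate(seq, rate, rng):
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(out)) < rate):
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


class TestHarvest:
    def test_flank_extension_arithmetic(self, rng):
        genome = {"c": random_sequence(100_000, rng)}
        hits = pd.DataFrame([{"chrom": "c", "start": 50_000, "end": 52_000}])
        ((chrom, s, e, seq),) = sg.harvest_homology_regions(hits, genome,
                                                            5_000)
        assert (chrom, s, e) == ("c", 45_000, 57_000)
        assert seq == genome["c"][45_000:57_000]

    def test_clipped_at_sequence_start(self, rng):
        genome = {"c": random_sequence(20_000, rng)}
        hits = pd.DataFrame([{"chrom": "c", "start": 1_000, "end": 1_500}])
        ((_, s, e, _seq),) = sg.harvest_homology_regions(hits, genome, 5_000)
        assert (s, e) == (0, 6_500)

    def test_overlapping_candidates_merged(self, rng):
        genome = {"c": random_sequence(100_000, rng)}
        hits = pd.DataFrame([{"chrom": "c", "start": 50_000, "end": 51_000},
                             {"chrom": "c", "start": 55_000, "end": 56_000}])
        out = sg.harvest_homology_regions(hits, genome, 5_000)
        assert len(out) == 1
        assert (out[0][1], out[0][2]) == (45_000, 61_000)

    def test_flank_outside_range_rejected(self, rng):
        genome = {"c": random_sequence(1_000, rng)}
        hits = pd.DataFrame([{"chrom": "c", "start": 10, "end": 20}])
        for bad in (4_000, 9_500):
            with pytest.raises(ValueError, match=r"\[5000, 9000\]"):
                sg.harvest_homology_regions(hits, genome, bad)


class TestDerivatives:
    def test_deletion_derivative_recovered(self, rng):
        elem = random_sequence(3_000, rng)
        deriv = elem[:1_000] + elem[2_200:]  # coding middle deleted
        bg = random_sequence(100_000, rng)
        genome = {"c": bg[:20_000] + elem + bg[20_000:60_000]
                  + deriv + bg[60_000:]}
        coding = pd.DataFrame([{"chrom": "c", "start": 21_000,
                                "end": 22_000}])
        found = sg.find_nonautonomous_derivatives([elem], genome, coding)
        assert found == [("c", 63_000, 64_800)]

    def test_no_similar_sequence_zero_derivatives(self, rng):
        elem = random_sequence(2_000, rng)
        genome = {"c": random_sequence(50_000, rng)}
        coding = pd.DataFrame(columns=["chrom", "start", "end"])
        assert sg.find_nonautonomous_derivatives([elem], genome,
                                                 coding) == []

    def test_autonomous_copy_not_double_reported(self, rng):
        elem = random_sequence(3_000, rng)
        bg = random_sequence(40_000, rng)
        genome = {"c": bg[:10_000] + elem + bg[10_000:]}
        coding = pd.DataFrame([{"chrom": "c", "start": 11_000,
                                "end": 12_000}])
        assert sg.find_nonautonomous_derivatives([elem], genome,
                                                 coding) == []


class TestConsensus:
    def test_identical_members_reproduced(self, rng):
        m = random_sequence(800, rng)
        assert sg.build_consensus([m, m, m]) == m

    def test_column_majority(self):
        assert sg.build_consensus(["AAG", "AAG", "AAT"]) == "AAG"

    def test_tie_becomes_iupac(self):
        assert sg.build_consensus(["AAG", "AAT"]) == "AAK"

    def test_single_member_is_error(self):
        with pytest.raises(ValueError):
            sg.build_consensus(["ACGT"])

    def test_mutated_copies_recover_ancestor(self, rng):
        ancestor = random_sequence(1_500, rng)
        members = [mutate(ancestor, 0.05, rng) for _ in range(5)]
        cons = sg.build_consensus(members)
        assert len(cons) == len(ancestor)
        assert seq_identity(cons, ancestor) >= 95.0


class TestTirDetection:
    def test_planted_families_recovered_exactly(self, tir_genome):
        genome, truth = tir_genome
        fams = sg.detect_tir_elements(genome.sequences())
        planted = truth[truth["family_name"] != "lonely"]
        detected = sorted((c, s, e) for f in fams
                          for c, s, e, _ in f.members)
        expected = sorted((r.chrom, r.start, r.end)
                          for r in planted.itertuples())
        assert detected == expected  # 100% recall and precision
        assert len(fams) == planted["family_name"].nunique()
        for f in fams:
            assert f.n_members >= 3
            assert f.tir_length_bp >= 10
            assert f.tsd_length_bp == 9

    def test_single_copy_candidate_rejected(self, tir_genome):
        genome, truth = tir_genome
        fams = sg.detect_tir_elements(genome.sequences())
        lonely = truth[truth["family_name"] == "lonely"]
        assert len(lonely) == 1
        r = lonely.iloc[0]
        for f in fams:
            for c, s, e, _ in f.members:
                assert not (c == r.chrom and s < r.end and r.start < e)

    def test_uniform_genome_yields_no_families(self):
        g = random_genome({"c": 1_500_000}, seed=21)
        assert sg.detect_tir_elements(g.sequences()) == []

    def test_boundaries_unrecoverable_without_tsd(self, rng):
        # without a target-site duplication the exact element boundaries
        # cannot be called: no family may claim the full planted span
        tir = random_sequence(15, rng)
        elem = tir + random_sequence(500, rng) + revcomp(tir)
        bg = random_sequence(400_000, rng)
        seq = bg
        planted = [250_000, 150_000, 50_000]
        for pos in planted:  # descending keeps earlier coordinates valid
            seq = seq[:pos] + elem + seq[pos:]
        spans = [(50_000, 50_530), (150_530, 151_060), (251_060, 251_590)]
        fams = sg.detect_tir_elements({"c": seq})
        full_spans = {(s, e) for f in fams for _c, s, e, _st in f.members}
        assert not (set(spans) & full_spans)


class TestLibraryMapback:
    def test_genome_of_one_consensus_copy(self, rng):
        cons = random_sequence(1_000, rng)
        fam = te.TeFamily("DTX_1", "unknown_TIR", "DNA_subclass1", cons, 3,
                          False)
        anno = sg.annotate_with_library({"c": cons}, [fam])
        assert anno.intervals.values.tolist() \
            == [["c", 0, 1_000, "DTX_1", "unknown_TIR"]]

    def test_planted_copies_full_recall(self, rng):
        cons = random_sequence(1_200, rng)
        positions = [5_000, 20_000, 44_000]
        bg = random_sequence(60_000, rng)
        seq = bg
        for pos in sorted(positions, reverse=True):
            seq = seq[:pos] + cons + seq[pos:]
        fam = te.TeFamily("f", "Gypsy", "retrotransposon", cons, 3, True)
        anno = sg.annotate_with_library({"c": seq}, [fam])
        starts = sorted(anno.intervals["start"])
        assert starts == [5_000, 20_000 + 1_200, 44_000 + 2_400]

    def test_empty_library_empty_annotation(self, rng):
        anno = sg.annotate_with_library({"c": random_sequence(1_000, rng)},
                                        [])
        assert anno.intervals.empty


class TestMergeAccounting:
    def test_interval_arithmetic_worked_example(self):
        a = te.TeAnnotationSet.from_records(
            "manual", [("c", 0, 100, "f1", "Gypsy")])
        b = te.TeAnnotationSet.from_records(
            "repeatmasker", [("c", 91, 191, "f2", "Gypsy")])
        summary = sg.merge_te_sources([a, b], assembly_bp=1_000)
        assert summary.combined_bp == 191
        assert summary.multi_source_overlap_bp == 9

    def test_single_empty_source_all_zero(self):
        s = te.TeAnnotationSet.from_records("manual", [])
        summary = sg.merge_te_sources([s], assembly_bp=1_000)
        assert summary.combined_bp == 0
        assert summary.combined_pct == 0.0
        assert summary.multi_source_overlap_bp == 0

    def test_out_of_bounds_interval_rejected(self):
        s = te.TeAnnotationSet.from_records("manual",
                                            [("c", 0, 500, "f", "Gypsy")])
        with pytest.raises(ValueError, match="bounds"):
            sg.merge_te_sources([s], assembly_bp=1_000,
                                chrom_lengths={"c": 400})

    def test_superfamily_rows_consistent(self):
        rows = [("c", 0, 100, "RLG_1", "Gypsy"),
                ("c", 200, 350, "RLG_2", "Gypsy"),
                ("c", 400, 480, "RLC_1", "Copia")]
        s = te.TeAnnotationSet.from_records("manual", rows)
        summary = sg.merge_te_sources([s], assembly_bp=1_000)
        tab = summary.superfamily_table.set_index("superfamily")
        assert tab.loc["Gypsy", "n_families"] == 2
        assert tab.loc["Gypsy", "te_space_bp"] == 250
        assert tab.loc["Copia", "te_space_pct"] == pytest.approx(8.0)
        assert tab["te_space_bp"].sum() == summary.combined_bp

    def test_agrees_with_bitmask_oracle_many_trials(self):
        rng = np.random.default_rng(99)
        L = 50_000
        for _trial in range(100):
            sets, masks = [], []
            for si in range(int(rng.integers(1, 4))):
                ivs, mask = [], np.zeros(L, dtype=bool)
                for _ in range(int(rng.integers(1, 25))):
                    a = int(rng.integers(0, L - 1))
                    b = int(rng.integers(a + 1, min(L, a + 2_000) + 1))
                    ivs.append(("c", a, b, f"f{si}", "Gypsy"))
                    mask[a:b] = True
                sets.append(te.TeAnnotationSet.from_records(f"s{si}", ivs))
                masks.append(mask)
            summary = sg.merge_te_sources(sets, assembly_bp=L)
            stack = np.vstack(masks)
            assert summary.combined_bp == int(stack.any(axis=0).sum())
            assert summary.multi_source_overlap_bp \
                == int((stack.sum(axis=0) >= 2).sum())
            for mask, s in zip(masks, sets):
                assert s.union_bp() == int(mask.sum())

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 400), st.integers(1, 80)),
                    min_size=1, max_size=25))
    def test_union_matches_bitmask(self, raw):
        ivs = [(a, a + w) for a, w in raw]
        mask = np.zeros(600, dtype=bool)
        for a, b in ivs:
            mask[a:b] = True
        assert union_bp(ivs) == int(mask.sum())
        merged = merge_intervals(ivs)
        assert all(b0 < a1 for (_, b0), (a1, _) in zip(merged, merged[1:]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.tuples(st.integers(0, 300),
                                       st.integers(1, 60)),
                             min_size=1, max_size=8),
                    min_size=1, max_size=4))
    def test_depth_counts_match_bitmask(self, raw_sources):
        sources = [[(a, a + w) for a, w in src] for src in raw_sources]
        masks = []
        for src in sources:
            m = np.zeros(400, dtype=bool)
            for a, b in src:
                m[a:b] = True
            masks.append(m)
        stack = np.vstack(masks)
        for depth in (1, 2, 3):
            assert coverage_at_least(sources, depth) \
                == int((stack.sum(axis=0) >= depth).sum())


class TestDensity:
    def fam(self, intervals):
        return te.TeAnnotationSet.from_records(
            "manual", [("c", s, e, "RLG_V", "Gypsy") for s, e in intervals])

    def test_clustered_family_is_marker(self):
        ivs = [(2_000_000 + i * 20_000, 2_000_000 + i * 20_000 + 8_000)
               for i in range(50)]
        _d, calls = sg.te_density_profile(self.fam(ivs), {"c": 30_000_000})
        row = calls.iloc[0]
        assert row.is_marker and row.n_runs == 1 and not row.two_regions

    def test_scattered_family_not_marker(self):
        ivs = [(i * 1_000_000 + 500, i * 1_000_000 + 6_000)
               for i in range(28)]
        _d, calls = sg.te_density_profile(self.fam(ivs), {"c": 30_000_000})
        assert not calls.iloc[0].is_marker

    def test_two_separated_spans_flag_two_regions(self):
        ivs = [(2_000_000 + i * 20_000, 2_000_000 + i * 20_000 + 8_000)
               for i in range(40)]
        ivs += [(20_000_000 + i * 20_000, 20_000_000 + i * 20_000 + 8_000)
                for i in range(40)]
        _d, calls = sg.te_density_profile(self.fam(ivs), {"c": 30_000_000})
        row = calls.iloc[0]
        assert row.is_marker and row.n_runs == 2 and row.two_regions

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            sg.te_density_profile(self.fam([(0, 10)]), {"c": 100},
                                  window_bp=0)

    def test_clustered_planted_family_detected_via_truth(self):
        g = random_genome({"c": 10_000_000}, seed=31)
        spec = TeSeedSpec("RLG_V", "LTR", 3_000, tsd_length_bp=5,
                          copy_number=15, clustered=True,
                          cluster_window_bp=2_000_000)
        planted = plant_te_copies(g, [spec], seed=31)
        truth = planted.te_table()
        anno = te.TeAnnotationSet.from_records(
            "manual", [(r.chrom, r.start, r.end, r.family_name, "Gypsy")
                       for r in truth.itertuples()])
        _d, calls = sg.te_density_profile(anno, {"c": 10_000_000})
        assert calls.iloc[0].is_marker
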