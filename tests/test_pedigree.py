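import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pedlink.pedigree import (AFFECTED, MISSING, UNAFFECTED, UNCERTAIN,
                              DiseaseModel, Individual, MarkerMap, Pedigree,
                              PedigreeError, cm_to_theta,
                              estimate_allele_freqs, read_mapfile,
                              read_pedfile, theta_to_cm, trim_pedigree,
                              write_pedfile)

from conftest import make_cohort, make_ped


class TestReadPed:
    def test_basic_founder_line(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("F1 A 0 0 1 2 A G\n")
        cohort = read_pedfile(p)
        ped = cohort.families["F1"]
        ind = ped.members["A"]
        assert ind.is_founder and ind.sex == 1 and ind.affection == AFFECTED
        g = ped.genotypes["A"][0]
        assert {cohort.map.alleles[0][g[0]], cohort.map.alleles[0][g[1]]} == {"A", "G"}

    def test_phenotype_zero_is_uncertain(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("F1 A 0 0 2 0 1 2\n")
        cohort = read_pedfile(p)
        assert cohort.families["F1"].members["A"].affection == UNCERTAIN

    def test_half_specified_parents_rejected(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("F1 A 0 0 1 1 1 1\nF1 B A 0 1 2 1 2\n")
        with pytest.raises(PedigreeError, match="half-specified"):
            read_pedfile(p)

    def test_malformed_column_count_names_line(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("F1 A 0 0 1 2 A\n")
        with pytest.raises(PedigreeError, match=":1"):
            read_pedfile(p)

    def test_missing_parent_reference(self, tmp_path):
        p = tmp_path / "t.ped"
        p.write_text("F1 B X Y 1 2 1 2\n")
        with pytest.raises(PedigreeError, match="missing parent"):
            read_pedfile(p)

    def test_roundtrip_bytes(self, tmp_path):
        from pedlink.simulate import CohortSpec, MapSpec, generate_cohort
        spec = CohortSpec(n_families=4, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=4))
        cohort, _ = generate_cohort(spec, seed=7)
        p1 = tmp_path / "a.ped"
        write_pedfile(cohort, p1)
        back = read_pedfile(p1, cohort.map)
        p2 = tmp_path / "b.ped"
        write_pedfile(back, p2)
        assert p1.read_bytes() == p2.read_bytes()
        for fid, ped in cohort.families.items():
            for pid, g in ped.genotypes.items():
                assert np.array_equal(g, back.families[fid].genotypes[pid])


class TestMapfile:
    def test_ordered_spacings(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("1 a 0.0 100\n1 b 0.5 200\n1 c 1.0 300\n")
        mm = read_mapfile(p)
        assert list(np.round(mm.spacings("1"), 6)) == [0.5, 0.5]

    def test_missing_cm_flagged(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("1 a 0.0 100\n1 b NA 200\n")
        mm = read_mapfile(p)
        assert mm.missing_cm.sum() == 1
        assert mm.marker[int(np.flatnonzero(mm.missing_cm)[0])] == "b"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("1 a 0.0 100\n1 a 0.5 200\n")
        with pytest.raises(PedigreeError, match="duplicate"):
            read_mapfile(p)

    def test_freqs_must_sum_to_one(self):
        mm = MarkerMap(["1"], ["a"], [0.0], [100],
                       freqs=[np.array([0.6, 0.5])])
        with pytest.raises(PedigreeError, match="sum to 1"):
            mm.validate()


class TestTrim:
    def test_removes_uninformative_leaf(self):
        rows = [("fa", None, None, 1, UNAFFECTED),
                ("mo", None, None, 2, UNAFFECTED),
                ("c1", "fa", "mo", 1, AFFECTED),
                ("c2", "fa", "mo", 2, UNAFFECTED)]
        ped = make_ped("T", rows, {"fa": [(0, 1)], "mo": [(0, 1)],
                                   "c1": [(0, 0)]})
        assert not ped.members["c2"].sampled
        trimmed = trim_pedigree(ped)
        assert "c2" not in trimmed.members
        assert trimmed.bits == ped.bits - 2

    def test_identity_when_all_sampled(self):
        ped = make_ped("T", [("fa", None, None, 1, UNAFFECTED),
                             ("mo", None, None, 2, UNAFFECTED),
                             ("c1", "fa", "mo", 1, AFFECTED)],
                       {"fa": [(0, 0)], "mo": [(0, 1)], "c1": [(0, 1)]})
        assert set(trim_pedigree(ped).members) == set(ped.members)

    def test_unsampled_founder_parents_retained(self):
        rows = [("gf", None, None, 1, UNAFFECTED),
                ("gm", None, None, 2, UNAFFECTED),
                ("p1", "gf", "gm", 1, AFFECTED),
                ("sp", None, None, 2, UNAFFECTED),
                ("c1", "p1", "sp", 1, AFFECTED)]
        ped = make_ped("T", rows, {"p1": [(0, 1)], "sp": [(1, 1)],
                                   "c1": [(0, 1)]})
        trimmed = trim_pedigree(ped)
        assert "gf" in trimmed.members and "gm" in trimmed.members

    def test_trim_preserves_twopoint_lod(self):
        from pedlink.linkage.twopoint import ThetaGrid, family_lod_curve
        rows = [("fa", None, None, 1, AFFECTED), ("mo", None, None, 2, UNAFFECTED),
                ("c1", "fa", "mo", 1, AFFECTED), ("c2", "fa", "mo", 2, AFFECTED),
                ("c3", "fa", "mo", 1, UNAFFECTED), ("c4", "fa", "mo", 2, UNCERTAIN)]
        ped = make_ped("T", rows, {"fa": [(0, 1)], "mo": [(1, 1)],
                                   "c1": [(0, 1)], "c2": [(0, 1)]})
        dm = DiseaseModel(0.001, (0.0, 0.001, 0.001))
        freqs = np.array([0.4, 0.6])
        a = family_lod_curve(ped, 0, freqs, dm, ThetaGrid())
        b = family_lod_curve(trim_pedigree(ped), 0, freqs, dm, ThetaGrid())
        assert np.allclose(a, b, atol=1e-12)


class TestValidation:
    def test_loop_rejected(self):
        # first cousins marrying: classic consanguinity loop
        rows = [("gf", None, None, 1, UNAFFECTED), ("gm", None, None, 2, UNAFFECTED),
                ("a", "gf", "gm", 1, UNAFFECTED), ("b", "gf", "gm", 2, UNAFFECTED),
                ("c", "a", "b", 1, AFFECTED)]
        # a and b are sibs married to each other -> loop
        with pytest.raises(PedigreeError, match="loop"):
            make_ped("L", rows, {})

    def test_parent_sex_consistency(self):
        rows = [("fa", None, None, 2, UNAFFECTED),   # female listed as father
                ("mo", None, None, 2, UNAFFECTED),
                ("c1", "fa", "mo", 1, AFFECTED)]
        with pytest.raises(PedigreeError, match="inconsistent"):
            make_ped("S", rows, {})


class TestAlleleFreqs:
    def _cohort(self):
        peds = [make_ped(f"F{i}", [("fa", None, None, 1, aff_f),
                                   ("mo", None, None, 2, UNAFFECTED),
                                   ("c1", "fa", "mo", 1, AFFECTED)],
                         {"fa": [g_f], "mo": [g_m], "c1": [(0, 1)]})
                for i, (aff_f, g_f, g_m) in enumerate([
                    (UNAFFECTED, (0, 0), (0, 1)),
                    (UNAFFECTED, (1, 1), (0, 1))])]
        return make_cohort(peds, [[0.5, 0.5]])

    def test_counting_estimate(self):
        # founder genotypes {AA, AB, BB, AB} -> freq(B) = 0.5
        cohort = self._cohort()
        mm = estimate_allele_freqs(cohort, who="founders")
        assert mm.freqs[0][1] == pytest.approx(0.5)

    def test_unaffected_founders_excludes_affected(self):
        peds = [make_ped("F1", [("fa", None, None, 1, AFFECTED),
                                ("mo", None, None, 2, UNAFFECTED),
                                ("c1", "fa", "mo", 1, AFFECTED)],
                         {"fa": [(1, 1)], "mo": [(0, 0)], "c1": [(0, 1)]})]
        cohort = make_cohort(peds, [[0.5, 0.5]])
        mm = estimate_allele_freqs(cohort, who="unaffected_founders")
        assert mm.freqs[0][0] == pytest.approx(1.0)

    def test_all_missing_marker_flagged(self):
        peds = [make_ped("F1", [("fa", None, None, 1, UNAFFECTED),
                                ("mo", None, None, 2, UNAFFECTED),
                                ("c1", "fa", "mo", 1, AFFECTED)],
                         {"c1": [(0, 1)]})]
        cohort = make_cohort(peds, [[0.5, 0.5]])
        mm = estimate_allele_freqs(cohort, who="founders")
        assert mm.freqs[0] is None

    def test_empty_class_errors(self):
        peds = [make_ped("F1", [("fa", None, None, 1, AFFECTED),
                                ("mo", None, None, 2, AFFECTED),
                                ("c1", "fa", "mo", 1, AFFECTED)],
                         {"fa": [(0, 0)], "mo": [(0, 1)], "c1": [(0, 1)]})]
        cohort = make_cohort(peds, [[0.5, 0.5]])
        with pytest.raises(PedigreeError):
            estimate_allele_freqs(cohort, who="unaffected_founders")

    def test_gene_drop_convergence(self):
        from pedlink.simulate import CohortSpec, MapSpec, generate_cohort
        spec = CohortSpec(n_families=40, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=12, spacing_cm=5.0),
            missing_rate=0.0, p_unsampled_founder=0.0)
        cohort, truth = generate_cohort(spec, seed=11)
        estimate_allele_freqs(cohort, who="founders")
        n_founders = sum(len(p.founders()) for p in cohort)
        ok = 0
        for j, p_true in enumerate(truth.marker_freqs):
            p_hat = cohort.map.freqs[j][0]
            bound = 3 * math.sqrt(p_true * (1 - p_true) / (2 * n_founders))
            ok += abs(p_hat - p_true) < bound
        assert ok / len(truth.marker_freqs) >= 0.95


class TestMapFunctions:
    def test_zero(self):
        assert cm_to_theta(0.0) == 0.0

    def test_haldane_50cm(self):
        assert cm_to_theta(50.0) == pytest.approx(0.31606, abs=1e-4)

    def test_asymptote(self):
        assert cm_to_theta(1e6) == pytest.approx(0.5, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cm_to_theta(-1.0)

    @given(st.floats(min_value=0.0, max_value=300.0))
    def test_roundtrip(self, d):
        assert theta_to_cm(cm_to_theta(d)) == pytest.approx(d, abs=1e-8)

    @given(st.floats(min_value=0.0, max_value=200.0))
    def test_kosambi_leq_haldane_distance_effect(self, d):
        assert cm_to_theta(d, "kosambi") >= cm_to_theta(d, "haldane") - 1e-12
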