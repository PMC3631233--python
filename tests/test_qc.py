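import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedlink.pedigree import (AFFECTED, MISSING, UNAFFECTED,
                              estimate_allele_freqs)
from pedlink.qc import (QCThresholds, hwe_exact_test, inbreeding_coefficient,
                        inbreeding_outliers, mendelian_error_scan,
                        select_multipoint_markers, snp_filter_cascade)

from conftest import make_cohort, make_ped
from oracles import hwe_exact_oracle


class TestMendelScan:
    def _cohort(self, genos):
        ped = make_ped("F1", [("fa", None, None, 1, UNAFFECTED),
                              ("mo", None, None, 2, UNAFFECTED),
                              ("c1", "fa", "mo", 1, AFFECTED)], genos)
        return make_cohort([ped], [[0.5, 0.5]])

    def test_ppc_error(self):
        cohort = self._cohort({"fa": [(0, 0)], "mo": [(0, 0)], "c1": [(0, 1)]})
        errs = mendelian_error_scan(cohort)
        assert len(errs) == 1 and errs.iloc[0]["kind"] == "P-P-C"

    def test_pc_error_single_parent(self):
        cohort = self._cohort({"fa": [(0, 0)], "c1": [(1, 1)]})
        errs = mendelian_error_scan(cohort)
        assert len(errs) == 1 and errs.iloc[0]["kind"] == "P-C"

    def test_het_parents_never_error(self):
        for child in [(0, 0), (0, 1), (1, 1)]:
            cohort = self._cohort({"fa": [(0, 1)], "mo": [(0, 1)],
                                   "c1": [child]})
            assert mendelian_error_scan(cohort).empty

    def test_clean_gene_drop_no_errors(self):
        from pedlink.simulate import CohortSpec, MapSpec, generate_cohort
        spec = CohortSpec(n_families=10, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=6), missing_rate=0.0)
        cohort, _ = generate_cohort(spec, seed=5)
        assert mendelian_error_scan(cohort).empty


class TestHWE:
    def test_worked_example_3_0_3(self):
        # full enumeration over het counts {0,2,4,6} gives 20/924
        assert hwe_exact_test(3, 0, 3) == pytest.approx(20 / 924, abs=1e-12)

    def test_monomorphic(self):
        assert hwe_exact_test(10, 0, 0) == 1.0

    def test_p_at_least_observed_probability(self):
        p = hwe_exact_test(25, 50, 25)
        assert 0 < p <= 1.0
        assert p == pytest.approx(hwe_exact_oracle(25, 50, 25), abs=1e-12)

    @given(st.integers(0, 17), st.integers(0, 17), st.integers(0, 16))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, naa, nab, nbb):
        if naa + nab + nbb == 0:
            return
        assert hwe_exact_test(naa, nab, nbb) == pytest.approx(
            hwe_exact_oracle(naa, nab, nbb), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 0)


def planted_fixture(seed=101):
    """30-family cohort, 100 SNPs, defects matching the worked QC example:
    5 low-call-rate, 3 Mendel-heavy, 4 low-MAF, 2 HWE, 2 duplicate-bp."""
    from pedlink.simulate import CohortSpec, DefectSpec, MapSpec, generate_cohort
    spec = CohortSpec(
        n_families=30,
        map_spec=MapSpec(n_chromosomes=4, markers_per_chrom=25,
                         spacing_cm=2.0, maf_mean=0.35, maf_sd=0.05,
                         min_maf=0.2),
        missing_rate=0.0, p_unsampled_founder=0.0, uncertain_rate=0.0,
        defects=DefectSpec(n_low_call_rate=5, n_mendel=3, n_low_maf=4,
                           n_hwe=2, n_dup_bp=2))
    return generate_cohort(spec, seed=seed)


class TestCascade:
    def test_planted_fixture_counts_exact(self):
        cohort, truth = planted_fixture()
        filtered, report = snp_filter_cascade(cohort)
        counts = report.counts()
        assert counts == {"call_rate": 5, "batch": 0, "mendel": 3, "maf": 4,
                          "hwe": 2, "dup_bp": 2, "missing_cm": 0, "dup_cm": 0}
        assert report.n_surviving == 84
        for filt, markers in truth.defects.items():
            assert sorted(report.removed[filt]) == markers
        total_removed = sum(len(v) for v in report.removed.values())
        assert total_removed == report.n_input - report.n_surviving

    def test_mendel_masks_whole_family(self):
        ped = make_ped("F1", [("fa", None, None, 1, UNAFFECTED),
                              ("mo", None, None, 2, UNAFFECTED),
                              ("c1", "fa", "mo", 1, AFFECTED),
                              ("c2", "fa", "mo", 2, AFFECTED)],
                       {"fa": [(0, 0), (0, 1)], "mo": [(0, 0), (0, 1)],
                        "c1": [(0, 1), (0, 1)], "c2": [(0, 0), (0, 0)]},
                       n_markers=2)
        ped2 = make_ped("F2", [("fa", None, None, 1, UNAFFECTED),
                               ("mo", None, None, 2, UNAFFECTED),
                               ("c1", "fa", "mo", 1, AFFECTED),
                               ("c2", "fa", "mo", 2, AFFECTED)],
                        {"fa": [(0, 1), (0, 1)], "mo": [(0, 1), (0, 1)],
                         "c1": [(0, 1), (0, 1)], "c2": [(0, 0), (0, 0)]},
                        n_markers=2)
        cohort = make_cohort([ped, ped2], [[0.5, 0.5], [0.5, 0.5]])
        th = QCThresholds(min_call_rate=0.0, mendel_family_frac=0.9,
                          min_maf=0.0, hwe_alpha=1e-9)
        filtered, report = snp_filter_cascade(cohort, th)
        fam = filtered.families["F1"]
        j = filtered.map.index("m0")
        assert all(np.all(g[j] == MISSING) for g in fam.genotypes.values())
        fam2 = filtered.families["F2"]
        assert not any(np.all(g[j] == MISSING) for g in fam2.genotypes.values())

    def test_dup_cm_two_decimal_rule(self):
        ped = make_ped("F1", [("fa", None, None, 1, UNAFFECTED),
                              ("mo", None, None, 2, UNAFFECTED),
                              ("c1", "fa", "mo", 1, AFFECTED)],
                       {"fa": [(0, 1), (0, 1)], "mo": [(0, 1), (0, 1)],
                        "c1": [(0, 1), (0, 1)]}, n_markers=2)
        cohort = make_cohort([ped], [[0.5, 0.5], [0.5, 0.5]],
                             cm=[12.339, 12.344])
        th = QCThresholds(min_call_rate=0.0, min_maf=0.0, hwe_alpha=1e-12)
        filtered, report = snp_filter_cascade(cohort, th)
        assert report.removed["dup_cm"] == ["m1"]
        assert filtered.map.marker == ["m0"]

    def test_deterministic_report(self):
        cohort1, _ = planted_fixture()
        cohort2, _ = planted_fixture()
        _, r1 = snp_filter_cascade(cohort1)
        _, r2 = snp_filter_cascade(cohort2)
        assert r1.removed == r2.removed and r1.masked == r2.masked

    def test_bad_threshold_config(self):
        with pytest.raises(ValueError):
            QCThresholds(min_call_rate=1.5)

    def test_low_loss_on_clean_common_markers(self):
        from pedlink.simulate import CohortSpec, MapSpec, generate_cohort
        spec = CohortSpec(n_families=25, map_spec=MapSpec(
            n_chromosomes=2, markers_per_chrom=25, maf_mean=0.35,
            maf_sd=0.05, min_maf=0.2), missing_rate=0.0,
            p_unsampled_founder=0.0)
        cohort, _ = generate_cohort(spec, seed=13)
        _, report = snp_filter_cascade(cohort)
        lost = len(report.removed["maf"]) + len(report.removed["hwe"])
        assert lost / report.n_input < 0.02


class TestInbreeding:
    def test_fully_heterozygous_gives_minus_one(self):
        g = np.zeros((40, 2), dtype=np.int16)
        g[:, 1] = 1
        freqs = [np.array([0.5, 0.5])] * 40
        assert inbreeding_coefficient(g, freqs) == pytest.approx(-1.0)

    def test_autozygous_gives_one(self):
        g = np.zeros((40, 2), dtype=np.int16)
        freqs = [np.array([0.5, 0.5])] * 40
        assert inbreeding_coefficient(g, freqs) == pytest.approx(1.0)

    def test_hwe_cohort_mean_near_zero(self):
        rng = np.random.default_rng(3)
        n_markers, n_samples, p = 150, 200, 0.4
        freqs = [np.array([p, 1 - p])] * n_markers
        fs = []
        for _ in range(n_samples):
            g = (rng.random((n_markers, 2)) > p).astype(np.int16)
            fs.append(inbreeding_coefficient(g, freqs))
        se = np.std(fs) / math.sqrt(n_samples)
        assert abs(np.mean(fs)) < 3 * se + 1e-3

    def test_outlier_flagging(self):
        from pedlink.simulate import CohortSpec, MapSpec, generate_cohort
        spec = CohortSpec(n_families=15, map_spec=MapSpec(
            n_chromosomes=2, markers_per_chrom=20), missing_rate=0.0)
        cohort, _ = generate_cohort(spec, seed=2)
        estimate_allele_freqs(cohort, who="founders")
        fid = next(iter(cohort.families))
        ped = cohort.families[fid]
        pid = next(iter(ped.genotypes))
        ped.genotypes[pid][:, 1] = ped.genotypes[pid][:, 0]  # force autozygous
        df = inbreeding_outliers(cohort, f_sd_limit=4.0)
        row = df[(df["family"] == fid) & (df["person"] == pid)]
        assert bool(row["outlier"].iloc[0])


class TestMultipointSelection:
    def _map(self, n=10, spacing=0.1, mafs=None):
        from pedlink.pedigree import MarkerMap
        mafs = mafs if mafs is not None else [0.3] * n
        return MarkerMap(["1"] * n, [f"m{i}" for i in range(n)],
                         [i * spacing for i in range(n)],
                         [100 * (i + 1) for i in range(n)],
                         freqs=[np.array([m, 1 - m]) for m in mafs])

    def test_target_spacing(self):
        thinned, mean_sp, _ = select_multipoint_markers(self._map(), 0.3)
        assert len(thinned) == 4
        assert mean_sp == pytest.approx(0.3, abs=0.05)

    def test_maf_tie_goes_to_lower_bp(self):
        thinned, _, _ = select_multipoint_markers(self._map(n=3, spacing=0.05),
                                                  1.0)
        assert thinned.marker == ["m0"]

    def test_highest_maf_wins(self):
        mm = self._map(n=3, spacing=0.05, mafs=[0.1, 0.4, 0.2])
        thinned, _, mean_maf = select_multipoint_markers(mm, 1.0)
        assert thinned.marker == ["m1"]
        assert mean_maf == pytest.approx(0.4)

    def test_oversized_window_keeps_one(self):
        thinned, _, _ = select_multipoint_markers(self._map(), 100.0)
        assert len(thinned) == 1

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            select_multipoint_markers(self._map(), 0.0)
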