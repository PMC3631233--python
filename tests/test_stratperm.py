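import numpy as np
import pandas as pd
import pytest

from pedlink.pedigree import estimate_allele_freqs
from pedlink.linkage.scan import EngineConfig, genome_tables, scan_from_tables
from pedlink.simulate import (CTD_CONDITIONS, CohortSpec, MapSpec,
                              generate_heterogeneity_cohort)
from pedlink.stratperm import (PermutationDistribution, StratificationRule,
                               SubsetEvaluator, conditional_permutation,
                               observed_maxima, run_stratified_permutation,
                               stratified_scan, stratify)


def flags_frame(rows):
    df = pd.DataFrame([{**{c: False for c in CTD_CONDITIONS}, **r,
                        "family": fid} for fid, r in rows]).set_index("family")
    return df


@pytest.fixture(scope="module")
def small_hetero():
    spec = CohortSpec(n_families=10,
                      map_spec=MapSpec(n_chromosomes=2, markers_per_chrom=4,
                                       spacing_cm=5.0),
                      linked_chrom="1", linked_pos_cm=10.0,
                      missing_rate=0.0)
    return generate_heterogeneity_cohort(spec, n_positive=5, n_negative=5,
                                         seed=2)


class TestStratify:
    def test_condition_list(self, small_hetero):
        cohort, flags, truth = small_hetero
        f2 = flags_frame([(fid, {"scoliosis": fid.endswith("1")})
                          for fid in cohort.families])
        pos, neg = stratify(cohort, f2)
        assert set(pos) == {f for f in cohort.families if f.endswith("1")}
        assert set(pos) | set(neg) == set(cohort.families)

    def test_missing_family_errors(self, small_hetero):
        cohort, flags, _ = small_hetero
        with pytest.raises(ValueError, match="lacking"):
            stratify(cohort, flags.iloc[:-1])

    def test_generated_flags_match_truth(self, small_hetero):
        cohort, flags, truth = small_hetero
        pos, neg = stratify(cohort, flags)
        assert {f for f in truth.strata if truth.strata[f] == "CTD-positive"} \
            == set(pos)


class TestStratifiedScan:
    def test_multipoint_lod_additivity_over_strata(self, small_hetero):
        cohort, flags, _ = small_hetero
        estimate_allele_freqs(cohort, who="founders")
        cfg = EngineConfig(step_cm=None)
        res = stratified_scan(cohort, flags, cfg, refit_freqs=False)
        tables = genome_tables(cohort, cfg)
        _, mp_all = scan_from_tables(tables["1"])
        mp_pos = res["CTD-positive"][1]
        mp_neg = res["CTD-negative"][1]
        a = mp_pos[mp_pos.chrom == "1"]["lod"].to_numpy()
        b = mp_neg[mp_neg.chrom == "1"]["lod"].to_numpy()
        assert np.allclose(a + b, np.array(mp_all.lod), atol=1e-12)

    def test_single_family_stratum(self, small_hetero):
        cohort, flags, _ = small_hetero
        estimate_allele_freqs(cohort, who="founders")
        fids = list(cohort.families)
        f2 = flags_frame([(fid, {"aneurysm": fid == fids[0]})
                          for fid in fids])
        cfg = EngineConfig(step_cm=None)
        res = stratified_scan(cohort, f2, cfg, refit_freqs=False)
        tables = genome_tables(cohort, cfg)
        _, mp_one = scan_from_tables(tables["1"], fids=[fids[0]])
        got = res["CTD-positive"][1]
        assert np.allclose(got[got.chrom == "1"]["lod"].to_numpy(),
                           np.array(mp_one.lod), atol=1e-12)

    def test_empty_stratum_errors(self, small_hetero):
        cohort, flags, _ = small_hetero
        f2 = flags_frame([(fid, {}) for fid in cohort.families])
        with pytest.raises(ValueError, match="no families"):
            stratified_scan(cohort, f2)


@pytest.fixture(scope="module")
def tables(small_hetero):
    cohort, flags, _ = small_hetero
    estimate_allele_freqs(cohort, who="founders")
    return genome_tables(cohort, EngineConfig(step_cm=None))


class TestConditionalPermutation:

    def test_draw_count_and_reproducibility(self, tables):
        obs = observed_maxima(tables, list(tables["1"].families)[:5])
        d1 = conditional_permutation(tables, obs, reps=20, seed=9)
        d2 = conditional_permutation(tables, obs, reps=20, seed=9)
        for key in d1.draws:
            for r in d1.draws[key]:
                assert len(d1.draws[key][r]) == 40
                assert np.array_equal(d1.draws[key][r], d2.draws[key][r])
        d3 = conditional_permutation(tables, obs, reps=20, seed=10)
        assert any(not np.array_equal(d1.draws[k][r], d3.draws[k][r])
                   for k in d1.draws for r in d1.draws[k])

    def test_p_boundaries(self, tables):
        key = ("parametric", "twopoint")
        obs_low = {k: {r: -1.0 for r in list(tables) + ["GW"]}
                   for k in [(m, s) for m in ("parametric", "npl_linear",
                                              "npl_exponential")
                             for s in ("twopoint", "multipoint")]}
        d = conditional_permutation(tables, obs_low, reps=20, seed=1)
        n = 40
        assert d.p_add_one[key]["GW"] == pytest.approx((n + 1) / (n + 1))
        obs_high = {k: {r: 1e9 for r in list(tables) + ["GW"]}
                    for k in obs_low}
        d = conditional_permutation(tables, obs_high, reps=20, seed=1)
        assert d.p_add_one[key]["GW"] == pytest.approx(1 / (n + 1))
        assert d.p_raw[key]["GW"] == 0.0

    def test_p_monotone_in_observed(self, tables):
        keys = list({(m, s) for m in ("parametric", "npl_linear",
                                      "npl_exponential")
                     for s in ("twopoint", "multipoint")})
        regions = list(tables) + ["GW"]
        ps = []
        for obs_val in (0.0, 0.3, 0.8, 2.0):
            obs = {k: {r: obs_val for r in regions} for k in keys}
            d = conditional_permutation(tables, obs, reps=30, seed=3)
            ps.append(d.p_add_one[("npl_linear", "multipoint")]["GW"])
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_evaluator_consistent_with_scan(self, tables):
        """GW parametric two-point maximum from the fast evaluator matches a
        direct scan at the evaluator's alpha resolution."""
        fids = list(tables["1"].families)
        ev = SubsetEvaluator(tables, alpha_step=0.01)
        mx = ev.maxima(fids)
        best = 0.0
        for t in tables.values():
            tp, _ = scan_from_tables(t)
            best = max(best, max(tp.hlod))
        assert mx[("parametric", "twopoint")]["GW"] == pytest.approx(best,
                                                                     abs=1e-9)

    def test_run_wrapper_table(self, small_hetero):
        cohort, flags, _ = small_hetero
        dist, _ = run_stratified_permutation(cohort, flags,
                                             EngineConfig(step_cm=None),
                                             reps=10, seed=0)
        df = dist.to_frame()
        assert set(df["model"]) == {"parametric", "npl_linear",
                                    "npl_exponential"}
        assert set(df["region"]) == {"1", "2", "GW"}
        assert ((df["p_emp"] > 0) & (df["p_emp"] <= 1)).all()
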