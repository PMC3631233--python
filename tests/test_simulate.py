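import dataclasses
import math

import numpy as np
import pytest

from pedlink.pedigree import AFFECTED, MISSING, cm_to_theta
from pedlink.qc import mendelian_error_scan
from pedlink.simulate import (CTD_CONDITIONS, CohortSpec, DefectSpec, MapSpec,
                              _bit_path, emit_files, generate_cohort,
                              generate_heterogeneity_cohort, plant_defects)


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path):
        spec = CohortSpec(n_families=6, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=5))
        outs = []
        for d in ("a", "b"):
            cohort, truth = generate_cohort(spec, seed=42)
            paths = emit_files(cohort, truth, tmp_path / d)
            outs.append(paths)
        for key in ("ped", "map", "truth"):
            assert open(outs[0][key], "rb").read() == \
                open(outs[1][key], "rb").read()

    def test_different_seeds_differ(self):
        spec = CohortSpec(n_families=6, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=5))
        c1, _ = generate_cohort(spec, seed=1)
        c2, _ = generate_cohort(spec, seed=2)
        g1 = next(iter(c1.families.values())).genotypes
        g2 = next(iter(c2.families.values())).genotypes
        assert any(not np.array_equal(g1[p], g2[p]) for p in g1 if p in g2)


class TestAscertainment:
    def test_min_two_affected_sampled(self):
        spec = CohortSpec(n_families=20, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=3))
        cohort, _ = generate_cohort(spec, seed=9)
        for ped in cohort:
            n = sum(1 for m in ped.members.values()
                    if m.affection == AFFECTED and m.sampled)
            assert n >= 2

    def test_affected_per_family_mean_target(self):
        spec = CohortSpec(n_families=66, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=2))
        means = []
        for seed in (0, 1, 2):
            cohort, _ = generate_cohort(spec, seed=seed)
            counts = [len(p.affected()) for p in cohort]
            means.append(np.mean(counts))
        assert abs(np.mean(means) - 2.77) < 0.45

    def test_infeasible_quota_errors(self):
        from pedlink.pedigree import DiseaseModel
        spec = CohortSpec(n_families=1, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=2),
            gen_model=DiseaseModel(1e-6, (0.0, 1e-6, 1e-6)),
            max_ascertainment_tries=50)
        with pytest.raises(RuntimeError, match="increase"):
            generate_cohort(spec, seed=0)


class TestBitPath:
    def test_flip_rate_matches_haldane(self):
        rng = np.random.default_rng(0)
        cm = np.array([0.0, 10.0])
        theta = cm_to_theta(10.0)
        flips = sum(int(p[0] != p[1]) for p in
                    (_bit_path(cm, rng, None, None) for _ in range(4000)))
        se = math.sqrt(theta * (1 - theta) / 4000)
        assert abs(flips / 4000 - theta) < 4 * se

    def test_anchored_path_flip_rate(self):
        rng = np.random.default_rng(1)
        cm = np.array([5.0, 30.0])
        anchor = 15.0
        th_left = cm_to_theta(10.0)
        n = 4000
        left_flips = 0
        for _ in range(n):
            p = _bit_path(cm, rng, anchor, 0)
            left_flips += p[0] != 0
        se = math.sqrt(th_left * (1 - th_left) / n)
        assert abs(left_flips / n - th_left) < 4 * se


class TestDefects:
    def test_mendel_plants_found_by_scan(self):
        spec = CohortSpec(n_families=20, map_spec=MapSpec(
            n_chromosomes=2, markers_per_chrom=8), missing_rate=0.0,
            defects=DefectSpec(n_mendel=3, mendel_n_families=2))
        cohort, truth = generate_cohort(spec, seed=17)
        errs = mendelian_error_scan(cohort)
        for marker, fams in truth.mendel_families.items():
            found = set(errs[errs["marker"] == marker]["family"])
            assert set(fams) <= found
        assert set(errs["marker"]) == set(truth.defects["mendel"])

    def test_call_rate_target(self):
        spec = CohortSpec(n_families=30, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=10), missing_rate=0.0,
            p_unsampled_founder=0.0,
            defects=DefectSpec(n_low_call_rate=2, call_rate_target=0.9))
        cohort, truth = generate_cohort(spec, seed=23)
        for marker in truth.defects["call_rate"]:
            j = cohort.map.index(marker)
            called = total = 0
            for ped in cohort:
                for pid, g in ped.genotypes.items():
                    if ped.members[pid].sampled:
                        total += 1
                        called += int(np.all(g[j] != MISSING))
            assert abs(called / total - 0.9) < 0.03

    def test_empty_defect_spec_identity(self):
        spec = CohortSpec(n_families=5, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=5))
        cohort, truth = generate_cohort(spec, seed=3)
        rng = np.random.default_rng(0)
        c2, t2 = plant_defects(cohort, DefectSpec(), rng)
        for fid, ped in cohort.families.items():
            for pid, g in ped.genotypes.items():
                assert np.array_equal(g, c2.families[fid].genotypes[pid])
        assert t2.defects == {}

    def test_quota_overflow_errors(self):
        spec = CohortSpec(n_families=5, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=4))
        cohort, _ = generate_cohort(spec, seed=3)
        with pytest.raises(ValueError, match="quota"):
            plant_defects(cohort, DefectSpec(n_low_call_rate=5),
                          np.random.default_rng(0))


class TestHeterogeneity:
    def test_strata_sizes_and_flags(self):
        spec = CohortSpec(n_families=66, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=4),
            linked_chrom="1", linked_pos_cm=0.5)
        cohort, flags, truth = generate_heterogeneity_cohort(
            spec, n_positive=34, n_negative=32, seed=5)
        assert len(cohort) == 66
        pos = [f for f, s in truth.strata.items() if s == "CTD-positive"]
        neg = [f for f, s in truth.strata.items() if s == "CTD-negative"]
        assert (len(pos), len(neg)) == (34, 32)
        assert set(flags.columns) == set(CTD_CONDITIONS)
        for f in pos:
            assert flags.loc[f].any()
        for f in neg:
            assert not flags.loc[f].any()
        # default: only the negative stratum is linked
        for f in pos:
            assert not truth.linked[f]
        for f in neg:
            assert truth.linked[f]

    def test_null_mode_no_linkage_truth(self):
        spec = CohortSpec(n_families=10, map_spec=MapSpec(
            n_chromosomes=1, markers_per_chrom=4),
            linked_chrom="1", linked_pos_cm=0.5)
        _, _, truth = generate_heterogeneity_cohort(
            spec, n_positive=5, n_negative=5,
            positive_linked=False, negative_linked=False, seed=5)
        assert not any(truth.linked.values())
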