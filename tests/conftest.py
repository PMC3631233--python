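from __future__ import annotations

import numpy as np
import pytest

from pedlink.pedigree import (AFFECTED, MISSING, UNAFFECTED, UNCERTAIN, Cohort,
                              DiseaseModel, Individual, MarkerMap, Pedigree)


def make_ped(fid, rows, genos=None, n_markers=1):
    """rows: (pid, father, mother, sex, affection); genos: pid -> list of
    allele pairs (None -> fully missing)."""
    members = [Individual(pid, fid, fa, mo, sex, aff)
               for pid, fa, mo, sex, aff in rows]
    gd = {}
    for m in members:
        pairs = (genos or {}).get(m.pid)
        arr = np.full((n_markers, 2), MISSING, dtype=np.int16)
        if pairs is not None:
            for j, p in enumerate(pairs):
                if p is not None:
                    arr[j] = p
        else:
            m.sampled = False
        gd[m.pid] = arr
    ped = Pedigree(fid, members, gd)
    ped.validate()
    return ped


NUCLEAR = [("fa", None, None, 1, UNAFFECTED), ("mo", None, None, 2, UNAFFECTED),
           ("c1", "fa", "mo", 1, AFFECTED), ("c2", "fa", "mo", 2, AFFECTED)]


@pytest.fixture
def sib_pair_ibd2():
    """Affected sib pair, fully informative marker, certain IBD = 2."""
    return make_ped("SP2", NUCLEAR, {
        "fa": [(0, 1)], "mo": [(2, 3)], "c1": [(0, 2)], "c2": [(0, 2)]})


@pytest.fixture
def sib_pair_ibd0():
    return make_ped("SP0", NUCLEAR, {
        "fa": [(0, 1)], "mo": [(2, 3)], "c1": [(0, 2)], "c2": [(1, 3)]})


@pytest.fixture
def phase_known_ten_meioses():
    """Grandparents fix the affected father's phase; ten affected children,
    all nonrecombinant.  Full-penetrance dominant model."""
    rows = [("gf", None, None, 1, AFFECTED), ("gm", None, None, 2, UNAFFECTED),
            ("fa", "gf", "gm", 1, AFFECTED), ("mo", None, None, 2, UNAFFECTED)]
    genos = {"gf": [(0, 0)], "gm": [(1, 1)], "fa": [(0, 1)], "mo": [(1, 1)]}
    for k in range(10):
        rows.append((f"c{k}", "fa", "mo", 1 + k % 2, AFFECTED))
        genos[f"c{k}"] = [(0, 1)]
    return make_ped("PK", rows, genos)


def oracle_fixture_battery():
    """(name, ped, freqs, dm, use_unaffected) tuples, <=8 members each, for
    likelihood-oracle equivalence."""
    dm_dom = DiseaseModel(0.001, (0.0, 1.0, 1.0))
    dm_pen = DiseaseModel(0.02, (0.05, 0.9, 0.9))   # phenocopies allowed
    dm_low = DiseaseModel(0.001, (0.0, 0.001, 0.001))
    dm_add = DiseaseModel(0.1, (0.05, 0.5, 0.9))
    f = [0.3, 0.7]
    fx = []

    trio_a = [("fa", None, None, 1, AFFECTED), ("mo", None, None, 2, UNAFFECTED),
              ("c1", "fa", "mo", 1, AFFECTED)]
    trio = [("fa", None, None, 1, UNAFFECTED), ("mo", None, None, 2, UNAFFECTED),
            ("c1", "fa", "mo", 1, AFFECTED)]
    fx.append(("trio_full", make_ped("T1", trio_a,
               {"fa": [(0, 1)], "mo": [(0, 0)], "c1": [(0, 1)]}), f, dm_dom, True))
    fx.append(("trio_low", make_ped("T2", trio,
               {"fa": [(0, 1)], "mo": [(0, 0)], "c1": [(0, 1)]}), f, dm_low, False))
    fx.append(("trio_missing_child", make_ped("T3", trio,
               {"fa": [(0, 1)], "mo": [(1, 1)]}), f, dm_add, False))

    quad = NUCLEAR
    for name, genos, dm, ua in [
        ("sibs_ibd2", {"fa": [(0, 1)], "mo": [(0, 1)],
                       "c1": [(0, 0)], "c2": [(0, 0)]}, dm_pen, True),
        ("sibs_low", {"fa": [(0, 1)], "mo": [(0, 1)],
                      "c1": [(0, 1)], "c2": [(1, 1)]}, dm_low, False),
        ("sibs_add", {"fa": [(0, 0)], "mo": [(0, 1)],
                      "c1": [(0, 0)], "c2": [(0, 1)]}, dm_add, False),
        ("sibs_untyped_parent", {"mo": [(0, 1)],
                                 "c1": [(0, 0)], "c2": [(0, 1)]}, dm_low, False),
    ]:
        fx.append((name, make_ped(name, quad, genos), f, dm, ua))

    five = quad + [("c3", "fa", "mo", 1, UNAFFECTED)]
    fx.append(("five_mixed", make_ped("F5", five,
               {"fa": [(0, 1)], "mo": [(0, 1)], "c1": [(0, 0)],
                "c2": [(0, 1)], "c3": [(1, 1)]}), f, dm_pen, True))
    fx.append(("five_low", make_ped("F5b", five,
               {"fa": [(0, 1)], "mo": [(1, 1)], "c1": [(0, 1)],
                "c2": [(0, 1)], "c3": [(1, 1)]}), f, dm_low, False))

    tg = [("gf", None, None, 1, UNAFFECTED), ("gm", None, None, 2, AFFECTED),
          ("p1", "gf", "gm", 1, AFFECTED), ("sp", None, None, 2, UNAFFECTED),
          ("c1", "p1", "sp", 1, AFFECTED), ("c2", "p1", "sp", 2, UNAFFECTED)]
    fx.append(("three_gen", make_ped("G3", tg,
               {"gf": [(1, 1)], "gm": [(0, 1)], "p1": [(0, 1)], "sp": [(1, 1)],
                "c1": [(0, 1)], "c2": [(1, 1)]}), f, dm_dom, True))
    fx.append(("three_gen_low", make_ped("G3b", tg,
               {"gm": [(0, 1)], "p1": [(0, 1)], "sp": [(1, 1)],
                "c1": [(0, 1)], "c2": [(1, 1)]}), f, dm_low, False))
    fx.append(("three_gen_add", make_ped("G3c", tg,
               {"gf": [(0, 0)], "gm": [(0, 1)], "p1": [(0, 0)], "sp": [(0, 1)],
                "c1": [(0, 0)], "c2": [(0, 1)]}), f, dm_add, False))

    # two marriages: father with two mates
    dbl = [("fa", None, None, 1, AFFECTED), ("m1", None, None, 2, UNAFFECTED),
           ("m2", None, None, 2, UNAFFECTED),
           ("c1", "fa", "m1", 1, AFFECTED), ("c2", "fa", "m1", 2, UNAFFECTED),
           ("c3", "fa", "m2", 1, AFFECTED)]
    fx.append(("two_marriages", make_ped("DM", dbl,
               {"fa": [(0, 1)], "m1": [(1, 1)], "m2": [(0, 1)],
                "c1": [(0, 1)], "c2": [(1, 1)], "c3": [(0, 0)]}), f, dm_dom, True))
    fx.append(("two_marriages_low", make_ped("DMb", dbl,
               {"fa": [(0, 1)], "m1": [(1, 1)], "m2": [(0, 1)],
                "c1": [(0, 1)], "c2": [(1, 1)], "c3": [(0, 0)]}), f, dm_low, False))

    eight = [("gf", None, None, 1, UNAFFECTED), ("gm", None, None, 2, UNAFFECTED),
             ("p1", "gf", "gm", 1, AFFECTED), ("p2", "gf", "gm", 2, UNAFFECTED),
             ("sp", None, None, 2, UNAFFECTED),
             ("c1", "p1", "sp", 1, AFFECTED), ("c2", "p1", "sp", 2, AFFECTED),
             ("c3", "p1", "sp", 1, UNCERTAIN)]
    fx.append(("eight_member", make_ped("E8", eight,
               {"gf": [(0, 1)], "gm": [(1, 1)], "p1": [(0, 1)], "p2": [(1, 1)],
                "sp": [(1, 1)], "c1": [(0, 1)], "c2": [(0, 1)],
                "c3": [(1, 1)]}), f, dm_pen, True))
    fx.append(("eight_low", make_ped("E8b", eight,
               {"gf": [(0, 1)], "gm": [(1, 1)], "p1": [(0, 1)], "p2": [(1, 1)],
                "sp": [(0, 1)], "c1": [(0, 1)], "c2": [(0, 0)],
                "c3": [(1, 1)]}), f, dm_low, False))
    fx.append(("eight_add", make_ped("E8c", eight,
               {"gf": [(0, 1)], "gm": [(0, 1)], "p1": [(0, 1)], "p2": [(0, 0)],
                "sp": [(0, 1)], "c1": [(0, 1)], "c2": [(0, 0)],
                "c3": [(0, 1)]}), f, dm_add, False))

    # skewed allele frequencies
    fx.append(("skewed_freqs", make_ped("SK", quad,
               {"fa": [(0, 1)], "mo": [(0, 1)], "c1": [(0, 0)],
                "c2": [(0, 1)]}), [0.05, 0.95], dm_low, False))
    fx.append(("skewed_dom", make_ped("SKb", five,
               {"fa": [(0, 1)], "mo": [(1, 1)], "c1": [(0, 1)],
                "c2": [(0, 1)], "c3": [(1, 1)]}), [0.9, 0.1], dm_pen, True))
    fx.append(("uncertain_only", make_ped("UC", [
        ("fa", None, None, 1, UNCERTAIN), ("mo", None, None, 2, UNCERTAIN),
        ("c1", "fa", "mo", 1, AFFECTED), ("c2", "fa", "mo", 2, AFFECTED)],
        {"fa": [(0, 1)], "mo": [(0, 1)], "c1": [(0, 1)], "c2": [(0, 1)]}),
        f, dm_low, False))
    assert len(fx) >= 20
    return fx


def make_cohort(peds, freqs_per_marker, cm=None, chrom=None):
    n = peds[0].genotypes[next(iter(peds[0].genotypes))].shape[0]
    chrom = chrom or ["1"] * n
    cm = cm if cm is not None else [float(j) for j in range(n)]
    mm = MarkerMap(chrom, [f"m{j}" for j in range(n)], cm,
                   [int((j + 1) * 1e5) for j in range(n)],
                   alleles=[[str(k + 1) for k in range(len(f))]
                            for f in freqs_per_marker],
                   freqs=[np.asarray(f, float) for f in freqs_per_marker])
    return Cohort({p.fid: p for p in peds}, mm)
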