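"""Independent brute-force oracles used to validate the engines.

These deliberately avoid the package's factor-elimination, descent and
emission code paths: plain Python enumeration only.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from pedlink.pedigree import AFFECTED, MISSING, UNAFFECTED

# state s in 0..15 encodes ordered haplotype pair (pat*4 + mat);
# haplotype h in 0..3 encodes (disease_allele*2 + marker_allele)


def _hap(s):
    return s // 4, s % 4


@lru_cache(maxsize=64)
def _trans_table(theta: float):
    t = {}
    for s in range(16):
        hp, hm = _hap(s)
        probs = {}
        for h, w in ((hp, (1 - theta) / 2), (hm, (1 - theta) / 2),
                     (((hp >> 1) << 1) | (hm & 1), theta / 2),
                     (((hm >> 1) << 1) | (hp & 1), theta / 2)):
            probs[h] = probs.get(h, 0.0) + w
        t[s] = probs
    return t


def _state_weight(s, ind, genotype, dm, use_unaffected):
    hp, hm = _hap(s)
    dose = (hp >> 1) + (hm >> 1)
    w = 1.0
    if ind.affection == AFFECTED:
        w = dm.penetrances[dose]
    elif ind.affection == UNAFFECTED and use_unaffected:
        w = 1.0 - dm.penetrances[dose]
    a, b = genotype
    mp, mm_ = hp & 1, hm & 1
    if a != MISSING and b != MISSING:
        if {mp, mm_} != {a, b} and (mp, mm_) != (a, b) and (mm_, mp) != (a, b):
            return 0.0
    elif (a == MISSING) != (b == MISSING):
        known = a if a != MISSING else b
        if known not in (mp, mm_):
            return 0.0
    return w


def enum_two_locus_likelihood(ped, marker_j, freqs, dm, theta,
                              use_unaffected=False) -> float:
    """Exhaustive sum over per-person ordered two-locus states (pruned to
    states with nonzero evidence weight)."""
    members = ped.topological()
    q = dm.allele_freq
    pm = (1.0 - freqs[0], freqs[0])  # careful: index by marker allele below
    hapf = [0.0] * 4
    for h in range(4):
        d, m = h >> 1, h & 1
        hapf[h] = (q if d else 1.0 - q) * (freqs[m])
    trans = _trans_table(theta)
    cand = []
    for ind in members:
        g = ped.genotype(ind.pid, marker_j)
        states = [(s, _state_weight(s, ind, g, dm, use_unaffected))
                  for s in range(16)]
        cand.append([(s, w) for s, w in states if w > 0])

    idx = {m.pid: i for i, m in enumerate(members)}
    total = 0.0
    for combo in itertools.product(*[range(len(c)) for c in cand]):
        prob = 1.0
        states = [cand[i][k][0] for i, k in enumerate(combo)]
        for i, ind in enumerate(members):
            s, w = cand[i][combo[i]]
            prob *= w
            hp, hm = _hap(s)
            if ind.is_founder:
                prob *= hapf[hp] * hapf[hm]
            else:
                fs = states[idx[ind.father]]
                ms = states[idx[ind.mother]]
                prob *= trans[fs].get(hp, 0.0) * trans[ms].get(hm, 0.0)
            if prob == 0.0:
                break
        total += prob
    return total


def _descent_slots(ped, vector):
    """pid -> (pat slot, mat slot) for one inheritance vector (int)."""
    members = ped.topological()
    founders = [m.pid for m in members if m.is_founder]
    nf = [m for m in members if not m.is_founder]
    fslot = {pid: (2 * i, 2 * i + 1) for i, pid in enumerate(founders)}
    slots = dict(fslot)
    for k, m in enumerate(nf):
        pat_bit = (vector >> (2 * k)) & 1
        mat_bit = (vector >> (2 * k + 1)) & 1
        slots[m.pid] = (slots[m.father][pat_bit], slots[m.mother][mat_bit])
    return slots


def enum_inheritance_posterior(ped, marker_j, freqs):
    """Posterior over inheritance vectors from one marker, by enumerating
    founder-allele assignments per vector."""
    members = ped.topological()
    founders = [m.pid for m in members if m.is_founder]
    n_bits = 2 * sum(1 for m in members if not m.is_founder)
    n_slots = 2 * len(founders)
    K = len(freqs)
    obs = {m.pid: ped.genotype(m.pid, marker_j) for m in members}
    post = []
    for v in range(1 << n_bits):
        slots = _descent_slots(ped, v)
        tot = 0.0
        for assign in itertools.product(range(K), repeat=n_slots):
            p = 1.0
            for a in assign:
                p *= freqs[a]
            ok = True
            for pid, (a, b) in obs.items():
                if a == MISSING and b == MISSING:
                    continue
                s1, s2 = slots[pid]
                have = (assign[s1], assign[s2])
                if a != MISSING and b != MISSING:
                    if {have[0], have[1]} != {a, b} and have != (a, b) \
                            and (have[1], have[0]) != (a, b):
                        ok = False
                        break
                else:
                    known = a if a != MISSING else b
                    if known not in have:
                        ok = False
                        break
            if ok:
                tot += p
        post.append(tot)
    z = sum(post)
    return [p / z for p in post]


def enum_sall(ped):
    """(svec, mu, sigma): S_all per vector plus exact null moments."""
    members = ped.topological()
    aff = [m.pid for m in members if m.affection == AFFECTED]
    n_bits = 2 * sum(1 for m in members if not m.is_founder)
    svec = []
    for v in range(1 << n_bits):
        slots = _descent_slots(ped, v)
        total = 0.0
        for pick in itertools.product((0, 1), repeat=len(aff)):
            labels = [slots[pid][k] for pid, k in zip(aff, pick)]
            prod = 1.0
            for lab in set(labels):
                prod *= math.factorial(labels.count(lab))
            total += prod
        svec.append(total / (1 << len(aff)))
    mu = sum(svec) / len(svec)
    var = sum((s - mu) ** 2 for s in svec) / len(svec)
    return svec, mu, math.sqrt(var)


def hwe_exact_oracle(naa, nab, nbb) -> float:
    """HWE exact p via explicit hypergeometric-style counting."""
    n = naa + nab + nbb
    na = 2 * naa + nab
    nb = 2 * nbb + nab
    if na == 0 or nb == 0:
        return 1.0

    def weight(h):
        a2 = (na - h) // 2
        b2 = (nb - h) // 2
        return (math.comb(n, a2) * math.comb(n - a2, h) * 2 ** h)

    hets = [h for h in range(min(na, nb) + 1)
            if (na - h) % 2 == 0 and h % 2 == min(na, nb) % 2]
    weights = {h: weight(h) for h in hets}
    tot = sum(weights.values())
    p_obs = weights[nab] / tot
    return min(1.0, sum(w for w in weights.values() if w / tot <= p_obs * (1 + 1e-12)) / tot)
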