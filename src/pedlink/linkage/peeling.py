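"""Exact pedigree likelihoods by variable elimination over joint
disease x marker genotype states.

Each individual carries an ordered pair of two-locus haplotypes
(paternal, maternal); a haplotype is ``(d << 1) | m`` with d the disease
allele (1 = risk) and m the marker allele index, giving 16 states for a
biallelic marker.  Founder priors assume linkage equilibrium; child
states follow from parental states with recombination fraction theta.
Loop-free pedigrees peel in time linear in family size.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from ..pedigree import (AFFECTED, MISSING, UNAFFECTED, DiseaseModel, Pedigree,
                        PedigreeError)

N_HAP = 4          # (disease allele, marker allele) for a biallelic marker
N_STATE = 16       # ordered haplotype pair


class Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars: tuple, table: np.ndarray):
        self.vars = tuple(vars)
        self.table = np.asarray(table, dtype=float)


def _multiply(a: Factor, b: Factor) -> Factor:
    newvars = a.vars + tuple(v for v in b.vars if v not in a.vars)
    ta = a.table.reshape(a.table.shape + (1,) * (len(newvars) - len(a.vars)))
    dest = [newvars.index(v) for v in b.vars]
    tbt = np.transpose(b.table, np.argsort(dest))
    shape = [1] * len(newvars)
    for v, n in zip(b.vars, b.table.shape):
        shape[newvars.index(v)] = n
    return Factor(newvars, ta * tbt.reshape(shape))


def _sum_out(f: Factor, var) -> Factor:
    i = f.vars.index(var)
    return Factor(f.vars[:i] + f.vars[i + 1:], f.table.sum(axis=i))


def eliminate(factors: list[Factor], keep: tuple = ()) -> Factor:
    """Sum-product variable elimination with a greedy min-size order."""
    factors = list(factors)
    all_vars = {v for f in factors for v in f.vars}
    elim = set(all_vars) - set(keep)
    domain = {}
    for f in factors:
        for v, n in zip(f.vars, f.table.shape):
            domain[v] = n
    while elim:
        # choose variable minimizing size of the merged factor
        best, best_cost = None, None
        for v in elim:
            touched = [f for f in factors if v in f.vars]
            vs = {u for f in touched for u in f.vars}
            cost = 1
            for u in vs:
                cost *= domain[u]
            if best_cost is None or cost < best_cost:
                best, best_cost = v, cost
        touched = [f for f in factors if best in f.vars]
        rest = [f for f in factors if best not in f.vars]
        prod = touched[0]
        for f in touched[1:]:
            prod = _multiply(prod, f)
        factors = rest + [_sum_out(prod, best)]
        elim.discard(best)
    prod = factors[0]
    for f in factors[1:]:
        prod = _multiply(prod, f)
    if keep:
        order = [prod.vars.index(v) for v in keep]
        prod = Factor(keep, np.transpose(prod.table, order))
    return prod


# ---------------------------------------------------------------------------
# Two-locus building blocks (cached: these dominate runtime)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=256)
def _hap_transmission(theta: float) -> np.ndarray:
    """P(transmitted haplotype | parent ordered state), shape (16, 4)."""
    t = np.zeros((N_STATE, N_HAP))
    for hp in range(N_HAP):
        for hm in range(N_HAP):
            s = hp * N_HAP + hm
            dp, mp = hp >> 1, hp & 1
            dm, mm_ = hm >> 1, hm & 1
            for (d, m), w in (((dp, mp), (1 - theta) / 2),
                              ((dm, mm_), (1 - theta) / 2),
                              ((dp, mm_), theta / 2),
                              ((dm, mp), theta / 2)):
                t[s, (d << 1) | m] += w
    return t


@lru_cache(maxsize=256)
def _child_cpt(theta: float) -> np.ndarray:
    """P(child state | father state, mother state), shape (16, 16, 16)."""
    t = _hap_transmission(theta)
    cpt = np.einsum("fp,mq->fmpq", t, t).reshape(N_STATE, N_STATE, N_HAP, N_HAP)
    return cpt.reshape(N_STATE, N_STATE, N_STATE)


@lru_cache(maxsize=4096)
def _founder_prior(q: float, pm: tuple) -> np.ndarray:
    """Founder state prior under linkage equilibrium; shape (16,)."""
    hap = np.empty(N_HAP)
    for h in range(N_HAP):
        d, m = h >> 1, h & 1
        hap[h] = (q if d else 1.0 - q) * pm[m]
    return np.outer(hap, hap).ravel()


def _dosage() -> np.ndarray:
    d = np.empty(N_STATE, dtype=int)
    for s in range(N_STATE):
        d[s] = (s // N_HAP >> 1) + (s % N_HAP >> 1)
    return d


_DOSAGE = _dosage()


def _marker_pair() -> np.ndarray:
    mp = np.empty((N_STATE, 2), dtype=int)
    for s in range(N_STATE):
        mp[s] = (s // N_HAP & 1, s % N_HAP & 1)
    return mp


_MARKER_PAIR = _marker_pair()


def state_weights(affection: int, genotype: tuple[int, int],
                  dm: DiseaseModel, use_unaffected: bool) -> np.ndarray:
    """Unary evidence factor over the 16 joint states for one individual."""
    w = np.ones(N_STATE)
    f = np.asarray(dm.penetrances)
    if affection == AFFECTED:
        w *= f[_DOSAGE]
    elif affection == UNAFFECTED and use_unaffected:
        w *= 1.0 - f[_DOSAGE]
    a, b = genotype
    if a != MISSING and b != MISSING:
        if max(a, b) > 1:
            raise PedigreeError("two-point engine requires biallelic markers")
        ok = ((_MARKER_PAIR[:, 0] == a) & (_MARKER_PAIR[:, 1] == b)) | \
             ((_MARKER_PAIR[:, 0] == b) & (_MARKER_PAIR[:, 1] == a))
        w = w * ok
    elif (a == MISSING) != (b == MISSING):
        known = a if a != MISSING else b
        w = w * ((_MARKER_PAIR[:, 0] == known) | (_MARKER_PAIR[:, 1] == known))
    return w


def pedigree_likelihood(ped: Pedigree, marker_index: int, freqs: np.ndarray,
                        dm: DiseaseModel, theta: float,
                        use_unaffected: bool = False,
                        max_members: int = 30) -> float:
    """Exact joint likelihood of phenotypes and genotypes at one marker under
    two-locus transmission with recombination ``theta``.

    Affecteds-only contract by default: unaffected/uncertain individuals
    contribute a phenotype factor of 1 (their genotypes always contribute).
    ``use_unaffected=True`` switches to the full penetrance likelihood.
    """
    if len(ped.members) > max_members:
        raise PedigreeError(
            f"family {ped.fid}: {len(ped.members)} members exceeds peeling cap "
            f"{max_members} (bits={ped.bits})")
    theta = float(theta)
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    if freqs is None:
        raise PedigreeError("allele frequencies required (run estimate_allele_freqs)")
    pm = (float(freqs[0]), float(1.0 - freqs[0]))
    prior = _founder_prior(dm.allele_freq, pm)
    cpt = _child_cpt(theta)
    factors: list[Factor] = []
    for ind in ped.members.values():
        if ind.is_founder:
            factors.append(Factor((ind.pid,), prior))
        else:
            factors.append(Factor((ind.father, ind.mother, ind.pid), cpt))
        w = state_weights(ind.affection, ped.genotype(ind.pid, marker_index),
                          dm, use_unaffected)
        factors.append(Factor((ind.pid,), w))
    return float(eliminate(factors).table)


def disease_only_likelihood(ped: Pedigree, dm: DiseaseModel,
                            use_unaffected: bool = False) -> float:
    """Likelihood of the phenotype data alone (no marker)."""
    q = dm.allele_freq
    prior3 = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    cpt = _disease_cpt()
    f = np.asarray(dm.penetrances)
    factors: list[Factor] = []
    for ind in ped.members.values():
        if ind.is_founder:
            factors.append(Factor((ind.pid,), prior3))
        else:
            factors.append(Factor((ind.father, ind.mother, ind.pid), cpt))
        if ind.affection == AFFECTED:
            factors.append(Factor((ind.pid,), f))
        elif ind.affection == UNAFFECTED and use_unaffected:
            factors.append(Factor((ind.pid,), 1.0 - f))
    return float(eliminate(factors).table)


def disease_posterior(ped: Pedigree, dm: DiseaseModel, pid: str,
                      use_unaffected: bool = False) -> np.ndarray:
    """Exact posterior P(disease genotype | phenotypes) for one member,
    dosage-coded (0/1/2 risk alleles)."""
    q = dm.allele_freq
    prior3 = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    cpt = _disease_cpt()
    f = np.asarray(dm.penetrances)
    factors: list[Factor] = []
    for ind in ped.members.values():
        if ind.is_founder:
            factors.append(Factor((ind.pid,), prior3))
        else:
            factors.append(Factor((ind.father, ind.mother, ind.pid), cpt))
        if ind.affection == AFFECTED:
            factors.append(Factor((ind.pid,), f))
        elif ind.affection == UNAFFECTED and use_unaffected:
            factors.append(Factor((ind.pid,), 1.0 - f))
    post = eliminate(factors, keep=(pid,)).table
    tot = post.sum()
    if tot <= 0:
        raise PedigreeError(
            f"family {ped.fid}: phenotype configuration has zero likelihood")
    return post / tot


@lru_cache(maxsize=1)
def _disease_cpt() -> np.ndarray:
    """P(child disease genotype | parents), unordered dosage coding 0/1/2."""
    trans = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])  # P(transmit risk | dosage)
    cpt = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            for af in range(2):
                for am in range(2):
                    w = (trans[gf, af]) * (trans[gm, am])
                    cpt[gf, gm, af + am] += w
    return cpt
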