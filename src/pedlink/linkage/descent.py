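"""Inheritance-vector (Lander-Green) machinery for multipoint analysis.

An inheritance vector assigns one bit per meiosis (2 per nonfounder):
0 = grandpaternal, 1 = grandmaternal.  Emissions are computed by summing
over founder-allele assignments; the marker-to-marker chain mixes each bit
independently with the inter-marker recombination fraction.

No founder-couple symmetry reduction is applied; the bit cap bounds the
2^bits state space directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from ..pedigree import MISSING, Cohort, Pedigree, PedigreeError, cm_to_theta

log = logging.getLogger(__name__)

DEFAULT_BIT_CAP = 16
_CHUNK = 4096  # vectors per emission chunk (bounds memory)


class BitCapExceeded(PedigreeError):
    pass


class DescentGraph:
    """Per-family descent bookkeeping: founder allele slots and, for every
    inheritance vector, the pair of founder slots carried by each member."""

    def __init__(self, ped: Pedigree, bit_cap: int = DEFAULT_BIT_CAP):
        self.ped = ped
        members = ped.topological()
        self.members = members
        self.member_index = {m.pid: i for i, m in enumerate(members)}
        self.founder_ids = [m.pid for m in members if m.is_founder]
        self.nonfounders = [m for m in members if not m.is_founder]
        self.n_meioses = 2 * len(self.nonfounders)
        if self.n_meioses > bit_cap:
            raise BitCapExceeded(
                f"family {ped.fid}: {self.n_meioses} meioses exceeds bit cap {bit_cap}")
        self.n_slots = 2 * len(self.founder_ids)
        self.nvec = 1 << self.n_meioses

    @cached_property
    def slots(self) -> np.ndarray:
        """(nvec, n_members, 2) founder-slot index for each member's
        (paternal, maternal) allele under every inheritance vector."""
        nvec, n = self.nvec, len(self.members)
        slots = np.empty((nvec, n, 2), dtype=np.int16)
        fslot = {pid: 2 * i for i, pid in enumerate(self.founder_ids)}
        vecs = np.arange(nvec, dtype=np.int64)
        for i, m in enumerate(self.members):
            if m.is_founder:
                slots[:, i, 0] = fslot[m.pid]
                slots[:, i, 1] = fslot[m.pid] + 1
        for k, m in enumerate(self.nonfounders):
            i = self.member_index[m.pid]
            for side, parent in ((0, m.father), (1, m.mother)):
                bit = (vecs >> (2 * k + side)) & 1
                pi = self.member_index[parent]
                slots[:, i, side] = np.where(bit == 0,
                                             slots[:, pi, 0], slots[:, pi, 1])
        return slots

    def member_weight_emission(self, weights: dict[int, np.ndarray],
                               slot_prior: np.ndarray) -> np.ndarray:
        """Generic descent marginal: sum over founder-allele assignments of
        prior(assignment) * prod_i W_i[allele_pat, allele_mat].

        ``weights`` maps member index -> (K, K) weight matrix; ``slot_prior``
        is the (K,) per-slot allele prior.  Returns an (nvec,) array.
        """
        K = len(slot_prior)
        n_assign = K ** self.n_slots
        if n_assign > 1 << 16:
            raise PedigreeError(
                f"family {self.ped.fid}: {n_assign} founder-allele assignments "
                "too many for emission enumeration")
        assign = np.indices((K,) * self.n_slots).reshape(self.n_slots, -1).T
        prior = np.prod(slot_prior[assign], axis=1)           # (n_assign,)
        out = np.empty(self.nvec)
        slots = self.slots
        for lo in range(0, self.nvec, _CHUNK):
            hi = min(lo + _CHUNK, self.nvec)
            acc = np.ones((n_assign, hi - lo))
            for i, w in weights.items():
                a1 = assign[:, slots[lo:hi, i, 0]]            # (n_assign, chunk)
                a2 = assign[:, slots[lo:hi, i, 1]]
                acc *= w[a1, a2]
            out[lo:hi] = prior @ acc
        return out

    def marker_emission(self, marker_index: int, freqs: np.ndarray) -> np.ndarray:
        """P(observed genotypes at one marker | inheritance vector)."""
        if freqs is None:
            raise PedigreeError("allele frequencies required for emission")
        K = len(freqs)
        weights: dict[int, np.ndarray] = {}
        for i, m in enumerate(self.members):
            a, b = self.ped.genotype(m.pid, marker_index)
            if a == MISSING and b == MISSING:
                continue
            w = np.zeros((K, K))
            if a != MISSING and b != MISSING:
                w[a, b] = 1.0
                w[b, a] = 1.0
            else:
                known = a if a != MISSING else b
                w[known, :] = 1.0
                w[:, known] = 1.0
            weights[i] = w
        if not weights:
            return np.ones(self.nvec)
        return self.member_weight_emission(weights, np.asarray(freqs, float))

    def cluster_emission(self, compat: dict[int, np.ndarray],
                         hap_freqs: np.ndarray) -> np.ndarray:
        """Emission for an LD-cluster super-marker: ``compat`` maps member
        index -> (H, H) 0/1 matrix of haplotype pairs consistent with the
        member's observed genotypes."""
        if not compat:
            return np.ones(self.nvec)
        return self.member_weight_emission(compat, np.asarray(hap_freqs, float))

    def parametric_weights(self, dm, use_unaffected: bool = False) -> np.ndarray:
        """P(phenotypes | inheritance vector): disease alleles dropped through
        the vector under the disease model (affecteds-only by default)."""
        from ..pedigree import AFFECTED, UNAFFECTED
        f = np.asarray(dm.penetrances)
        weights: dict[int, np.ndarray] = {}
        for i, m in enumerate(self.members):
            if m.affection == AFFECTED:
                pen = f
            elif m.affection == UNAFFECTED and use_unaffected:
                pen = 1.0 - f
            else:
                continue
            w = np.empty((2, 2))
            for a in (0, 1):
                for b in (0, 1):
                    w[a, b] = pen[a + b]
            weights[i] = w
        if not weights:
            return np.ones(self.nvec)
        q = dm.allele_freq
        return self.member_weight_emission(weights, np.array([1.0 - q, q]))


def mix_bits(p: np.ndarray, theta: float, n_bits: int) -> np.ndarray:
    """One chain step: each meiosis bit flips independently with prob theta."""
    if theta <= 0:
        return p
    q = p.reshape((2,) * n_bits)
    for b in range(n_bits):
        q = (1.0 - theta) * q + theta * np.flip(q, axis=b)
    return q.reshape(-1)


@dataclass
class InheritanceDistribution:
    """Posterior over inheritance vectors at each requested position."""
    pos_cm: np.ndarray                 # (P,)
    posteriors: np.ndarray             # (P, nvec), rows sum to 1
    log_likelihood: float              # log of the marker-data likelihood
    n_bits: int


def position_grid(marker_cm: np.ndarray, step_cm: float | None) -> np.ndarray:
    """Analysis grid: every marker position plus a uniform step."""
    marker_cm = np.asarray(marker_cm, float)
    pos = set(np.round(marker_cm, 10))
    if step_cm:
        lo, hi = marker_cm.min(), marker_cm.max()
        pos.update(np.round(np.arange(lo, hi + 1e-9, step_cm), 10))
    return np.array(sorted(pos))


def lander_green(graph: DescentGraph, marker_cm: np.ndarray,
                 emissions: list[np.ndarray],
                 positions: np.ndarray | None = None,
                 map_function: str = "haldane") -> InheritanceDistribution:
    """Forward-backward over inheritance vectors along one chromosome.

    ``emissions[k]`` is the (nvec,) emission for marker k (markers ordered by
    ``marker_cm``).  ``positions`` defaults to the marker positions.
    A marker whose emission is identically zero (Mendelian inconsistency not
    caught upstream) is treated as missing, with a warning.
    """
    nvec, nb = graph.nvec, graph.n_meioses
    marker_cm = np.asarray(marker_cm, float)
    M = len(marker_cm)
    if positions is None:
        positions = marker_cm.copy()
    emissions = list(emissions)
    for k, e in enumerate(emissions):
        if not np.any(e > 0):
            log.warning("family %s: all-zero emission at marker %d; treated missing",
                        graph.ped.fid, k)
            emissions[k] = np.ones(nvec)
    thetas = cm_to_theta(np.diff(marker_cm), map_function) if M > 1 else np.array([])

    loglik = 0.0
    alphas = np.empty((M, nvec))
    a = emissions[0] / nvec
    s = a.sum()
    loglik += np.log(s)
    alphas[0] = a / s
    for k in range(1, M):
        a = mix_bits(alphas[k - 1], float(thetas[k - 1]), nb) * emissions[k]
        s = a.sum()
        loglik += np.log(s)
        alphas[k] = a / s

    betas = np.empty((M, nvec))
    betas[M - 1] = np.ones(nvec)
    for k in range(M - 2, -1, -1):
        b = mix_bits(betas[k + 1] * emissions[k + 1], float(thetas[k]), nb)
        betas[k] = b / b.sum()

    post = np.empty((len(positions), nvec))
    for j, x in enumerate(positions):
        k = int(np.searchsorted(marker_cm, x, side="right")) - 1
        if k < 0:
            right = mix_bits(emissions[0] * betas[0],
                             cm_to_theta(marker_cm[0] - x, map_function), nb)
            p = right / nvec
        elif np.isclose(x, marker_cm[k]):
            p = alphas[k] * betas[k]
        elif k >= M - 1:
            p = mix_bits(alphas[M - 1],
                         cm_to_theta(x - marker_cm[M - 1], map_function), nb)
        else:
            left = mix_bits(alphas[k], cm_to_theta(x - marker_cm[k], map_function), nb)
            right = mix_bits(emissions[k + 1] * betas[k + 1],
                             cm_to_theta(marker_cm[k + 1] - x, map_function), nb)
            p = left * right
        t = p.sum()
        post[j] = p / t if t > 0 else np.full(nvec, 1.0 / nvec)
    return InheritanceDistribution(np.asarray(positions, float), post,
                                   float(loglik), nb)
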