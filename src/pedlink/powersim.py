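"""Monte-Carlo power estimation for a two-point linkage design.

Per replicate: disease-locus genotypes are drawn exactly from
P(genotypes | phenotypes) under the disease model (no rejection), a marker
of given MAF is gene-dropped at recombination fraction theta from the
disease locus, and the cohort's maximum two-point LOD over the theta grid
(and at theta = 0.01) is recorded.  Power is the fraction of replicates
exceeding the LOD threshold, with an exact binomial CI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .linkage.twopoint import ThetaGrid, family_lod_curve
from .pedigree import (AFFECTED, AFFECTEDS_ONLY_MODEL, MISSING, UNAFFECTED,
                       Cohort, DiseaseModel, Pedigree, PedigreeError)

log = logging.getLogger(__name__)

_MAX_ENUM_MEMBERS = 11


class ConditionalSampler:
    """Exact sampler of ordered disease-locus genotypes given phenotypes.

    The joint distribution over ordered (paternal, maternal) allele states
    is enumerated once (4^n states, so families are capped at 11 members)
    and replicates are drawn from the cached categorical.
    """

    def __init__(self, ped: Pedigree, dm: DiseaseModel,
                 use_unaffected: bool = True):
        n = len(ped.members)
        if n > _MAX_ENUM_MEMBERS:
            raise PedigreeError(
                f"family {ped.fid}: {n} members exceeds conditional-sampler "
                f"cap {_MAX_ENUM_MEMBERS}")
        self.ped = ped
        members = ped.topological()
        self.order = [m.pid for m in members]
        idx = {pid: i for i, pid in enumerate(self.order)}
        states = np.indices((4,) * n).reshape(n, -1)     # (n, 4^n)
        a_pat = states >> 1                              # risk-allele indicators
        a_mat = states & 1
        q = dm.allele_freq
        pa = np.array([1.0 - q, q])
        f = np.asarray(dm.penetrances)
        prob = np.ones(states.shape[1])
        for m in members:
            i = idx[m.pid]
            if m.is_founder:
                prob *= pa[a_pat[i]] * pa[a_mat[i]]
            else:
                fi, mi = idx[m.father], idx[m.mother]
                # boolean arrays must be summed as integers (True+True == 2)
                prob *= 0.5 * ((a_pat[i] == a_pat[fi]).astype(float)
                               + (a_pat[i] == a_mat[fi]))
                prob *= 0.5 * ((a_mat[i] == a_pat[mi]).astype(float)
                               + (a_mat[i] == a_mat[mi]))
            dos = a_pat[i] + a_mat[i]
            if m.affection == AFFECTED:
                prob *= f[dos]
            elif m.affection == UNAFFECTED and use_unaffected:
                prob *= 1.0 - f[dos]
        tot = prob.sum()
        if tot <= 0:
            raise PedigreeError(
                f"family {ped.fid}: phenotype configuration has zero "
                "likelihood under the disease model")
        self._probs = prob / tot
        self._a_pat = a_pat.astype(np.int8)
        self._a_mat = a_mat.astype(np.int8)

    def sample(self, rng: np.random.Generator, size: int = 1) -> list[dict]:
        """Draw ordered genotype dicts pid -> (paternal, maternal) allele."""
        ks = rng.choice(len(self._probs), size=size, p=self._probs)
        out = []
        for k in ks:
            out.append({pid: (int(self._a_pat[i, k]), int(self._a_mat[i, k]))
                        for i, pid in enumerate(self.order)})
        return out

    def marginal(self, pid: str) -> np.ndarray:
        """Exact dosage-coded marginal P(genotype | phenotypes)."""
        i = self.order.index(pid)
        dos = self._a_pat[i] + self._a_mat[i]
        return np.array([self._probs[dos == d].sum() for d in range(3)])


def drop_linked_marker(ped: Pedigree, ordered: dict, theta: float,
                       marker_maf: float, rng: np.random.Generator) -> dict:
    """Gene-drop one marker at recombination ``theta`` from the disease locus,
    conditional on the ordered disease genotypes.  Allele 1 has frequency
    ``marker_maf``.  Returns pid -> (m_pat, m_mat)."""
    marker: dict[str, tuple[int, int]] = {}
    for m in ped.topological():
        if m.is_founder:
            marker[m.pid] = (int(rng.random() < marker_maf),
                             int(rng.random() < marker_maf))
            continue
        pair = []
        for side, parent in ((0, m.father), (1, m.mother)):
            pd_ = ordered[parent]
            child_allele = ordered[m.pid][side]
            if pd_[0] != pd_[1]:
                slot = 0 if child_allele == pd_[0] else 1
            else:
                slot = int(rng.integers(2))
            if rng.random() < theta:
                slot ^= 1
            pair.append(marker[parent][slot])
        marker[m.pid] = (pair[0], pair[1])
    return marker


@dataclass
class PowerConfig:
    dm: DiseaseModel = field(default_factory=lambda: AFFECTEDS_ONLY_MODEL)
    marker_maf: float = 0.30
    theta: float = 0.01
    replicates: int = 1000
    lod_threshold: float = 3.0
    seed: int = 0
    theta_grid: ThetaGrid = field(default_factory=ThetaGrid)

    def __post_init__(self):
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError("theta must be in [0, 0.5]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class PowerResult:
    power: float
    ci95: tuple[float, float]
    power_theta001: float
    max_lods: np.ndarray          # per-replicate max over the theta grid
    lods_theta001: np.ndarray     # per-replicate LOD at theta = 0.01

    def summary(self) -> str:
        return (f"P(max LOD > threshold) = {self.power:.3f} "
                f"[{self.ci95[0]:.3f}, {self.ci95[1]:.3f}]; "
                f"at theta=0.01: {self.power_theta001:.3f}")


def _clopper_pearson(k: int, n: int, alpha: float = 0.05):
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def estimate_power(cohort: Cohort, config: PowerConfig) -> PowerResult:
    """Monte-Carlo power for the cohort's structures and phenotypes."""
    rng = np.random.default_rng(config.seed)
    grid = config.theta_grid
    i001 = grid.thetas.index(0.01) if 0.01 in grid.thetas else None
    samplers = {ped.fid: ConditionalSampler(ped, config.dm) for ped in cohort}
    freqs = np.array([1.0 - config.marker_maf, config.marker_maf])
    lod_cache: dict[tuple[str, bytes], np.ndarray] = {}
    max_lods = np.empty(config.replicates)
    lods001 = np.empty(config.replicates)
    for r in range(config.replicates):
        total = np.zeros(len(grid))
        for ped in cohort:
            ordered = samplers[ped.fid].sample(rng)[0]
            marker = drop_linked_marker(ped, ordered, config.theta,
                                        config.marker_maf, rng)
            geno = {}
            for pid, m in ped.members.items():
                if m.sampled:
                    a, b = marker[pid]
                    geno[pid] = np.array([[a, b]], dtype=np.int16)
                else:
                    geno[pid] = np.full((1, 2), MISSING, dtype=np.int16)
            key = (ped.fid, b"".join(geno[p].tobytes() for p in ped.members))
            curve = lod_cache.get(key)
            if curve is None:
                trial = Pedigree(ped.fid, list(ped.members.values()), geno)
                curve = family_lod_curve(trial, 0, freqs, config.dm, grid)
                lod_cache[key] = curve
            total += curve
        max_lods[r] = total.max()
        lods001[r] = total[i001] if i001 is not None else np.nan
    k = int(np.sum(max_lods > config.lod_threshold))
    k001 = int(np.sum(lods001 > config.lod_threshold))
    n = config.replicates
    return PowerResult(k / n, _clopper_pearson(k, n), k001 / n,
                       max_lods, lods001)
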