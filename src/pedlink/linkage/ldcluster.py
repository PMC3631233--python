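"""Inter-marker LD clustering: adjacent markers with composite r^2 above a
threshold are grouped and modeled as super-markers with EM-estimated
haplotype frequencies (no recombination assumed within a cluster)."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from ..pedigree import MISSING, Cohort

log = logging.getLogger(__name__)

DEFAULT_R2 = 0.16


@dataclass
class LDCluster:
    marker_indices: list[int]            # contiguous map indices
    haplotypes: list[tuple[int, ...]]
    freqs: np.ndarray

    @property
    def size(self) -> int:
        return len(self.marker_indices)


def founder_dosages(cohort: Cohort, idx: np.ndarray) -> np.ndarray:
    """(n_founders, M) dosage of allele 1, NaN where missing."""
    rows = []
    for ped in cohort:
        for ind in ped.founders():
            g = ped.genotypes.get(ind.pid)
            if g is None:
                continue
            sub = g[idx].astype(float)
            d = sub.sum(axis=1)
            d[np.any(sub < 0, axis=1)] = np.nan
            rows.append(d)
    return np.array(rows) if rows else np.zeros((0, len(idx)))


def composite_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of genotype dosages (composite LD)."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return 0.0
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1] ** 2)


def cluster_markers(cohort: Cohort, chrom_idx: np.ndarray,
                    r2_threshold: float = DEFAULT_R2,
                    max_cluster: int = 5) -> list[list[int]]:
    """Greedy walk joining each marker to the current cluster while its
    composite r^2 with the previous marker meets the threshold."""
    dose = founder_dosages(cohort, chrom_idx)
    clusters: list[list[int]] = []
    cur = [int(chrom_idx[0])]
    for j in range(1, len(chrom_idx)):
        r2 = composite_r2(dose[:, j - 1], dose[:, j]) if dose.size else 0.0
        if r2 >= r2_threshold and len(cur) < max_cluster:
            cur.append(int(chrom_idx[j]))
        else:
            clusters.append(cur)
            cur = [int(chrom_idx[j])]
    clusters.append(cur)
    return clusters


def _compatible(hap1, hap2, geno) -> bool:
    for j, (a, b) in enumerate(geno):
        if a == MISSING and b == MISSING:
            continue
        if a != MISSING and b != MISSING:
            if {hap1[j], hap2[j]} != {a, b} and (hap1[j], hap2[j]) != (a, b) \
                    and (hap2[j], hap1[j]) != (a, b):
                return False
        else:
            known = a if a != MISSING else b
            if known not in (hap1[j], hap2[j]):
                return False
    return True


def em_haplotype_freqs(genos: list[np.ndarray], n_alleles: list[int],
                       max_iter: int = 500, tol: float = 1e-10):
    """EM haplotype-frequency estimation from unphased multilocus genotypes.

    ``genos``: one (k, 2) allele-index array per individual.  Returns
    ``(haplotypes, freqs)`` or None on non-convergence.
    """
    haps = list(itertools.product(*[range(max(n, 1)) for n in n_alleles]))
    H = len(haps)
    pairs_per_ind = []
    for g in genos:
        gl = [tuple(row) for row in g]
        pairs = [(i, j) for i in range(H) for j in range(H)
                 if _compatible(haps[i], haps[j], gl)]
        if pairs:
            pairs_per_ind.append(np.array(pairs))
    if not pairs_per_ind:
        return None
    p = np.full(H, 1.0 / H)
    for _ in range(max_iter):
        counts = np.zeros(H)
        for pairs in pairs_per_ind:
            w = p[pairs[:, 0]] * p[pairs[:, 1]]
            tot = w.sum()
            if tot <= 0:
                continue
            w /= tot
            np.add.at(counts, pairs[:, 0], w)
            np.add.at(counts, pairs[:, 1], w)
        new = counts / counts.sum()
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    else:
        return None
    keep = p > 1e-9
    return [haps[i] for i in np.flatnonzero(keep)], p[keep] / p[keep].sum()


def build_clusters(cohort: Cohort, chrom_idx: np.ndarray,
                   r2_threshold: float = DEFAULT_R2) -> list[LDCluster]:
    """Cluster a chromosome's markers and fit within-cluster haplotype
    frequencies from founder genotypes.  Falls back to singleton clusters
    (independent markers) when EM fails."""
    mm = cohort.map
    groups = cluster_markers(cohort, chrom_idx, r2_threshold)
    out: list[LDCluster] = []
    for grp in groups:
        if len(grp) == 1:
            i = grp[0]
            f = mm.freqs[i]
            if f is None:
                f = np.array([0.5, 0.5])
            out.append(LDCluster(grp, [(0,), (1,)], np.asarray(f, float)))
            continue
        genos = []
        for ped in cohort:
            for ind in ped.founders():
                g = ped.genotypes.get(ind.pid)
                if g is not None:
                    genos.append(g[grp])
        fit = em_haplotype_freqs(genos, [len(mm.alleles[i]) for i in grp])
        if fit is None:
            log.warning("EM non-convergence for cluster %s; markers kept independent",
                        [mm.marker[i] for i in grp])
            for i in grp:
                f = mm.freqs[i] if mm.freqs[i] is not None else np.array([0.5, 0.5])
                out.append(LDCluster([i], [(0,), (1,)], np.asarray(f, float)))
            continue
        haps, freqs = fit
        out.append(LDCluster(grp, haps, freqs))
    return out


def cluster_compat(cluster: LDCluster, geno: np.ndarray) -> np.ndarray | None:
    """(H, H) 0/1 matrix of haplotype pairs consistent with an individual's
    observed genotypes at the cluster's markers; None if fully missing."""
    gl = [tuple(row) for row in geno]
    if all(a == MISSING and b == MISSING for a, b in gl):
        return None
    H = len(cluster.haplotypes)
    w = np.zeros((H, H))
    for i in range(H):
        for j in range(H):
            if _compatible(cluster.haplotypes[i], cluster.haplotypes[j], gl):
                w[i, j] = 1.0
    return w
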