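"""Chromosome scans: two-point and multipoint, parametric and nonparametric.

The heavy per-family quantities (two-point LOD curves, multipoint LOD
curves, NPL score distributions) are computed once into
:class:`ChromosomeTables`; cohort-level statistics for any family subset are
then cheap sums/maximizations over those tables.  The stratified analysis
and the conditional permutation test both reuse this path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..pedigree import AFFECTEDS_ONLY_MODEL, Cohort, DiseaseModel
from .descent import (BitCapExceeded, DescentGraph, InheritanceDistribution,
                      lander_green, position_grid)
from .ldcluster import build_clusters, cluster_compat
from .npl import NplFamilyScores, combined_npl_z, kong_cox, npl_family_scores
from .twopoint import LinkageResult, ThetaGrid, family_lod_curve

log = logging.getLogger(__name__)


@dataclass
class EngineConfig:
    dm: DiseaseModel = field(default_factory=lambda: AFFECTEDS_ONLY_MODEL)
    theta_grid: ThetaGrid = field(default_factory=ThetaGrid)
    alpha_step: float = 0.01
    bit_cap: int = 16
    step_cm: float | None = 0.3
    use_unaffected: bool = False
    use_ld_clusters: bool = False
    r2_threshold: float = 0.16
    map_function: str = "haldane"


@dataclass
class FamilyChromTables:
    fid: str
    tp_lod: np.ndarray | None            # (M, T) two-point parametric curves
    tp_scores: NplFamilyScores | None    # NPL at marker positions
    mp_lod: np.ndarray | None            # (P,) multipoint parametric LOD
    mp_scores: NplFamilyScores | None


@dataclass
class ChromosomeTables:
    chromosome: str
    marker_indices: np.ndarray
    marker_cm: np.ndarray
    marker_bp: np.ndarray
    positions: np.ndarray                # multipoint grid (cM)
    families: dict[str, FamilyChromTables]
    config: EngineConfig

    def fids(self) -> list[str]:
        return list(self.families)


def _multipoint_family(ped, cohort: Cohort, idx: np.ndarray, positions,
                       config: EngineConfig):
    """(mp_lod, mp_scores, inh) for one family, or (None, None, None) when the
    family exceeds the bit cap."""
    try:
        graph = DescentGraph(ped, config.bit_cap)
    except BitCapExceeded as e:
        log.warning("multipoint: %s; family skipped for this chromosome", e)
        return None, None
    mm = cohort.map
    if config.use_ld_clusters:
        clusters = build_clusters(cohort, idx, config.r2_threshold)
        cm, emissions = [], []
        for cl in clusters:
            cm.append(float(np.mean([mm.cm[i] for i in cl.marker_indices])))
            compat = {}
            for i, m in enumerate(graph.members):
                g = ped.genotypes.get(m.pid)
                if g is None:
                    continue
                w = cluster_compat(cl, g[cl.marker_indices])
                if w is not None:
                    compat[i] = w
            emissions.append(graph.cluster_emission(compat, cl.freqs))
        cm = np.asarray(cm)
        order = np.argsort(cm)
        cm = cm[order]
        emissions = [emissions[i] for i in order]
    else:
        cm = mm.cm[idx]
        emissions = [graph.marker_emission(int(i), mm.freqs[int(i)]) for i in idx]
    inh = lander_green(graph, cm, emissions, positions, config.map_function)
    w = graph.parametric_weights(config.dm, config.use_unaffected)
    num = inh.posteriors @ w
    den = float(w.mean())
    with np.errstate(divide="ignore"):
        mp_lod = np.log10(num / den)
    scores = npl_family_scores(graph, inh)
    return mp_lod, scores


def _twopoint_scores(ped, cohort: Cohort, idx: np.ndarray,
                     config: EngineConfig) -> NplFamilyScores | None:
    """Single-marker NPL scores stacked over markers (position grid = markers)."""
    try:
        graph = DescentGraph(ped, config.bit_cap)
    except BitCapExceeded:
        return None
    mm = cohort.map
    posts = []
    for i in idx:
        e = graph.marker_emission(int(i), mm.freqs[int(i)])
        tot = e.sum()
        posts.append(e / tot if tot > 0 else np.full(graph.nvec, 1.0 / graph.nvec))
    inh = InheritanceDistribution(mm.cm[idx], np.vstack(posts), 0.0,
                                  graph.n_meioses)
    return npl_family_scores(graph, inh)


def chromosome_tables(cohort: Cohort, chromosome: str,
                      config: EngineConfig | None = None,
                      twopoint: bool = True,
                      multipoint: bool = True) -> ChromosomeTables:
    config = config or EngineConfig()
    mm = cohort.map
    idx = mm.chrom_indices(chromosome)
    if len(idx) == 0:
        raise ValueError(f"no markers on chromosome {chromosome!r}")
    positions = position_grid(mm.cm[idx], config.step_cm)
    fams: dict[str, FamilyChromTables] = {}
    for ped in cohort:
        tp_lod = tp_scores = mp_lod = mp_scores = None
        if twopoint:
            tp_lod = np.vstack([
                family_lod_curve(ped, int(i), mm.freqs[int(i)], config.dm,
                                 config.theta_grid, config.use_unaffected)
                for i in idx])
            tp_scores = _twopoint_scores(ped, cohort, idx, config)
        if multipoint:
            mp_lod, mp_scores = _multipoint_family(ped, cohort, idx, positions,
                                                   config)
        fams[ped.fid] = FamilyChromTables(ped.fid, tp_lod, tp_scores,
                                          mp_lod, mp_scores)
    return ChromosomeTables(chromosome, idx, mm.cm[idx], mm.bp[idx],
                            positions, fams, config)


def _hlod_from_mat(lod_mat: np.ndarray, alpha_step: float):
    """HLOD over (alpha, last axis) from per-family LOD curves (F, ...)."""
    alphas = np.arange(0.0, 1.0 + 1e-9, alpha_step)
    ratios = np.power(10.0, lod_mat)                  # (F, ...)
    mix = alphas.reshape((-1,) + (1,) * lod_mat.ndim) * ratios[None] \
        + (1.0 - alphas).reshape((-1,) + (1,) * lod_mat.ndim)
    ll = np.log10(mix).sum(axis=1)                    # (A, ...)
    h = ll.max(axis=0)
    a_idx = ll.argmax(axis=0)
    return np.maximum(h, 0.0), np.where(h > 0, alphas[a_idx], 0.0)


def scan_from_tables(tables: ChromosomeTables,
                     fids: list[str] | None = None):
    """Two-point and multipoint :class:`LinkageResult` for a family subset."""
    fids = list(tables.families) if fids is None else list(fids)
    cfg = tables.config
    tp = LinkageResult()
    mp = LinkageResult()

    tp_mats = [tables.families[f].tp_lod for f in fids
               if tables.families[f].tp_lod is not None]
    if tp_mats:
        mat = np.stack(tp_mats)                       # (F, M, T)
        total = mat.sum(axis=0)                       # (M, T)
        hl, al = _hlod_from_mat(mat, cfg.alpha_step)  # (M, T) each
        tp_scores = [tables.families[f].tp_scores for f in fids
                     if tables.families[f].tp_scores is not None]
        zc = combined_npl_z([s for s in tp_scores if s])
        inf = [s for s in tp_scores if s and s.informative]
        if inf:
            kl, kld = kong_cox(inf, "linear")
            ke, ked = kong_cox(inf, "exponential")
        else:
            M = len(tables.marker_cm)
            kl = kld = ke = ked = np.zeros(M)
            zc = np.zeros(M)
        for m in range(len(tables.marker_cm)):
            t_best = int(np.argmax(hl[m]))
            tp.chrom.append(tables.chromosome)
            tp.pos_cm.append(float(tables.marker_cm[m]))
            tp.bp.append(float(tables.marker_bp[m]))
            tp.lod.append(float(total[m].max()))
            tp.hlod.append(float(hl[m, t_best]))
            tp.alpha.append(float(al[m, t_best]))
            tp.npl_z.append(float(zc[m]) if len(zc) else 0.0)
            tp.kc_lin.append(float(kl[m]))
            tp.kc_lin_delta.append(float(kld[m]))
            tp.kc_exp.append(float(ke[m]))
            tp.kc_exp_delta.append(float(ked[m]))

    mp_mats = [tables.families[f].mp_lod for f in fids
               if tables.families[f].mp_lod is not None]
    if mp_mats:
        mat = np.stack(mp_mats)                       # (F, P)
        total = mat.sum(axis=0)
        hl, al = _hlod_from_mat(mat, cfg.alpha_step)
        mp_scores = [tables.families[f].mp_scores for f in fids
                     if tables.families[f].mp_scores is not None]
        zc = combined_npl_z([s for s in mp_scores if s])
        inf = [s for s in mp_scores if s and s.informative]
        if inf:
            kl, kld = kong_cox(inf, "linear")
            ke, ked = kong_cox(inf, "exponential")
        else:
            P = len(tables.positions)
            kl = kld = ke = ked = np.zeros(P)
            zc = np.zeros(P)
        bp_interp = np.interp(tables.positions, tables.marker_cm,
                              tables.marker_bp.astype(float))
        for p in range(len(tables.positions)):
            mp.chrom.append(tables.chromosome)
            mp.pos_cm.append(float(tables.positions[p]))
            mp.bp.append(float(bp_interp[p]))
            mp.lod.append(float(total[p]))
            mp.hlod.append(float(hl[p]))
            mp.alpha.append(float(al[p]))
            mp.npl_z.append(float(zc[p]) if len(zc) else 0.0)
            mp.kc_lin.append(float(kl[p]))
            mp.kc_lin_delta.append(float(kld[p]))
            mp.kc_exp.append(float(ke[p]))
            mp.kc_exp_delta.append(float(ked[p]))
    return tp, mp


def genome_tables(cohort: Cohort, config: EngineConfig | None = None,
                  twopoint: bool = True, multipoint: bool = True
                  ) -> dict[str, ChromosomeTables]:
    return {c: chromosome_tables(cohort, c, config, twopoint, multipoint)
            for c in cohort.map.chromosomes()}


def genome_scan(cohort: Cohort, config: EngineConfig | None = None):
    """Full scan; returns ``(tp_result, mp_result, tables)`` with results
    concatenated over chromosomes."""
    import pandas as pd
    tables = genome_tables(cohort, config)
    tps, mps = [], []
    for t in tables.values():
        tp, mp = scan_from_tables(t)
        tps.append(tp.to_frame())
        mps.append(mp.to_frame())
    return (pd.concat(tps, ignore_index=True),
            pd.concat(mps, ignore_index=True), tables)
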