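"""Clinical stratification and the conditional permutation test.

The permutation null: repeatedly split the cohort into two random halves,
rerun all six analyses (parametric HLOD / Kong-Cox linear / Kong-Cox
exponential, each two-point and multipoint) in each half, and retain the
per-chromosome and genome-wide maximum LOD of each half (2 draws per
repetition).  Empirical p-values use the add-one correction
(count+1)/(N+1); the raw proportion is also reported.

All per-family statistics are precomputed once (see
:mod:`pedlink.linkage.scan`), so each repetition reduces to subset sums.
For speed the permutation evaluators use a fixed delta grid for Kong-Cox
and a coarser alpha grid for the HLOD than the reporting-path optimizers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage.npl import kong_cox_logmgf_tables
from .linkage.scan import ChromosomeTables, EngineConfig, genome_tables
from .pedigree import Cohort, estimate_allele_freqs
from .simulate import CTD_CONDITIONS

log = logging.getLogger(__name__)

MODELS = ("parametric", "npl_linear", "npl_exponential")
SCOPES = ("twopoint", "multipoint")
_LN10 = math.log(10.0)


@dataclass(frozen=True)
class StratificationRule:
    conditions: tuple[str, ...] = CTD_CONDITIONS
    positive_label: str = "CTD-positive"
    negative_label: str = "CTD-negative"


def stratify(cohort: Cohort, flags: pd.DataFrame,
             rule: StratificationRule = StratificationRule()):
    """Split families into (positive, negative) fid lists: positive = any
    qualifying condition flagged."""
    missing = [f for f in cohort.families if f not in flags.index]
    if missing:
        raise ValueError(f"families lacking condition flags: {missing}")
    pos, neg = [], []
    cols = [c for c in rule.conditions if c in flags.columns]
    for fid in cohort.families:
        if bool(flags.loc[fid, cols].any()):
            pos.append(fid)
        else:
            neg.append(fid)
    log.info("stratification: %d %s, %d %s", len(pos), rule.positive_label,
             len(neg), rule.negative_label)
    return pos, neg


def stratified_scan(cohort: Cohort, flags: pd.DataFrame,
                    config: EngineConfig | None = None,
                    rule: StratificationRule = StratificationRule(),
                    refit_freqs: bool = True):
    """All six analyses within each stratum separately.

    Returns ``{label: (tp_frame, mp_frame, tables)}``.  Founder allele
    frequencies are re-estimated per stratum unless ``refit_freqs=False``.
    """
    from .linkage.scan import genome_scan
    pos, neg = stratify(cohort, flags, rule)
    out = {}
    for label, fids in ((rule.positive_label, pos), (rule.negative_label, neg)):
        if not fids:
            raise ValueError(f"stratum {label} has no families")
        sub = cohort.subset_families(fids)
        if refit_freqs:
            sub = Cohort(sub.families, _copy_map(cohort.map), sub.batches)
            estimate_allele_freqs(sub, who="founders")
        out[label] = genome_scan(sub, config)
    return out


def _copy_map(mm):
    from .pedigree import MarkerMap
    return MarkerMap(list(mm.chrom), list(mm.marker), mm.cm.copy(),
                     mm.bp.copy(), [list(a) for a in mm.alleles],
                     [None if f is None else f.copy() for f in mm.freqs])


# ---------------------------------------------------------------------------
# Fast subset evaluator
# ---------------------------------------------------------------------------

class SubsetEvaluator:
    """Per-chromosome max-LOD statistics for arbitrary family subsets, from
    precomputed genome tables."""

    def __init__(self, tables: dict[str, ChromosomeTables],
                 alpha_step: float = 0.05,
                 delta_grid: np.ndarray | None = None):
        self.tables = tables
        self.alphas = np.arange(0.0, 1.0 + 1e-9, alpha_step)
        self.deltas = delta_grid if delta_grid is not None else \
            np.linspace(0.0, 2.5, 26)
        self.fids = sorted({f for t in tables.values() for f in t.families})
        self._fid_index = {f: i for i, f in enumerate(self.fids)}
        self._chrom: dict[str, dict] = {}
        for chrom, t in tables.items():
            entry: dict = {"tp_param": {}, "mp_param": {},
                           "tp_lin": {}, "tp_exp": {}, "mp_lin": {}, "mp_exp": {}}
            for fid, ft in t.families.items():
                if ft.tp_lod is not None:
                    entry["tp_param"][fid] = np.power(10.0, ft.tp_lod)
                if ft.mp_lod is not None:
                    entry["mp_param"][fid] = np.power(10.0, ft.mp_lod)
                if ft.tp_scores is not None and ft.tp_scores.informative:
                    lin, expo = kong_cox_logmgf_tables(ft.tp_scores, self.deltas)
                    entry["tp_lin"][fid] = lin
                    entry["tp_exp"][fid] = expo
                if ft.mp_scores is not None and ft.mp_scores.informative:
                    lin, expo = kong_cox_logmgf_tables(ft.mp_scores, self.deltas)
                    entry["mp_lin"][fid] = lin
                    entry["mp_exp"][fid] = expo
            self._chrom[chrom] = entry

    def _hlod_max(self, mats: list[np.ndarray]) -> float:
        if not mats:
            return 0.0
        ratios = np.stack(mats)                       # (F, ...) of 10^LOD
        shape = (-1,) + (1,) * ratios.ndim
        mix = self.alphas.reshape(shape) * ratios[None] \
            + (1.0 - self.alphas).reshape(shape)
        ll = np.log10(mix).sum(axis=1)
        return max(0.0, float(ll.max()))

    def _kc_max(self, tabs: list[np.ndarray]) -> float:
        if not tabs:
            return 0.0
        tot = np.sum(tabs, axis=0)                    # (P, D)
        best = np.max(tot)
        return max(0.0, float(best) / _LN10)

    def maxima(self, fids) -> dict[tuple[str, str], dict[str, float]]:
        """{(model, scope): {chrom: max LOD} plus 'GW'} for a family subset."""
        fset = set(fids)
        out: dict[tuple[str, str], dict[str, float]] = \
            {(m, s): {} for m in MODELS for s in SCOPES}
        for chrom, entry in self._chrom.items():
            sel = lambda d: [v for f, v in d.items() if f in fset]
            out[("parametric", "twopoint")][chrom] = \
                self._hlod_max(sel(entry["tp_param"]))
            out[("parametric", "multipoint")][chrom] = \
                self._hlod_max(sel(entry["mp_param"]))
            out[("npl_linear", "twopoint")][chrom] = self._kc_max(sel(entry["tp_lin"]))
            out[("npl_linear", "multipoint")][chrom] = self._kc_max(sel(entry["mp_lin"]))
            out[("npl_exponential", "twopoint")][chrom] = \
                self._kc_max(sel(entry["tp_exp"]))
            out[("npl_exponential", "multipoint")][chrom] = \
                self._kc_max(sel(entry["mp_exp"]))
        for key, d in out.items():
            d["GW"] = max(d.values()) if d else 0.0
        return out


def observed_maxima(tables: dict[str, ChromosomeTables], fids,
                    alpha_step: float = 0.05,
                    delta_grid: np.ndarray | None = None):
    """Observed per-chromosome/GW maxima for a stratum, computed with the
    same evaluators the permutation uses (apples to apples)."""
    return SubsetEvaluator(tables, alpha_step, delta_grid).maxima(fids)


# ---------------------------------------------------------------------------
# Conditional permutation
# ---------------------------------------------------------------------------

@dataclass
class PermutationDistribution:
    reps: int
    seed: int
    draws: dict[tuple[str, str], dict[str, np.ndarray]]   # chrom/GW -> (2R,)
    observed: dict[tuple[str, str], dict[str, float]]
    p_add_one: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    p_raw: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def finalize(self) -> None:
        for key, dmap in self.draws.items():
            self.p_add_one[key] = {}
            self.p_raw[key] = {}
            for region, arr in dmap.items():
                obs = self.observed[key][region]
                n = len(arr)
                c = int(np.sum(arr >= obs - 1e-12))
                self.p_add_one[key][region] = (c + 1) / (n + 1)
                self.p_raw[key][region] = c / n if n else math.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (model, scope), dmap in self.draws.items():
            for region, arr in dmap.items():
                rows.append({
                    "model": model, "scope": scope, "region": region,
                    "observed": self.observed[(model, scope)][region],
                    "q50": float(np.quantile(arr, 0.5)),
                    "q95": float(np.quantile(arr, 0.95)),
                    "q99": float(np.quantile(arr, 0.99)),
                    "p_emp": self.p_add_one[(model, scope)][region],
                    "p_raw": self.p_raw[(model, scope)][region],
                })
        return pd.DataFrame(rows)


def conditional_permutation(tables: dict[str, ChromosomeTables],
                            observed: dict[tuple[str, str], dict[str, float]],
                            reps: int = 500, seed: int = 0,
                            alpha_step: float = 0.05,
                            delta_grid: np.ndarray | None = None
                            ) -> PermutationDistribution:
    """Random half-split permutation distribution of max LOD scores.

    ``observed`` as returned by :func:`observed_maxima` for the stratum of
    interest.  Each repetition contributes both halves' maxima (2 draws).
    """
    if reps < 50:
        log.warning("reps=%d < 50: empirical p-values will be unstable", reps)
    ev = SubsetEvaluator(tables, alpha_step, delta_grid)
    fids = ev.fids
    if len(fids) % 2:
        log.warning("odd family count %d: halves of %d and %d", len(fids),
                    len(fids) // 2, len(fids) - len(fids) // 2)
    rng = np.random.default_rng(seed)
    regions = list(tables.keys()) + ["GW"]
    draws: dict[tuple[str, str], dict[str, list[float]]] = {
        (m, s): {r: [] for r in regions} for m in MODELS for s in SCOPES}
    half = len(fids) // 2
    for _ in range(reps):
        perm = rng.permutation(fids)
        for part in (perm[:half], perm[half:]):
            mx = ev.maxima(part)
            for key in draws:
                for r in regions:
                    draws[key][r].append(mx[key][r])
    dist = PermutationDistribution(
        reps=reps, seed=seed,
        draws={k: {r: np.asarray(v) for r, v in d.items()}
               for k, d in draws.items()},
        observed=observed)
    dist.finalize()
    return dist


def run_stratified_permutation(cohort: Cohort, flags: pd.DataFrame,
                               config: EngineConfig | None = None,
                               stratum: str = "negative",
                               reps: int = 500, seed: int = 0,
                               rule: StratificationRule = StratificationRule()):
    """End-to-end: precompute tables on the full cohort, take the observed
    maxima in the requested stratum, and permute.  Cohort-level founder
    frequencies are used throughout (the permutation halves share them)."""
    estimate_allele_freqs(cohort, who="founders")
    tables = genome_tables(cohort, config)
    pos, neg = stratify(cohort, flags, rule)
    fids = pos if stratum == "positive" else neg
    obs = observed_maxima(tables, fids)
    return conditional_permutation(tables, obs, reps=reps, seed=seed), tables
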