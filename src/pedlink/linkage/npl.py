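"""Nonparametric linkage: S_all scoring, NPL Z, and Kong-Cox one-parameter
allele-sharing LOD scores (linear and exponential models).

S_all for an inheritance vector is 2^-a * sum over ways of picking one
allele per affected of the product of factorials of founder-allele
multiplicities.  Null moments come from exact enumeration over uniform
inheritance vectors.  The Kong-Cox likelihoods tilt the per-family
inheritance distribution by delta >= 0: linearly (factors 1 + delta*z(v),
which reduces to 1 + delta*zbar given the data) or exponentially
(exp(delta*z(v)) renormalized), with equal family weights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ..pedigree import AFFECTED
from .descent import DescentGraph, InheritanceDistribution

log = logging.getLogger(__name__)


def sall_vector(graph: DescentGraph) -> np.ndarray | None:
    """S_all score for every inheritance vector; None if <2 affected."""
    aff_idx = [i for i, m in enumerate(graph.members) if m.affection == AFFECTED]
    a = len(aff_idx)
    if a < 2:
        return None
    slots = graph.slots[:, aff_idx, :]               # (nvec, a, 2)
    nvec = slots.shape[0]
    total = np.zeros(nvec)
    for pick in range(1 << a):
        chosen = np.empty((nvec, a), dtype=np.int16)
        for j in range(a):
            chosen[:, j] = slots[:, j, (pick >> j) & 1]
        chosen.sort(axis=1)
        # product of factorials of run lengths, computed per element as
        # (index within its run + 1)
        prod = np.ones(nvec)
        run = np.ones(nvec)
        for j in range(1, a):
            same = chosen[:, j] == chosen[:, j - 1]
            run = np.where(same, run + 1, 1.0)
            prod *= run
        total += prod
    return total / (1 << a)


@dataclass
class NplFamilyScores:
    """Per-family standardized sharing scores along one position grid.

    ``z_values``/``null_probs`` describe the exact null distribution of the
    standardized score; ``post_probs[p]`` is its posterior at position p.
    """
    fid: str
    pos_cm: np.ndarray          # (P,)
    zbar: np.ndarray            # (P,) posterior mean standardized score
    z_values: np.ndarray        # (U,) unique standardized score values
    null_probs: np.ndarray      # (U,)
    post_probs: np.ndarray      # (P, U)
    informative: bool = True


def npl_family_scores(graph: DescentGraph,
                      inh: InheritanceDistribution) -> NplFamilyScores | None:
    """Standardize S_all against its exact enumeration null; None when the
    family has <2 affected or a degenerate null (sigma = 0)."""
    s = sall_vector(graph)
    if s is None:
        log.info("family %s: <2 affected, skipped for NPL", graph.ped.fid)
        return None
    mu = float(s.mean())
    sigma = float(s.std())
    if sigma == 0.0:
        return NplFamilyScores(graph.ped.fid, inh.pos_cm,
                               np.zeros(len(inh.pos_cm)), np.zeros(1),
                               np.ones(1), np.ones((len(inh.pos_cm), 1)),
                               informative=False)
    z = (s - mu) / sigma
    zu, inverse = np.unique(np.round(z, 12), return_inverse=True)
    U = len(zu)
    null = np.bincount(inverse, minlength=U) / len(z)
    post = np.zeros((len(inh.pos_cm), U))
    np.add.at(post.T, inverse, inh.posteriors.T)
    zbar = post @ zu
    return NplFamilyScores(graph.ped.fid, inh.pos_cm, zbar, zu, null, post)


def combined_npl_z(families: list[NplFamilyScores]) -> np.ndarray:
    """Equal-weight combined NPL Z = sum z_f / sqrt(F) over informative families."""
    inf = [f for f in families if f.informative]
    if not inf:
        return np.zeros(len(families[0].pos_cm)) if families else np.zeros(0)
    return np.sum([f.zbar for f in inf], axis=0) / math.sqrt(len(inf))


# ---------------------------------------------------------------------------
# Kong-Cox
# ---------------------------------------------------------------------------

_LN10 = math.log(10.0)


def _golden_max(fun, lo: float, hi: float, tol: float = 1e-6) -> float:
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return 0.5 * (a + b)


def _delta_bound_linear(families: list[NplFamilyScores]) -> float:
    zmin = 0.0
    for f in families:
        m = float(f.z_values[f.null_probs > 0].min()) if f.informative else 0.0
        zmin = min(zmin, m)
    if zmin >= 0:
        return 10.0
    return -1.0 / zmin * (1.0 - 1e-9)


def kong_cox(families: list[NplFamilyScores], model: str = "linear",
             n_grid: int = 129):
    """Kong-Cox LOD along the shared position grid.

    Returns ``(lod, delta_hat)`` arrays of length P.  One-sided: delta >= 0,
    LOD clipped at 0.  Raises when no family is informative.
    """
    fams = [f for f in families if f.informative]
    if not fams:
        raise ValueError("Kong-Cox: no informative families (all Z undefined)")
    P = len(fams[0].pos_cm)
    if model == "linear":
        dmax = _delta_bound_linear(fams)

        zb_all = np.stack([f.zbar for f in fams])        # (F, P)

        def loglik(delta, p=None):
            arg = 1.0 + delta * (zb_all if p is None else zb_all[:, p])
            bad = np.any(arg <= 0, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.log(np.maximum(arg, 1e-300)).sum(axis=0)
            if p is None:
                out = np.where(bad, -np.inf, out)
                return out
            return -np.inf if bad else out
    elif model == "exponential":
        dmax = 3.0

        def loglik(delta, p=None):
            tot = 0.0
            for f in fams:
                e = np.exp(delta * f.z_values)           # (U,)
                post = f.post_probs if p is None else f.post_probs[p]
                tot = tot + np.log(post @ e) - math.log(float(f.null_probs @ e))
            return tot
    else:
        raise ValueError(f"unknown Kong-Cox model {model!r}")

    grid = np.linspace(0.0, dmax, n_grid)
    ll = np.stack([np.atleast_1d(loglik(d)) for d in grid])   # (G, P)
    ll[np.isneginf(ll)] = -np.inf
    best = np.argmax(ll, axis=0)
    lod = np.empty(P)
    delta_hat = np.empty(P)
    for p in range(P):
        g = int(best[p])
        if g == 0 and ll[min(g + 1, n_grid - 1), p] <= ll[0, p]:
            lod[p], delta_hat[p] = 0.0, 0.0
            continue
        lo = grid[max(g - 1, 0)]
        hi = grid[min(g + 1, n_grid - 1)]
        d = _golden_max(lambda x: loglik(x, p), lo, hi)
        val = loglik(d, p)
        if val <= 0.0 or d <= 0.0:
            lod[p], delta_hat[p] = 0.0, 0.0
        else:
            lod[p], delta_hat[p] = val / _LN10, d
    return lod, delta_hat


def kong_cox_logmgf_tables(f: NplFamilyScores, delta_grid: np.ndarray):
    """Precomputed per-family tables for the fast permutation path.

    Returns ``(lin, expo)``: ``lin[p, d] = ln(1 + delta_d * zbar[p])`` (-inf
    when invalid) and ``expo[p, d] = ln E_post[e^{dz}] - ln E_0[e^{dz}]``.
    """
    zb = f.zbar[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        lin = np.log1p(delta_grid[None, :] * zb)
    lin[1.0 + delta_grid[None, :] * zb <= 0] = -np.inf
    if f.informative:
        zmin = float(f.z_values[f.null_probs > 0].min())
        if zmin < 0:
            lin[:, delta_grid > -1.0 / zmin] = -np.inf
    e = np.exp(np.outer(f.z_values, delta_grid))          # (U, D)
    expo = np.log(f.post_probs @ e) - np.log(f.null_probs @ e)[None, :]
    return lin, expo
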