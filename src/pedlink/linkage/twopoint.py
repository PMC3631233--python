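"""Two-point LOD curves, heterogeneity LOD (HLOD) and support intervals."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..pedigree import Cohort, DiseaseModel, Pedigree

DEFAULT_THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class ThetaGrid:
    thetas: tuple[float, ...] = DEFAULT_THETA_GRID

    def __post_init__(self):
        t = self.thetas
        if list(t) != sorted(set(t)):
            raise ValueError("theta grid must be strictly increasing")
        if t[-1] != 0.5:
            raise ValueError("theta grid must include 0.5")
        if t[0] < 0:
            raise ValueError("theta must be >= 0")

    def __iter__(self):
        return iter(self.thetas)

    def __len__(self):
        return len(self.thetas)


def family_lod_curve(ped: Pedigree, marker_index: int, freqs, dm: DiseaseModel,
                     grid: ThetaGrid = ThetaGrid(),
                     use_unaffected: bool = False) -> np.ndarray:
    """LOD(theta) for one family at one marker: log10 L(theta) - log10 L(0.5)."""
    from .peeling import pedigree_likelihood
    l_half = pedigree_likelihood(ped, marker_index, freqs, dm, 0.5,
                                 use_unaffected=use_unaffected)
    if l_half <= 0:
        raise ValueError(
            f"family {ped.fid}: zero likelihood at theta=0.5 "
            "(phenotypes impossible under disease model)")
    out = np.empty(len(grid))
    for i, th in enumerate(grid):
        if th == 0.5:
            out[i] = 0.0
            continue
        l = pedigree_likelihood(ped, marker_index, freqs, dm, th,
                                use_unaffected=use_unaffected)
        out[i] = math.log10(l) - math.log10(l_half) if l > 0 else -math.inf
    return out


def twopoint_lod(cohort: Cohort, marker_index: int, dm: DiseaseModel,
                 grid: ThetaGrid = ThetaGrid(), use_unaffected: bool = False):
    """Cohort two-point LOD curve (sum over families) at one marker.

    Returns ``(lod_curve, per_family, theta_hat, max_lod)`` where
    ``per_family`` maps fid -> curve on the same grid.
    """
    freqs = cohort.map.freqs[marker_index]
    per_family = {ped.fid: family_lod_curve(ped, marker_index, freqs, dm, grid,
                                            use_unaffected)
                  for ped in cohort}
    total = np.sum(list(per_family.values()), axis=0) if per_family else \
        np.zeros(len(grid))
    imax = int(np.argmax(total))
    return total, per_family, grid.thetas[imax], float(total[imax])


def hlod(per_family_curves: dict[str, np.ndarray],
         grid: ThetaGrid = ThetaGrid(),
         alpha_step: float = 0.01):
    """Smith admixture heterogeneity LOD.

    HLOD = max over (theta, alpha) of sum_f log10(alpha*10^LOD_f + 1 - alpha).
    Returns ``(hlod, alpha_hat, theta_hat)``; alpha_hat = 0 by convention when
    the curve is flat at zero.
    """
    if not per_family_curves:
        raise ValueError("hlod requires at least one family")
    curves = np.vstack(list(per_family_curves.values()))   # (F, T)
    alphas = np.arange(0.0, 1.0 + 1e-9, alpha_step)
    ratios = np.power(10.0, curves)                        # (F, T)
    # (A, F, T): alpha*ratio + (1-alpha)
    mix = alphas[:, None, None] * ratios[None, :, :] + (1.0 - alphas)[:, None, None]
    with np.errstate(divide="ignore"):
        ll = np.log10(mix).sum(axis=1)                     # (A, T)
    a_i, t_i = np.unravel_index(int(np.argmax(ll)), ll.shape)
    best = float(ll[a_i, t_i])
    if best <= 0.0:
        return 0.0, 0.0, 0.5
    return best, float(alphas[a_i]), float(grid.thetas[t_i])


@dataclass
class LinkageResult:
    """Per-position linkage statistics for one scan."""
    chrom: list[str] = field(default_factory=list)
    pos_cm: list[float] = field(default_factory=list)
    bp: list[float] = field(default_factory=list)
    lod: list[float] = field(default_factory=list)
    hlod: list[float] = field(default_factory=list)
    alpha: list[float] = field(default_factory=list)
    npl_z: list[float] = field(default_factory=list)
    kc_lin: list[float] = field(default_factory=list)
    kc_lin_delta: list[float] = field(default_factory=list)
    kc_exp: list[float] = field(default_factory=list)
    kc_exp_delta: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({k: getattr(self, k) for k in
                             ("chrom", "pos_cm", "bp", "lod", "hlod", "alpha",
                              "npl_z", "kc_lin", "kc_lin_delta", "kc_exp",
                              "kc_exp_delta")})


def support_interval(pos_cm: np.ndarray, lod: np.ndarray,
                     bp: np.ndarray | None = None, drop: float = 1.0):
    """Maximal contiguous run of positions with LOD >= max - drop around the
    peak; boundaries refined by linear interpolation (in cM and, when ``bp``
    is given, in bp)."""
    pos_cm = np.asarray(pos_cm, float)
    lod = np.asarray(lod, float)
    imax = int(np.argmax(lod))
    if np.all(lod == lod[imax]):
        import logging
        logging.getLogger(__name__).warning(
            "flat LOD curve: support interval spans the whole region")
        return (float(pos_cm[0]), float(pos_cm[-1]),
                (float(bp[0]), float(bp[-1])) if bp is not None else None)
    cut = lod[imax] - drop
    lo = imax
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = imax
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1

    def interp(i, j):
        # crossing between grid points i (below cut) and j (>= cut)
        if lod[j] == lod[i]:
            return pos_cm[j]
        t = (cut - lod[i]) / (lod[j] - lod[i])
        return pos_cm[i] + t * (pos_cm[j] - pos_cm[i])

    start = interp(lo - 1, lo) if lo > 0 else float(pos_cm[0])
    end = interp(hi + 1, hi) if hi < len(lod) - 1 else float(pos_cm[-1])
    bp_pair = None
    if bp is not None:
        bp = np.asarray(bp, float)
        bp_pair = (float(np.interp(start, pos_cm, bp)),
                   float(np.interp(end, pos_cm, bp)))
    return float(start), float(end), bp_pair
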