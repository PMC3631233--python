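"""Multipoint genotyping-error detection: a genotype is flagged when removing
it increases the family's chromosome likelihood far more than its population
frequency explains (unlikely double recombinants and similar)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ..pedigree import MISSING, Cohort
from .descent import BitCapExceeded, DescentGraph, lander_green

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlaggedGenotype:
    fid: str
    pid: str
    marker_index: int
    ratio: float


def _hwe_prob(freqs: np.ndarray, a: int, b: int) -> float:
    if a == MISSING or b == MISSING:
        return 1.0
    pa, pb = float(freqs[a]), float(freqs[b])
    return pa * pb if a == b else 2.0 * pa * pb


def error_detect(cohort: Cohort, chromosome: str, threshold: float = 1000.0,
                 bit_cap: int = 16) -> list[FlaggedGenotype]:
    """Scan one chromosome for improbable genotypes.

    Flags (fid, pid, marker) where
    ``P_HWE(g) * L(data without g) / L(data) > threshold``.
    """
    idx = cohort.map.chrom_indices(chromosome)
    cm = cohort.map.cm[idx]
    flags: list[FlaggedGenotype] = []
    for ped in cohort:
        try:
            graph = DescentGraph(ped, bit_cap)
        except BitCapExceeded as e:
            log.warning("error_detect: %s", e)
            continue
        emissions = [graph.marker_emission(int(i), cohort.map.freqs[int(i)])
                     for i in idx]
        base = lander_green(graph, cm, emissions,
                            positions=np.array([cm[0]])).log_likelihood
        for pid, g in ped.genotypes.items():
            mi = graph.member_index.get(pid)
            if mi is None:
                continue
            for k, i in enumerate(idx):
                a, b = int(g[i, 0]), int(g[i, 1])
                if a == MISSING and b == MISSING:
                    continue
                saved = g[i].copy()
                g[i] = MISSING
                emis_k = graph.marker_emission(int(i), cohort.map.freqs[int(i)])
                g[i] = saved
                trial = emissions[:k] + [emis_k] + emissions[k + 1:]
                ll = lander_green(graph, cm, trial,
                                  positions=np.array([cm[0]])).log_likelihood
                ratio = _hwe_prob(cohort.map.freqs[int(i)], a, b) * \
                    math.exp(ll - base)
                if ratio > threshold:
                    flags.append(FlaggedGenotype(ped.fid, pid, int(i), ratio))
    return flags


def apply_mask(cohort: Cohort, flags: list[FlaggedGenotype]) -> int:
    """Set flagged genotypes missing in place; returns the number masked."""
    n = 0
    for f in flags:
        g = cohort.families[f.fid].genotypes.get(f.pid)
        if g is not None:
            g[f.marker_index] = MISSING
            n += 1
    return n
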