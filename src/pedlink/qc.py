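"""Marker and sample quality control.

The SNP filter cascade applies, in order: call rate, cross-batch presence,
Mendelian-error family fraction, MAF (unaffected founders), HWE exact test
(unaffected founders), identical physical position, missing genetic
distance, identical genetic position at two decimal places.  A marker is
attributed to the FIRST filter that removes it.  Genotypes at surviving
markers showing non-Mendelian inheritance are masked for the whole family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import (AFFECTED, MISSING, UNAFFECTED, Cohort, MarkerMap,
                       Pedigree, estimate_allele_freqs)

log = logging.getLogger(__name__)

FILTER_ORDER = ("call_rate", "batch", "mendel", "maf", "hwe",
                "dup_bp", "missing_cm", "dup_cm")


@dataclass
class QCThresholds:
    min_call_rate: float = 0.98
    mendel_family_frac: float = 0.04
    min_maf: float = 0.05
    hwe_alpha: float = 0.001
    drop_identical_bp: bool = True
    drop_missing_cm: bool = True
    drop_identical_cm_2dp: bool = True
    f_sd_limit: float = 4.0

    def __post_init__(self):
        for name in ("min_call_rate", "mendel_family_frac", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"QC threshold {name}={v} outside [0,1]")


@dataclass
class QCReport:
    removed: dict[str, list[str]] = field(default_factory=dict)
    sample_exclusions: list[tuple[str, str, str]] = field(default_factory=list)
    masked: list[tuple[str, str]] = field(default_factory=list)  # (fid, marker)
    n_input: int = 0
    n_surviving: int = 0

    def counts(self) -> dict[str, int]:
        return {f: len(self.removed.get(f, [])) for f in FILTER_ORDER}

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, len(self.removed.get(f, []))) for f in FILTER_ORDER]
        rows.append(("surviving", self.n_surviving))
        return pd.DataFrame(rows, columns=["filter", "n_markers"])


# ---------------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------------

def _ppc_consistent(child: tuple[int, int], fa: tuple[int, int],
                    mo: tuple[int, int]) -> bool:
    c = set()
    for pa in fa:
        for ma in mo:
            c.add((pa, ma))
            c.add((ma, pa))
    return tuple(child) in c or (child[1], child[0]) in c


def mendelian_error_scan(cohort: Cohort) -> pd.DataFrame:
    """Scan every family x marker for Mendelian violations.

    P-P-C: child genotype impossible given both genotyped parents.
    P-C: child shares no allele with a single genotyped parent.
    Returns a table (family, marker_index, marker, child, kind).
    """
    rows = []
    for ped in cohort:
        for ind in ped.nonfounders():
            cg = ped.genotypes.get(ind.pid)
            if cg is None:
                continue
            fg = ped.genotypes.get(ind.father)
            mg = ped.genotypes.get(ind.mother)
            for j in range(len(cohort.map)):
                c = (int(cg[j, 0]), int(cg[j, 1]))
                if MISSING in c:
                    continue
                fa = None if fg is None else (int(fg[j, 0]), int(fg[j, 1]))
                mo = None if mg is None else (int(mg[j, 0]), int(mg[j, 1]))
                fa = None if fa is not None and MISSING in fa else fa
                mo = None if mo is not None and MISSING in mo else mo
                if fa is not None and mo is not None:
                    if not _ppc_consistent(c, fa, mo):
                        rows.append((ped.fid, j, cohort.map.marker[j],
                                     ind.pid, "P-P-C"))
                elif fa is not None or mo is not None:
                    par = fa if fa is not None else mo
                    if not (set(c) & set(par)):
                        rows.append((ped.fid, j, cohort.map.marker[j],
                                     ind.pid, "P-C"))
    return pd.DataFrame(rows, columns=["family", "marker_index", "marker",
                                       "child", "kind"])


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional HWE test: sum of probabilities of heterozygote
    counts no more probable than observed, given the allele counts."""
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no observations")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = range(rare % 2, rare + 1, 2)
    logs = {}
    for h in hets:
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        logs[h] = (math.lgamma(n + 1) - math.lgamma(naa + 1)
                   - math.lgamma(h + 1) - math.lgamma(nbb + 1)
                   + h * math.log(2.0))
    mx = max(logs.values())
    probs = {h: math.exp(v - mx) for h, v in logs.items()}
    tot = sum(probs.values())
    p_obs = probs[n_ab] / tot
    p = sum(v for v in probs.values() if v / tot <= p_obs * (1 + 1e-12)) / tot
    return min(1.0, p)


def _genotype_counts(cohort: Cohort, j: int, unaffected_founders: bool = True):
    """(n_aa, n_ab, n_bb) at marker j over (unaffected) founders; allele 0 = a."""
    naa = nab = nbb = 0
    for ped in cohort:
        for ind in ped.founders():
            if unaffected_founders and ind.affection != UNAFFECTED:
                continue
            g = ped.genotypes.get(ind.pid)
            if g is None:
                continue
            a, b = int(g[j, 0]), int(g[j, 1])
            if a == MISSING or b == MISSING:
                continue
            if a == b == 0:
                naa += 1
            elif a != b:
                nab += 1
            else:
                nbb += 1
    return naa, nab, nbb


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def _call_rates(cohort: Cohort) -> np.ndarray:
    n_called = np.zeros(len(cohort.map))
    n_total = 0
    for ped in cohort:
        for pid, g in ped.genotypes.items():
            if not ped.members[pid].sampled:
                continue
            n_total += 1
            n_called += np.all(g != MISSING, axis=1)
    return n_called / max(n_total, 1)


def _batch_presence(cohort: Cohort) -> dict[str, np.ndarray]:
    """Per batch: per-marker non-missing call count."""
    out: dict[str, np.ndarray] = {}
    for ped in cohort:
        for pid, g in ped.genotypes.items():
            if not ped.members[pid].sampled:
                continue
            b = cohort.batch_of(ped, pid)
            out.setdefault(b, np.zeros(len(cohort.map)))
            out[b] += np.all(g != MISSING, axis=1)
    return out


def snp_filter_cascade(cohort: Cohort, thresholds: QCThresholds | None = None
                       ) -> tuple[Cohort, QCReport]:
    """Apply the marker filter cascade; returns the filtered cohort and report.

    Also masks, per family, the genotypes of every surviving marker with a
    Mendelian violation in that family.
    """
    th = thresholds or QCThresholds()
    mm = cohort.map
    M = len(mm)
    report = QCReport(n_input=M)
    status = np.full(M, "", dtype=object)   # first-hit filter name or ""

    call = _call_rates(cohort)
    for j in np.flatnonzero(call < th.min_call_rate):
        status[j] = "call_rate"

    batches = _batch_presence(cohort)
    if len(batches) > 1:
        for j in range(M):
            if status[j]:
                continue
            if any(b[j] == 0 for b in batches.values()):
                status[j] = "batch"

    errors = mendelian_error_scan(cohort)
    fam_with_err: dict[int, set[str]] = {}
    for _, row in errors.iterrows():
        fam_with_err.setdefault(int(row.marker_index), set()).add(row.family)
    scoreable = _scoreable_families(cohort)
    for j, fams in fam_with_err.items():
        if status[j]:
            continue
        denom = scoreable[j]
        if denom and len(fams) / denom > th.mendel_family_frac:
            status[j] = "mendel"

    estimate_allele_freqs(cohort, who="unaffected_founders")
    for j in range(M):
        if status[j]:
            continue
        f = mm.freqs[j]
        maf = mm.maf(j)
        if f is None or (not math.isnan(maf) and maf < th.min_maf):
            status[j] = "maf"

    for j in range(M):
        if status[j]:
            continue
        naa, nab, nbb = _genotype_counts(cohort, j)
        if naa + nab + nbb and hwe_exact_test(naa, nab, nbb) < th.hwe_alpha:
            status[j] = "hwe"

    if th.drop_identical_bp:
        _dedup(cohort, status, key=lambda j: (mm.chrom[j], int(mm.bp[j])),
               call=call, name="dup_bp")

    if th.drop_missing_cm:
        for j in range(M):
            if not status[j] and math.isnan(mm.cm[j]):
                status[j] = "missing_cm"

    if th.drop_identical_cm_2dp:
        _dedup(cohort, status,
               key=lambda j: (mm.chrom[j], None if math.isnan(mm.cm[j])
                              else round(mm.cm[j], 2)),
               call=call, name="dup_cm")

    for name in FILTER_ORDER:
        report.removed[name] = [mm.marker[j] for j in range(M)
                                if status[j] == name]
    keep = np.flatnonzero(status == "")
    filtered = cohort.subset_markers(keep)
    report.n_surviving = len(keep)

    # Mendelian masking on the surviving map
    keep_old = {int(old): new for new, old in enumerate(keep)}
    for _, row in errors.iterrows():
        new_j = keep_old.get(int(row.marker_index))
        if new_j is None:
            continue
        fam = filtered.families[row.family]
        for g in fam.genotypes.values():
            g[new_j] = MISSING
        report.masked.append((row.family, filtered.map.marker[new_j]))
    report.masked = sorted(set(report.masked))
    log.info("QC cascade: %d -> %d markers; per-filter %s; %d family-marker "
             "genotype masks", M, len(keep), report.counts(), len(report.masked))
    return filtered, report


def _scoreable_families(cohort: Cohort) -> np.ndarray:
    """Per marker: number of families with >=1 trio/duo where child and at
    least one parent are genotyped (Mendel-fraction denominator)."""
    M = len(cohort.map)
    out = np.zeros(M)
    for ped in cohort:
        fam_ok = np.zeros(M, dtype=bool)
        for ind in ped.nonfounders():
            cg = ped.genotypes.get(ind.pid)
            if cg is None:
                continue
            c_ok = np.all(cg != MISSING, axis=1)
            for par in (ind.father, ind.mother):
                pg = ped.genotypes.get(par)
                if pg is not None:
                    fam_ok |= c_ok & np.all(pg != MISSING, axis=1)
        out += fam_ok
    return out


def _dedup(cohort: Cohort, status: np.ndarray, key, call: np.ndarray,
           name: str) -> None:
    groups: dict[object, list[int]] = {}
    for j in range(len(cohort.map)):
        if status[j]:
            continue
        k = key(j)
        if k is None or (isinstance(k, tuple) and k[1] is None):
            continue
        groups.setdefault(k, []).append(j)
    for k, js in groups.items():
        if len(js) < 2:
            continue
        # keep highest call rate, then lowest bp
        js_sorted = sorted(js, key=lambda j: (-call[j], int(cohort.map.bp[j])))
        for j in js_sorted[1:]:
            status[j] = name


# ---------------------------------------------------------------------------
# Inbreeding
# ---------------------------------------------------------------------------

def inbreeding_coefficient(genotypes: np.ndarray, freqs: list) -> float:
    """Method-of-moments F for one sample: (O_hom - E_hom) / (N - E_hom)
    over non-missing biallelic markers with known founder frequencies."""
    o_hom = 0.0
    e_hom = 0.0
    n = 0
    for j in range(genotypes.shape[0]):
        f = freqs[j]
        if f is None or len(f) != 2:
            continue
        a, b = int(genotypes[j, 0]), int(genotypes[j, 1])
        if a == MISSING or b == MISSING:
            continue
        p = float(f[0])
        n += 1
        e_hom += 1.0 - 2.0 * p * (1.0 - p)
        o_hom += 1.0 if a == b else 0.0
    if n == 0 or n == e_hom:
        raise ValueError("no informative markers for inbreeding coefficient")
    return (o_hom - e_hom) / (n - e_hom)


def inbreeding_outliers(cohort: Cohort, f_sd_limit: float = 4.0) -> pd.DataFrame:
    """Per-sample F with cohort-level outlier flag |F - mean| > limit * sd."""
    rows = []
    for ped in cohort:
        for pid, g in ped.genotypes.items():
            if not ped.members[pid].sampled:
                continue
            try:
                f = inbreeding_coefficient(g, cohort.map.freqs)
            except ValueError:
                f = math.nan
            rows.append((ped.fid, pid, f))
    df = pd.DataFrame(rows, columns=["family", "person", "F"])
    mean, sd = df["F"].mean(), df["F"].std(ddof=0)
    df["outlier"] = (df["F"] - mean).abs() > f_sd_limit * sd if sd > 0 else False
    df.loc[df["F"].isna(), "outlier"] = True
    return df


# ---------------------------------------------------------------------------
# Multipoint marker selection
# ---------------------------------------------------------------------------

def select_multipoint_markers(mm: MarkerMap, target_spacing_cm: float,
                              ) -> tuple[MarkerMap, float, float]:
    """Greedy per-chromosome thinning: within each spacing window keep the
    marker with the highest MAF (ties -> lower bp).

    Returns ``(thinned map, mean spacing, mean MAF)``.
    """
    if target_spacing_cm <= 0:
        raise ValueError("target spacing must be positive")
    chosen: list[int] = []
    for c in mm.chromosomes():
        idx = mm.chrom_indices(c)
        idx = idx[~np.isnan(mm.cm[idx])]
        if len(idx) == 0:
            continue
        start = mm.cm[idx].min()
        end = mm.cm[idx].max()
        w = start
        while w <= end + 1e-9:
            inside = [int(j) for j in idx
                      if w <= mm.cm[j] < w + target_spacing_cm]
            if inside:
                best = max(inside, key=lambda j: (
                    -math.inf if math.isnan(mm.maf(j)) else mm.maf(j),
                    -int(mm.bp[j])))
                chosen.append(best)
            w += target_spacing_cm
    chosen.sort(key=lambda j: (mm.chrom[j], mm.cm[j], mm.bp[j]))
    thinned = mm.subset(np.array(chosen, dtype=int))
    per_chrom = [thinned.spacings(c) for c in thinned.chromosomes()
                 if len(thinned.chrom_indices(c)) > 1]
    spacings = np.concatenate(per_chrom) if per_chrom else np.array([])
    mafs = [thinned.maf(i) for i in range(len(thinned))]
    mean_sp = float(np.mean(spacings)) if len(spacings) else math.nan
    mean_maf = float(np.nanmean(mafs)) if mafs else math.nan
    log.info("multipoint selection: %d -> %d markers, mean spacing %.3f cM, "
             "mean MAF %.3f", len(mm), len(thinned), mean_sp, mean_maf)
    return thinned, mean_sp, mean_maf
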