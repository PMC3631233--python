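"""Candidate-variant triage and family segregation classification.

Selection keeps variants that (1) are rare in the reference population
(MAF < 0.05; novel variants pass vacuously), (2) were identified in more
than one affected individual (with an explicit same-family exception flag
for novel variants), and (3) have a reference MAF below the study MAF
estimated from screened affected carriers.

Segregation per family: complete sharing when every genotyped affected
carries the variant; reduced penetrance when any genotyped unaffected or
uncertain member carries it (unknown when none are genotyped).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

CARRIER_STATES = ("het", "hom_alt", "hom_ref", "unknown")


@dataclass(frozen=True)
class VariantRecord:
    gene: str
    chrom: str
    position: int
    variant_id: str
    ref: str
    alt: str
    variant_class: str
    study_maf: float | None = None        # estimated from screened affecteds
    ref_maf: float | None = None          # e.g. 1000 Genomes European; None = novel
    n_affected_carriers: int = 0
    same_family_novel: bool = False       # novel variants co-identified in one family

    def __post_init__(self):
        if self.position <= 0:
            raise ValueError(f"{self.variant_id}: position must be positive")
        for maf in (self.study_maf, self.ref_maf):
            if maf is not None and not 0.0 <= maf <= 0.5:
                raise ValueError(
                    f"{self.variant_id}: MAF {maf} outside [0, 0.5] "
                    "(minor-allele convention)")


def select_variants(records: list[VariantRecord],
                    max_ref_maf: float = 0.05) -> list[VariantRecord]:
    """Apply the three follow-up criteria; order-independent."""
    out = []
    for r in sorted(records, key=lambda v: (v.chrom, v.position, v.variant_id)):
        if r.study_maf is None:
            raise ValueError(f"{r.variant_id}: study MAF missing")
        if r.ref_maf is not None and r.ref_maf >= max_ref_maf:
            continue
        if r.n_affected_carriers <= 1 and not r.same_family_novel:
            continue
        if r.ref_maf is not None and r.ref_maf >= r.study_maf:
            continue
        out.append(r)
    return out


@dataclass
class SegregationResult:
    family: str
    complete_sharing: str        # yes / no / unknown
    reduced_penetrance: str      # yes / no / unknown
    affected_carriers: int
    affected_total: int
    unaffected_carriers: int
    unaffected_total: int

    def sharing_label(self) -> str:
        return (f"{self.complete_sharing.capitalize()} "
                f"({self.affected_carriers}/{self.affected_total})")

    def penetrance_label(self) -> str:
        return (f"{self.reduced_penetrance.capitalize()} "
                f"({self.unaffected_carriers}/{self.unaffected_total})")


def _carries(state: str) -> bool:
    return state in ("het", "hom_alt")


def segregation_check(carriers: pd.DataFrame) -> list[SegregationResult]:
    """Classify sharing/penetrance per family.

    ``carriers`` columns: family, person, affection ('affected', 'unaffected'
    or 'uncertain'), carrier ('het'/'hom_alt'/'hom_ref'/'unknown').  Only
    sampled (genotyped) members should appear; 'unknown' rows are ignored in
    counts.  Families with zero genotyped members are skipped with a log line.
    """
    bad = set(carriers["carrier"]) - set(CARRIER_STATES)
    if bad:
        raise ValueError(f"unknown carrier states: {sorted(bad)}")
    out = []
    for fid, grp in carriers.groupby("family", sort=True):
        typed = grp[grp["carrier"] != "unknown"]
        if typed.empty:
            log.info("family %s: no genotyped members, skipped", fid)
            continue
        aff = typed[typed["affection"] == "affected"]
        non = typed[typed["affection"].isin(("unaffected", "uncertain"))]
        aff_carry = int(aff["carrier"].map(_carries).sum())
        non_carry = int(non["carrier"].map(_carries).sum())
        if len(aff) == 0:
            sharing = "unknown"
        else:
            sharing = "yes" if aff_carry == len(aff) else "no"
        if len(non) == 0:
            pen = "unknown"
        else:
            pen = "yes" if non_carry > 0 else "no"
        out.append(SegregationResult(str(fid), sharing, pen, aff_carry,
                                     len(aff), non_carry, len(non)))
    return out


def segregation_table(variant: VariantRecord,
                      carriers: pd.DataFrame) -> pd.DataFrame:
    """Per-family report mirroring the follow-up table layout."""
    rows = []
    for r in segregation_check(carriers):
        rows.append({
            "gene": variant.gene, "chrom": variant.chrom,
            "position": variant.position, "variant_id": variant.variant_id,
            "alleles": f"{variant.ref}/{variant.alt}",
            "class": variant.variant_class,
            "maf": f"{_fmt(variant.study_maf)}/{_fmt(variant.ref_maf)}",
            "family": r.family,
            "all_affected": r.sharing_label(),
            "reduced_penetrance": r.penetrance_label(),
        })
    return pd.DataFrame(rows)


def _fmt(maf: float | None) -> str:
    return "NA" if maf is None or (isinstance(maf, float) and math.isnan(maf)) \
        else f"{maf:.3f}"
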