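"""Synthetic cohort generator: multiplex families ascertained for >=2
affected sampled members, gene-dropped SNP maps with Haldane recombination,
optional linked disease locus per stratum, planted QC defects, and a truth
ledger sufficient for every downstream test.

Generation-mode penetrances default much higher than the analysis model:
with near-zero penetrances the >=2-affected ascertainment loop would almost
never terminate.  Analyses remain affecteds-only regardless, which is robust
to this mismatch.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import (AFFECTED, MISSING, UNAFFECTED, UNCERTAIN, Cohort,
                       DiseaseModel, Individual, MarkerMap, Pedigree,
                       cm_to_theta, write_mapfile, write_pedfile)

#: Qualifying clinical conditions for the connective-tissue stratification.
CTD_CONDITIONS = (
    "hypermobility", "kyphosis", "aneurysm", "mitral_valve_prolapse",
    "pectus_excavatum", "scoliosis", "orthostatic_hypotension",
    "supraventricular_tachycardia", "heart_valve_disease", "heart_murmur",
)

#: Generation-mode disease model (ascertainment-friendly dominant).
DEFAULT_GEN_MODEL = DiseaseModel(0.05, (0.01, 0.8, 0.8))


@dataclass
class MapSpec:
    n_chromosomes: int = 2
    markers_per_chrom: int = 10
    spacing_cm: float = 0.31
    maf_mean: float = 0.42
    maf_sd: float = 0.09
    min_maf: float = 0.05
    bp_spacing: int = 250_000


@dataclass
class DefectSpec:
    n_low_call_rate: int = 0
    call_rate_target: float = 0.90
    n_mendel: int = 0
    mendel_n_families: int = 3
    n_low_maf: int = 0
    low_maf: float = 0.01
    n_hwe: int = 0
    n_dup_bp: int = 0
    n_missing_cm: int = 0
    n_dup_cm: int = 0

    def total(self) -> int:
        return (self.n_low_call_rate + self.n_mendel + self.n_low_maf +
                self.n_hwe + self.n_dup_bp + self.n_missing_cm + self.n_dup_cm)


@dataclass
class CohortSpec:
    n_families: int = 66
    map_spec: MapSpec = field(default_factory=MapSpec)
    gen_model: DiseaseModel = field(default_factory=lambda: DEFAULT_GEN_MODEL)
    linked_chrom: str | None = None      # None -> null mode (no linked locus)
    linked_pos_cm: float | None = None
    linked_fraction: float = 1.0         # fraction of families linked
    min_affected: int = 2
    mean_children: float = 3.0           # nuclear sibship size target
    p_three_generation: float = 0.3
    p_unsampled_founder: float = 0.3
    uncertain_rate: float = 0.05
    missing_rate: float = 0.01
    max_ascertainment_tries: int = 20_000
    defects: DefectSpec = field(default_factory=DefectSpec)


@dataclass
class TruthLedger:
    """Everything acceptance tests may read about how a cohort was built."""
    linked: dict[str, bool]                      # fid -> linked at the locus
    locus: tuple[str, float] | None              # (chromosome, cM)
    marker_freqs: list[float]                    # generator freq of allele 0
    defects: dict[str, list[str]] = field(default_factory=dict)
    mendel_families: dict[str, list[str]] = field(default_factory=dict)
    strata: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["locus"] = list(self.locus) if self.locus else None
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _sample_structure(fid: str, spec: CohortSpec, rng: np.random.Generator
                      ) -> list[Individual]:
    three_gen = rng.random() < spec.p_three_generation
    members: list[Individual] = []

    def kid_count() -> int:
        return max(2, int(rng.poisson(spec.mean_children)))

    if three_gen:
        members.append(Individual("gf", fid, None, None, 1, UNAFFECTED,
                                  sampled=rng.random() > spec.p_unsampled_founder))
        members.append(Individual("gm", fid, None, None, 2, UNAFFECTED,
                                  sampled=rng.random() > spec.p_unsampled_founder))
        members.append(Individual("p1", fid, "gf", "gm", 1, UNAFFECTED))
        members.append(Individual("sp", fid, None, None, 2, UNAFFECTED,
                                  sampled=rng.random() > spec.p_unsampled_founder))
        for k in range(min(kid_count(), 3)):
            members.append(Individual(f"c{k}", fid, "p1", "sp",
                                      1 if rng.random() < 0.5 else 2, UNAFFECTED))
    else:
        members.append(Individual("fa", fid, None, None, 1, UNAFFECTED))
        members.append(Individual("mo", fid, None, None, 2, UNAFFECTED))
        for k in range(min(kid_count(), 5)):
            members.append(Individual(f"c{k}", fid, "fa", "mo",
                                      1 if rng.random() < 0.5 else 2, UNAFFECTED))
    return members


# ---------------------------------------------------------------------------
# Disease drop + ascertainment
# ---------------------------------------------------------------------------

def _drop_disease(members: list[Individual], dm: DiseaseModel,
                  rng: np.random.Generator):
    """One gene drop at the disease locus: ordered genotypes plus the meiosis
    bit (0 = grandpaternal) for each nonfounder side."""
    q = dm.allele_freq
    geno: dict[str, tuple[int, int]] = {}
    bits: dict[tuple[str, int], int] = {}
    for m in members:
        if m.father is None:
            geno[m.pid] = (int(rng.random() < q), int(rng.random() < q))
    for m in members:
        if m.father is None:
            continue
        alleles = []
        for side, parent in ((0, m.father), (1, m.mother)):
            b = int(rng.random() < 0.5)
            bits[(m.pid, side)] = b
            alleles.append(geno[parent][b])
        geno[m.pid] = (alleles[0], alleles[1])
    return geno, bits


def _ascertain_family(members: list[Individual], spec: CohortSpec,
                      rng: np.random.Generator):
    """Redraw disease genotypes and phenotypes until >=min_affected sampled
    members are affected.  Returns (genotypes, bits); mutates affections."""
    f = spec.gen_model.penetrances
    for _ in range(spec.max_ascertainment_tries):
        geno, bits = _drop_disease(members, spec.gen_model, rng)
        aff = {m.pid: rng.random() < f[sum(geno[m.pid])] for m in members}
        n_aff_sampled = sum(1 for m in members if aff[m.pid] and m.sampled)
        if n_aff_sampled >= spec.min_affected:
            for m in members:
                if aff[m.pid]:
                    m.affection = AFFECTED
                elif rng.random() < spec.uncertain_rate:
                    m.affection = UNCERTAIN
                else:
                    m.affection = UNAFFECTED
            return geno, bits
    raise RuntimeError(
        f"family {members[0].fid}: could not reach {spec.min_affected} affected "
        f"sampled members in {spec.max_ascertainment_tries} tries; increase "
        "generation penetrances or allele frequency")


# ---------------------------------------------------------------------------
# Marker drop
# ---------------------------------------------------------------------------

def _bit_path(cm: np.ndarray, rng: np.random.Generator,
              anchor_cm: float | None, anchor_bit: int | None) -> np.ndarray:
    """Meiosis indicator along a chromosome: Markov chain with Haldane flip
    probabilities, optionally conditioned on the bit at an anchor position."""
    M = len(cm)
    bits = np.empty(M, dtype=np.int8)
    if anchor_cm is None:
        bits[0] = rng.integers(2)
        for j in range(1, M):
            th = cm_to_theta(cm[j] - cm[j - 1])
            bits[j] = bits[j - 1] ^ (rng.random() < th)
        return bits
    k = int(np.searchsorted(cm, anchor_cm))
    # walk right from the anchor
    prev = anchor_bit
    prev_cm = anchor_cm
    for j in range(k, M):
        th = cm_to_theta(abs(cm[j] - prev_cm))
        prev = prev ^ (rng.random() < th)
        bits[j] = prev
        prev_cm = cm[j]
    # walk left
    prev = anchor_bit
    prev_cm = anchor_cm
    for j in range(k - 1, -1, -1):
        th = cm_to_theta(abs(prev_cm - cm[j]))
        prev = prev ^ (rng.random() < th)
        bits[j] = prev
        prev_cm = cm[j]
    return bits


def _drop_chromosome(members: list[Individual], cm: np.ndarray,
                     freqs: np.ndarray, rng: np.random.Generator,
                     anchor_cm: float | None = None,
                     disease_bits: dict | None = None) -> dict[str, np.ndarray]:
    """Gene-drop marker genotypes for one chromosome.  When ``anchor_cm`` is
    given, each meiosis is conditioned on its recorded disease-locus bit."""
    M = len(cm)
    hap: dict[tuple[str, int], np.ndarray] = {}
    for m in members:
        if m.father is None:
            for side in (0, 1):
                # freqs is the frequency of allele 0
                hap[(m.pid, side)] = (rng.random(M) >= freqs).astype(np.int16)
    for m in members:
        if m.father is None:
            continue
        for side, parent in ((0, m.father), (1, m.mother)):
            ab = disease_bits[(m.pid, side)] if anchor_cm is not None else None
            path = _bit_path(cm, rng, anchor_cm, ab)
            pp, pm = hap[(parent, 0)], hap[(parent, 1)]
            hap[(m.pid, side)] = np.where(path == 0, pp, pm).astype(np.int16)
    return {m.pid: np.stack([hap[(m.pid, 0)], hap[(m.pid, 1)]], axis=1)
            for m in members}


# ---------------------------------------------------------------------------
# Map + cohort
# ---------------------------------------------------------------------------

def _make_map(ms: MapSpec, rng: np.random.Generator):
    chrom, marker, cm, bp, gen_freqs = [], [], [], [], []
    for c in range(1, ms.n_chromosomes + 1):
        for j in range(ms.markers_per_chrom):
            chrom.append(str(c))
            marker.append(f"rs{c}_{j + 1}")
            cm.append(round(j * ms.spacing_cm, 6))
            bp.append((j + 1) * ms.bp_spacing)
            maf = float(np.clip(rng.normal(ms.maf_mean, ms.maf_sd),
                                ms.min_maf, 0.5))
            # allele 0 carries the minor frequency half the time
            gen_freqs.append(maf if rng.random() < 0.5 else 1.0 - maf)
    mm = MarkerMap(chrom, marker, cm, bp,
                   alleles=[["1", "2"] for _ in marker])
    return mm, np.array(gen_freqs)


def generate_cohort(spec: CohortSpec, seed: int | np.random.Generator = 0
                    ) -> tuple[Cohort, TruthLedger]:
    """Generate a cohort per spec; deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    mm, gen_freqs = _make_map(spec.map_spec, rng)
    if spec.linked_chrom is not None and spec.linked_pos_cm is None:
        raise ValueError("linked_chrom requires linked_pos_cm")
    families: dict[str, Pedigree] = {}
    batches: dict[str, str] = {}
    linked_truth: dict[str, bool] = {}
    for fi in range(spec.n_families):
        fid = f"F{fi + 1:03d}"
        members = _sample_structure(fid, spec, rng)
        _dgeno, bits = _ascertain_family(members, spec, rng)
        linked = (spec.linked_chrom is not None and
                  rng.random() < spec.linked_fraction)
        linked_truth[fid] = bool(linked)
        genos = {m.pid: np.empty((len(mm), 2), dtype=np.int16) for m in members}
        for c in mm.chromosomes():
            idx = mm.chrom_indices(c)
            anchor = spec.linked_pos_cm if (linked and c == spec.linked_chrom) \
                else None
            drop = _drop_chromosome(members, mm.cm[idx], gen_freqs[idx], rng,
                                    anchor, bits)
            for pid, g in drop.items():
                genos[pid][idx] = g
        for m in members:
            g = genos[m.pid]
            if not m.sampled:
                g[:] = MISSING
            elif spec.missing_rate > 0:
                mask = rng.random(len(mm)) < spec.missing_rate
                g[mask] = MISSING
            batches[f"{fid}:{m.pid}"] = "batch1" if fi % 2 == 0 else "batch2"
        families[fid] = Pedigree(fid, members, genos)
    cohort = Cohort(families, mm, batches)
    locus = (spec.linked_chrom, spec.linked_pos_cm) \
        if spec.linked_chrom is not None else None
    truth = TruthLedger(linked_truth, locus, [float(f) for f in gen_freqs])
    if spec.defects.total():
        cohort, truth = plant_defects(cohort, spec.defects, rng, truth)
    return cohort, truth


# ---------------------------------------------------------------------------
# Planted defects
# ---------------------------------------------------------------------------

def plant_defects(cohort: Cohort, ds: DefectSpec,
                  rng: np.random.Generator, truth: TruthLedger | None = None
                  ) -> tuple[Cohort, TruthLedger]:
    """Inject QC defects into a clean cohort (in place on a copy); the ledger
    lists, per filter, exactly the markers a first-hit cascade should remove."""
    mm = cohort.map
    M = len(mm)
    if ds.total() > M // 2:
        raise ValueError(f"defect quota {ds.total()} too large for {M} markers")
    if truth is None:
        truth = TruthLedger({p.fid: False for p in cohort}, None, [])
    cohort = Cohort({f: p.copy() for f, p in cohort.families.items()},
                    mm, cohort.batches)
    # candidates exclude each chromosome's first marker so that dup targets
    # always have a left neighbour on the same chromosome
    candidates = [j for j in range(M)
                  if j > 0 and mm.chrom[j] == mm.chrom[j - 1]]
    rng.shuffle(candidates)
    used: set[int] = set()

    def next_marker(need_clean_left: bool = False) -> int:
        for j in candidates:
            if j in used:
                continue
            if need_clean_left and (j - 1) in used:
                continue
            used.add(j)
            if need_clean_left:
                used.add(j - 1)   # reserve the neighbour as the kept copy
            return j
        raise ValueError("ran out of defect-candidate markers")

    led: dict[str, list[str]] = {k: [] for k in
                                 ("call_rate", "mendel", "maf", "hwe",
                                  "dup_bp", "missing_cm", "dup_cm")}
    fids = list(cohort.families)

    for _ in range(ds.n_low_call_rate):
        j = next_marker()
        for ped in cohort:
            for pid, g in ped.genotypes.items():
                if ped.members[pid].sampled and rng.random() > ds.call_rate_target:
                    g[j] = MISSING
        led["call_rate"].append(mm.marker[j])

    for _ in range(ds.n_mendel):
        j = next_marker()
        chosen = rng.choice(len(fids), size=ds.mendel_n_families, replace=False)
        for ci in chosen:
            ped = cohort.families[fids[ci]]
            child = next(m for m in ped.nonfounders() if m.sampled)
            ped.genotypes[child.father][j] = 0
            ped.genotypes[child.mother][j] = 0
            ped.genotypes[child.pid][j] = 1
            truth.mendel_families.setdefault(mm.marker[j], []).append(ped.fid)
        led["mendel"].append(mm.marker[j])

    for _ in range(ds.n_low_maf):
        j = next_marker()
        for ped in cohort:
            # fresh single-marker gene drop with allele 1 rare
            redo = {}
            for m in ped.topological():
                if m.father is None:
                    redo[m.pid] = (int(rng.random() < ds.low_maf),
                                   int(rng.random() < ds.low_maf))
                else:
                    redo[m.pid] = (redo[m.father][rng.integers(2)],
                                   redo[m.mother][rng.integers(2)])
            for m in ped.members.values():
                g = ped.genotypes[m.pid]
                if np.all(g[j] != MISSING):
                    g[j] = redo[m.pid]
        led["maf"].append(mm.marker[j])

    for _ in range(ds.n_hwe):
        j = next_marker()
        for ped in cohort:
            for m in ped.founders():
                if m.affection == UNAFFECTED and m.sampled:
                    ped.genotypes[m.pid][j] = (0, 1)
        led["hwe"].append(mm.marker[j])

    for _ in range(ds.n_dup_bp):
        j = next_marker(need_clean_left=True)
        mm.bp[j] = mm.bp[j - 1]
        led["dup_bp"].append(mm.marker[j])

    for _ in range(ds.n_missing_cm):
        j = next_marker()
        mm.cm[j] = math.nan
        led["missing_cm"].append(mm.marker[j])

    for _ in range(ds.n_dup_cm):
        j = next_marker(need_clean_left=True)
        mm.cm[j] = round(mm.cm[j - 1], 2) + 0.004
        led["dup_cm"].append(mm.marker[j])

    truth.defects = {k: sorted(v) for k, v in led.items() if v}
    return cohort, truth


# ---------------------------------------------------------------------------
# Heterogeneity cohorts
# ---------------------------------------------------------------------------

def generate_heterogeneity_cohort(spec: CohortSpec,
                                  n_positive: int = 34, n_negative: int = 32,
                                  positive_linked: bool = False,
                                  negative_linked: bool = True,
                                  seed: int | np.random.Generator = 0):
    """Cohort where (by default) only the negative stratum is linked at the
    spec's locus.  Returns ``(cohort, flags, truth)`` where ``flags`` is the
    per-family clinical-condition table consumed by stratification."""
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    if spec.linked_chrom is None:
        raise ValueError("heterogeneity cohort requires a linked locus in spec")
    spec_all = dataclasses.replace(spec, n_families=n_positive + n_negative,
                                   linked_fraction=0.0)
    cohort, truth = generate_cohort(spec_all, rng)
    fids = list(cohort.families)
    pos_fids = set(fids[:n_positive])
    # regenerate each family's linkage according to its stratum
    spec_linked = dataclasses.replace(spec, linked_fraction=1.0)
    rows = []
    for fid in fids:
        stratum = "CTD-positive" if fid in pos_fids else "CTD-negative"
        linked = positive_linked if fid in pos_fids else negative_linked
        truth.strata[fid] = stratum
        cohort.families[fid].stratum = stratum
        truth.linked[fid] = linked
        if linked:
            one = dataclasses.replace(spec_linked, n_families=1)
            sub, _ = _regenerate_family(cohort.families[fid], one,
                                        cohort.map, truth, rng)
            cohort.families[fid] = sub
            cohort.families[fid].stratum = stratum
        flags = {c: False for c in CTD_CONDITIONS}
        if stratum == "CTD-positive":
            k = 1 + int(rng.integers(0, 2))
            for c in rng.choice(len(CTD_CONDITIONS), size=k, replace=False):
                flags[CTD_CONDITIONS[c]] = True
        rows.append({"family": fid, **flags})
    flags_df = pd.DataFrame(rows).set_index("family")
    return cohort, flags_df, truth


def _regenerate_family(ped: Pedigree, spec: CohortSpec, mm: MarkerMap,
                       truth: TruthLedger, rng: np.random.Generator):
    """Redraw one family's phenotypes and genotypes with a linked locus,
    keeping its structure."""
    members = [dataclasses.replace(m) for m in ped.members.values()]
    dgeno, bits = _ascertain_family(members, spec, rng)
    gen_freqs = np.array(truth.marker_freqs)
    genos = {m.pid: np.empty((len(mm), 2), dtype=np.int16) for m in members}
    for c in mm.chromosomes():
        idx = mm.chrom_indices(c)
        anchor = spec.linked_pos_cm if c == spec.linked_chrom else None
        drop = _drop_chromosome(members, mm.cm[idx], gen_freqs[idx], rng,
                                anchor, bits)
        for pid, g in drop.items():
            genos[pid][idx] = g
    for m in members:
        if not m.sampled:
            genos[m.pid][:] = MISSING
        elif spec.missing_rate > 0:
            mask = rng.random(len(mm)) < spec.missing_rate
            genos[m.pid][mask] = MISSING
    return Pedigree(ped.fid, members, genos, ped.stratum), truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def emit_files(cohort: Cohort, truth: TruthLedger, outdir,
               flags: pd.DataFrame | None = None) -> dict[str, str]:
    """Write PED/MAP/batches/truth (and clinical flags) as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"ped": str(outdir / "cohort.ped"), "map": str(outdir / "cohort.map"),
             "batches": str(outdir / "batches.tsv"),
             "truth": str(outdir / "truth.json")}
    write_pedfile(cohort, paths["ped"])
    write_mapfile(cohort.map, paths["map"])
    with open(paths["batches"], "w") as fh:
        fh.write("family\tperson\tbatch\n")
        for key, b in cohort.batches.items():
            fid, pid = key.split(":", 1)
            fh.write(f"{fid}\t{pid}\t{b}\n")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    if flags is not None:
        paths["flags"] = str(outdir / "clinical_flags.tsv")
        flags.to_csv(paths["flags"], sep="\t")
    return paths
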