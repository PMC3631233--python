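"""Pedigree and marker-map data model, PED/MAP I/O, validation and map arithmetic.

Conventions follow the whitespace-delimited LINKAGE/PLINK PED dialect:
six leading columns (FID, IID, PAT, MAT, SEX, PHENO) followed by one
allele pair per marker.  Phenotype codes are mapped 1 -> unaffected,
2 -> affected, 0/-9 -> uncertain.  Missing alleles use a configurable
code (default ``"0"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)

MALE, FEMALE, UNKNOWN_SEX = 1, 2, 0
UNCERTAIN, UNAFFECTED, AFFECTED = 0, 1, 2

_PHENO_CODES = {"1": UNAFFECTED, "2": AFFECTED, "0": UNCERTAIN, "-9": UNCERTAIN}
_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN_SEX}

MISSING = -1  # internal allele-index code for a missing allele


class PedigreeError(ValueError):
    """Raised on malformed or inconsistent pedigree input."""


@dataclass
class Individual:
    pid: str
    fid: str
    father: str | None
    mother: str | None
    sex: int
    affection: int
    sampled: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father is None

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(
                f"half-specified parents for {self.fid}:{self.pid} "
                "(father and mother must both be present or both absent)"
            )


class Pedigree:
    """One family: members, per-member genotypes and an optional stratum label.

    Genotypes are stored per member as an ``(n_markers, 2)`` int16 array of
    allele indices into the marker map's allele lists; ``-1`` marks a
    missing allele.
    """

    def __init__(self, fid: str, members: list[Individual],
                 genotypes: dict[str, np.ndarray] | None = None,
                 stratum: str | None = None):
        self.fid = fid
        self.members: dict[str, Individual] = {m.pid: m for m in members}
        if len(self.members) != len(members):
            raise PedigreeError(f"duplicate person id in family {fid}")
        self.genotypes: dict[str, np.ndarray] = genotypes or {}
        self.stratum = stratum

    # -- structure ---------------------------------------------------------

    def founders(self) -> list[Individual]:
        return [m for m in self.members.values() if m.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members.values() if not m.is_founder]

    @property
    def bits(self) -> int:
        """Meiosis count 2*nonfounders - founders (inheritance-vector size)."""
        return 2 * len(self.nonfounders()) - len(self.founders())

    @property
    def n_meioses(self) -> int:
        return 2 * len(self.nonfounders())

    def affected(self) -> list[Individual]:
        return [m for m in self.members.values() if m.affection == AFFECTED]

    def children_of(self, pid: str) -> list[Individual]:
        return [m for m in self.members.values()
                if pid in (m.father, m.mother)]

    def topological(self) -> list[Individual]:
        """Members ordered with parents before children."""
        order, seen = [], set()

        def visit(pid: str) -> None:
            if pid in seen:
                return
            ind = self.members[pid]
            if not ind.is_founder:
                visit(ind.father)
                visit(ind.mother)
            seen.add(pid)
            order.append(ind)

        for pid in self.members:
            visit(pid)
        return order

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        g = nx.DiGraph()
        for m in self.members.values():
            g.add_node(m.pid)
            if m.is_founder:
                continue
            for par, want_sex in ((m.father, MALE), (m.mother, FEMALE)):
                if par not in self.members:
                    raise PedigreeError(
                        f"family {self.fid}: {m.pid} references missing parent {par}")
                psex = self.members[par].sex
                if psex not in (want_sex, UNKNOWN_SEX):
                    raise PedigreeError(
                        f"family {self.fid}: parent {par} has sex inconsistent "
                        f"with parental role for child {m.pid}")
                g.add_edge(par, m.pid)
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError(f"family {self.fid}: parent graph has a cycle")
        if self._has_loop():
            raise PedigreeError(
                f"family {self.fid}: pedigree contains a loop "
                "(consanguinity/marriage loop); looped pedigrees are not supported")

    def _has_loop(self) -> bool:
        # Marriage-node graph: spouse -- union -- child edges; a loop-free
        # pedigree yields a forest.
        g = nx.Graph()
        for m in self.nonfounders():
            union = ("U", m.father, m.mother)
            g.add_edge(("I", m.father), union)
            g.add_edge(("I", m.mother), union)
            g.add_edge(union, ("I", m.pid))
        return len(g) > 0 and len(g.edges) > len(g) - nx.number_connected_components(g)

    # -- genotype helpers --------------------------------------------------

    def genotype(self, pid: str, j: int) -> tuple[int, int]:
        arr = self.genotypes.get(pid)
        if arr is None:
            return (MISSING, MISSING)
        return (int(arr[j, 0]), int(arr[j, 1]))

    def subset_markers(self, idx: np.ndarray) -> "Pedigree":
        geno = {pid: arr[idx].copy() for pid, arr in self.genotypes.items()}
        p = Pedigree(self.fid, [replace(m) for m in self.members.values()],
                     geno, self.stratum)
        return p

    def copy(self) -> "Pedigree":
        return Pedigree(self.fid, [replace(m) for m in self.members.values()],
                        {pid: a.copy() for pid, a in self.genotypes.items()},
                        self.stratum)

    def __repr__(self) -> str:
        return f"<Pedigree {self.fid}: {len(self.members)} members, bits={self.bits}>"


def trim_pedigree(ped: Pedigree) -> Pedigree:
    """Drop uninformative leaves: unsampled, not-affected individuals who are
    nobody's parent.  Iterates to a fixed point; linkage likelihoods are
    unchanged because removed members carry neither genotype nor phenotype
    information."""
    p = ped.copy()
    while True:
        parents = {m.father for m in p.members.values() if m.father} | \
                  {m.mother for m in p.members.values() if m.mother}
        drop = [m.pid for m in p.members.values()
                if m.pid not in parents and not m.sampled
                and m.affection != AFFECTED]
        if not drop:
            return p
        for pid in drop:
            del p.members[pid]
            p.genotypes.pop(pid, None)


@dataclass
class DiseaseModel:
    """Disease-allele frequency plus penetrances (f0, f1, f2) for 0/1/2 copies."""
    allele_freq: float
    penetrances: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError("disease allele frequency must be in (0,1)")
        if any(not 0.0 <= f <= 1.0 for f in self.penetrances):
            raise ValueError("penetrances must be in [0,1]")


#: Affecteds-only rare dominant model used throughout the analyses.
AFFECTEDS_ONLY_MODEL = DiseaseModel(0.001, (0.0, 0.001, 0.001))


class MarkerMap:
    """Ordered marker map: chromosome, id, genetic (cM) and physical (bp)
    position, plus per-marker allele labels and founder-estimated frequencies."""

    def __init__(self, chrom: list[str], marker: list[str], cm: list[float],
                 bp: list[int], alleles: list[list[str]] | None = None,
                 freqs: list[np.ndarray | None] | None = None):
        n = len(marker)
        if len(set(marker)) != n:
            dup = sorted({m for m in marker if marker.count(m) > 1})
            raise PedigreeError(f"duplicate marker ids in map: {dup[:5]}")
        self.chrom = list(chrom)
        self.marker = list(marker)
        self.cm = np.asarray(cm, dtype=float)
        self.bp = np.asarray(bp, dtype=np.int64)
        self.alleles = alleles if alleles is not None else [["1", "2"] for _ in range(n)]
        self.freqs = freqs if freqs is not None else [None] * n
        self._index = {m: i for i, m in enumerate(self.marker)}

    def __len__(self) -> int:
        return len(self.marker)

    def index(self, marker_id: str) -> int:
        return self._index[marker_id]

    @property
    def missing_cm(self) -> np.ndarray:
        return np.isnan(self.cm)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c)
        return list(seen)

    def chrom_indices(self, chromosome: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.chrom) if c == chromosome],
                        dtype=int)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx, dtype=int)
        return MarkerMap([self.chrom[i] for i in idx],
                         [self.marker[i] for i in idx],
                         self.cm[idx], self.bp[idx],
                         [self.alleles[i] for i in idx],
                         [self.freqs[i] for i in idx])

    def sorted(self) -> "MarkerMap":
        key = sorted(range(len(self)),
                     key=lambda i: (self.chrom[i],
                                    math.inf if np.isnan(self.cm[i]) else self.cm[i],
                                    self.bp[i]))
        return self.subset(np.array(key, dtype=int))

    def spacings(self, chromosome: str) -> np.ndarray:
        idx = self.chrom_indices(chromosome)
        return np.diff(self.cm[idx])

    def maf(self, i: int) -> float:
        f = self.freqs[i]
        if f is None:
            return math.nan
        return float(min(f)) if len(f) == 2 else float(1.0 - max(f))

    def validate(self) -> None:
        for c in self.chromosomes():
            idx = self.chrom_indices(c)
            cm = self.cm[idx]
            ok = cm[~np.isnan(cm)]
            if np.any(np.diff(ok) < 0):
                raise PedigreeError(f"chromosome {c}: genetic positions not sorted")
        for i, f in enumerate(self.freqs):
            if f is not None and abs(float(np.sum(f)) - 1.0) > 1e-12:
                raise PedigreeError(
                    f"marker {self.marker[i]}: allele frequencies do not sum to 1")


class Cohort:
    """A set of families sharing one marker map (and optional batch labels)."""

    def __init__(self, families: dict[str, Pedigree], marker_map: MarkerMap,
                 batches: dict[str, str] | None = None):
        self.families = families
        self.map = marker_map
        self.batches = batches or {}

    def __iter__(self):
        return iter(self.families.values())

    def __len__(self) -> int:
        return len(self.families)

    def subset_families(self, fids) -> "Cohort":
        return Cohort({f: self.families[f] for f in fids}, self.map, self.batches)

    def subset_markers(self, idx: np.ndarray) -> "Cohort":
        fams = {f: p.subset_markers(idx) for f, p in self.families.items()}
        return Cohort(fams, self.map.subset(idx), self.batches)

    def batch_of(self, ped: Pedigree, pid: str) -> str:
        return self.batches.get(f"{ped.fid}:{pid}", "batch1")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pedfile(path, marker_map: MarkerMap | None = None,
                 missing_code: str = "0") -> Cohort:
    """Read a whitespace-delimited PED file into a :class:`Cohort`.

    When ``marker_map`` is given its allele lists are used (and extended in
    place if novel alleles appear); otherwise a two-allele placeholder map
    with ids ``m1..mM`` is created.
    """
    rows: list[tuple[str, str, str, str, str, str, list[str]]] = []
    n_alleles = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6 or (len(parts) - 6) % 2:
                raise PedigreeError(
                    f"{path}:{lineno}: malformed PED line "
                    f"({len(parts)} columns; need 6 + 2*n_markers)")
            if n_alleles is None:
                n_alleles = len(parts) - 6
            elif len(parts) - 6 != n_alleles:
                raise PedigreeError(
                    f"{path}:{lineno}: inconsistent marker count "
                    f"({(len(parts) - 6) // 2} vs {n_alleles // 2})")
            rows.append((parts[0], parts[1], parts[2], parts[3], parts[4],
                         parts[5], parts[6:]))
    n_markers = (n_alleles or 0) // 2
    if marker_map is None:
        marker_map = MarkerMap(["1"] * n_markers,
                               [f"m{i + 1}" for i in range(n_markers)],
                               [float(i) for i in range(n_markers)],
                               list(range(1, n_markers + 1)),
                               alleles=[[] for _ in range(n_markers)])
    elif len(marker_map) != n_markers:
        raise PedigreeError(
            f"{path}: {n_markers} markers in PED but map has {len(marker_map)}")

    allele_index = [{a: k for k, a in enumerate(marker_map.alleles[j])}
                    for j in range(n_markers)]

    def code(j: int, a: str) -> int:
        if a == missing_code:
            return MISSING
        k = allele_index[j].get(a)
        if k is None:
            k = len(marker_map.alleles[j])
            marker_map.alleles[j].append(a)
            allele_index[j][a] = k
        return k

    families: dict[str, Pedigree] = {}
    fam_rows: dict[str, list] = {}
    for r in rows:
        fam_rows.setdefault(r[0], []).append(r)
    for fid, rws in fam_rows.items():
        members, genos = [], {}
        for (_, iid, pat, mat, sex, pheno, alleles) in rws:
            father = None if pat == "0" else pat
            mother = None if mat == "0" else mat
            if sex not in _SEX_CODES:
                raise PedigreeError(f"family {fid}, person {iid}: bad sex code {sex!r}")
            aff = _PHENO_CODES.get(pheno)
            if aff is None:
                raise PedigreeError(
                    f"family {fid}, person {iid}: bad phenotype code {pheno!r}")
            g = np.empty((n_markers, 2), dtype=np.int16)
            for j in range(n_markers):
                g[j, 0] = code(j, alleles[2 * j])
                g[j, 1] = code(j, alleles[2 * j + 1])
            sampled = bool(np.any(g != MISSING)) if n_markers else False
            members.append(Individual(iid, fid, father, mother,
                                      _SEX_CODES[sex], aff, sampled))
            genos[iid] = g
        ped = Pedigree(fid, members, genos)
        ped.validate()
        families[fid] = ped
    log.info("read %d families, %d individuals, %d markers from %s",
             len(families), len(rows), n_markers, path)
    return Cohort(families, marker_map)


def write_pedfile(cohort: Cohort, path, missing_code: str = "0") -> None:
    sex_out = {MALE: "1", FEMALE: "2", UNKNOWN_SEX: "0"}
    aff_out = {AFFECTED: "2", UNAFFECTED: "1", UNCERTAIN: "0"}
    with open(path, "w") as fh:
        for ped in cohort:
            for m in ped.members.values():
                cols = [ped.fid, m.pid, m.father or "0", m.mother or "0",
                        sex_out[m.sex], aff_out[m.affection]]
                g = ped.genotypes.get(m.pid)
                for j in range(len(cohort.map)):
                    for k in (0, 1):
                        a = MISSING if g is None else int(g[j, k])
                        cols.append(missing_code if a == MISSING
                                    else cohort.map.alleles[j][a])
                fh.write(" ".join(cols) + "\n")


def read_mapfile(path) -> MarkerMap:
    """Read a map file with columns chromosome, id, cM, bp.

    Empty/NA cM fields are kept as NaN and flagged (feeds the missing-genetic-
    distance QC filter).  The map is sorted by (chromosome, cM); if that
    disagrees with bp order a warning is logged.
    """
    chrom, marker, cm, bp = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].lower() in ("chrom", "chromosome", "chr"):
                continue
            if len(parts) < 4:
                raise PedigreeError(f"{path}:{lineno}: need 4 columns (chrom id cM bp)")
            chrom.append(parts[0])
            marker.append(parts[1])
            cm.append(math.nan if parts[2] in (".", "NA", "nan", "") else float(parts[2]))
            bp.append(int(parts[3]))
    mm = MarkerMap(chrom, marker, cm, bp)
    by_bp = sorted(range(len(mm)), key=lambda i: (mm.chrom[i], mm.bp[i]))
    srt = mm.sorted()
    if [mm.marker[i] for i in by_bp] != srt.marker:
        log.warning("%s: cM order disagrees with bp order; re-sorted by cM", path)
    n_missing = int(srt.missing_cm.sum())
    if n_missing:
        log.info("%s: %d markers flagged with missing genetic distance", path, n_missing)
    return srt


def write_mapfile(mm: MarkerMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tmarker\tcm\tbp\n")
        for i in range(len(mm)):
            cmv = "NA" if np.isnan(mm.cm[i]) else f"{mm.cm[i]:.6f}"
            fh.write(f"{mm.chrom[i]}\t{mm.marker[i]}\t{cmv}\t{mm.bp[i]}\n")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def estimate_allele_freqs(cohort: Cohort, who: str = "founders") -> MarkerMap:
    """Counting estimate of allele frequencies from founder genotypes.

    ``who`` is ``"founders"`` or ``"unaffected_founders"``.  Frequencies are
    written into the cohort's map in place (and returned).  Markers with zero
    observations keep ``freqs=None`` and are logged.
    """
    if who not in ("founders", "unaffected_founders"):
        raise ValueError(f"unknown selection class {who!r}")
    mm = cohort.map
    n_markers = len(mm)
    counts = [np.zeros(max(len(mm.alleles[j]), 1), dtype=float)
              for j in range(n_markers)]
    any_selected = False
    for ped in cohort:
        for ind in ped.founders():
            if who == "unaffected_founders" and ind.affection != UNAFFECTED:
                continue
            g = ped.genotypes.get(ind.pid)
            if g is None:
                continue
            any_selected = True
            for j in range(n_markers):
                for k in (0, 1):
                    a = int(g[j, k])
                    if a >= 0:
                        counts[j][a] += 1.0
    if not any_selected:
        raise PedigreeError(f"no genotyped individuals in class {who!r}")
    empty = []
    for j in range(n_markers):
        tot = counts[j].sum()
        if tot == 0:
            mm.freqs[j] = None
            empty.append(mm.marker[j])
        else:
            mm.freqs[j] = counts[j] / tot
    if empty:
        log.info("allele frequencies undefined (no observations) for %d markers", len(empty))
    return mm


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------

def cm_to_theta(d_cm, map_function: str = "haldane"):
    """Genetic distance (cM) to recombination fraction."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative genetic distance")
    m = d / 100.0
    if map_function == "haldane":
        theta = 0.5 * (1.0 - np.exp(-2.0 * m))
    elif map_function == "kosambi":
        theta = 0.5 * np.tanh(2.0 * m)
    else:
        raise ValueError(f"unknown map function {map_function!r}")
    return float(theta) if np.isscalar(d_cm) else theta


def theta_to_cm(theta, map_function: str = "haldane"):
    t = np.asarray(theta, dtype=float)
    if np.any((t < 0) | (t >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    if map_function == "haldane":
        d = -50.0 * np.log(1.0 - 2.0 * t)
    elif map_function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * t) / (1.0 - 2.0 * t))
    else:
        raise ValueError(f"unknown map function {map_function!r}")
    return float(d) if np.isscalar(theta) else d
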