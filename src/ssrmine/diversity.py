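"""Codominant-marker diversity statistics and population-structure summaries.

Covers per-locus allele counts, major allele frequency, expected and
observed heterozygosity, polymorphism information content, pairwise
genetic distances (Nei 1972 standard distance and shared-allele
dissimilarity), neighbor-joining trees, principal coordinates analysis
and the Mantel permutation test. Missing genotypes are dropped per locus
for the statistics and pairwise for the distances; He carries no
small-sample correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

Genotype = tuple[object, object]  # unordered allele pair; labels are opaque

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# Genotype matrix

class GenotypeMatrix:
    """Individuals x loci table of unordered allele pairs.

    Allele labels are opaque (bp sizes or repeat counts). ``None`` marks a
    missing genotype. Optional per-individual group tags and geographic
    coordinates ride along for grouped statistics and the Mantel test.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[str],
        genotypes: dict[tuple[str, str], Genotype | None],
        groups: dict[str, str] | None = None,
        coordinates: dict[str, tuple[float, float]] | None = None,
    ):
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual names")
        if len(set(loci)) != len(loci):
            raise ValueError("duplicate locus names")
        self.individuals = list(individuals)
        self.loci = list(loci)
        self._geno = dict(genotypes)
        self.groups = dict(groups or {})
        self.coordinates = dict(coordinates or {})

    def genotype(self, individual: str, locus: str) -> Genotype | None:
        return self._geno.get((individual, locus))

    def subset_by_group(self, group: str) -> list[str]:
        return [i for i in self.individuals if self.groups.get(i) == group]

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            loci = [h[:-2] for h in header[2::2]]
            individuals, genotypes, groups = [], {}, {}
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                ind, group = fields[0], fields[1]
                individuals.append(ind)
                if group != ".":
                    groups[ind] = group
                for k, locus in enumerate(loci):
                    a1, a2 = fields[2 + 2 * k], fields[3 + 2 * k]
                    genotypes[(ind, locus)] = (
                        None if a1 == "." or a2 == "." else (int(a1), int(a2))
                    )
        return cls(individuals, loci, genotypes, groups)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            cols = [f"{l}_{i}" for l in self.loci for i in (1, 2)]
            fh.write("individual\tgroup\t" + "\t".join(cols) + "\n")
            for ind in self.individuals:
                cells = []
                for locus in self.loci:
                    g = self.genotype(ind, locus)
                    cells += ([".", "."] if g is None else [str(g[0]), str(g[1])])
                fh.write(f"{ind}\t{self.groups.get(ind, '.')}\t"
                         + "\t".join(cells) + "\n")

    def to_structure(self, path: str | Path) -> None:
        """Two-row-per-individual input for external admixture programs.

        Alleles are written as integer codes, missing as -9.
        """
        group_codes = {g: i + 1 for i, g in enumerate(sorted(set(self.groups.values())))}
        with open(path, "w") as fh:
            fh.write("\t".join(["", ""] + self.loci) + "\n")
            for ind in self.individuals:
                code = group_codes.get(self.groups.get(ind), 0)
                for slot in (0, 1):
                    cells = []
                    for locus in self.loci:
                        g = self.genotype(ind, locus)
                        cells.append("-9" if g is None else str(g[slot]))
                    fh.write(f"{ind}\t{code}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Per-locus statistics

@dataclass(frozen=True)
class LocusStats:
    na: int
    maf: float
    he: float
    ho: float
    pic: float
    n_genotyped: int


def allele_frequencies(
    matrix: GenotypeMatrix, locus: str, subset: Sequence[str] | None = None
) -> dict[object, float]:
    individuals = subset if subset is not None else matrix.individuals
    counts: dict[object, int] = {}
    total = 0
    for ind in individuals:
        g = matrix.genotype(ind, locus)
        if g is None:
            continue
        for a in g:
            counts[a] = counts.get(a, 0) + 1
            total += 1
    if total == 0:
        raise ValueError(f"locus {locus!r}: no genotyped individuals in subset")
    return {a: c / total for a, c in counts.items()}


def he_from_freqs(freqs: Iterable[float]) -> float:
    """Gene diversity 1 - sum(p_i^2), uncorrected."""
    return 1.0 - sum(p * p for p in freqs)


def pic_from_freqs(freqs: Iterable[float]) -> float:
    """Botstein polymorphism information content."""
    p = list(freqs)
    s2 = sum(x * x for x in p)
    s4 = sum(x ** 4 for x in p)
    return 1.0 - s2 - (s2 * s2 - s4)


def locus_stats(
    matrix: GenotypeMatrix, locus: str, subset: Sequence[str] | None = None
) -> LocusStats:
    individuals = subset if subset is not None else matrix.individuals
    freqs = allele_frequencies(matrix, locus, individuals)
    het = tot = 0
    for ind in individuals:
        g = matrix.genotype(ind, locus)
        if g is None:
            continue
        tot += 1
        if g[0] != g[1]:
            het += 1
    p = list(freqs.values())
    return LocusStats(
        na=len(p),
        maf=max(p),
        he=he_from_freqs(p),
        ho=het / tot,
        pic=pic_from_freqs(p),
        n_genotyped=tot,
    )


def individual_heterozygosity(matrix: GenotypeMatrix, individual: str) -> float:
    """Percent of genotyped loci at which the individual is heterozygous."""
    het = tot = 0
    for locus in matrix.loci:
        g = matrix.genotype(individual, locus)
        if g is None:
            continue
        tot += 1
        if g[0] != g[1]:
            het += 1
    if tot == 0:
        raise ValueError(f"{individual!r}: no genotyped loci")
    return 100.0 * het / tot


# ---------------------------------------------------------------------------
# Distance matrices

@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal
    measure: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        self.values = v

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("," + ",".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                fh.write(name + ","
                         + ",".join(f"{x:.6f}" for x in self.values[i]) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, measure: str = "") -> "DistanceMatrix":
        with open(path) as fh:
            ids = fh.readline().rstrip("\n").split(",")[1:]
            rows = [list(map(float, line.rstrip("\n").split(",")[1:])) for line in fh]
        return cls(ids=ids, values=np.array(rows), measure=measure)


def _indiv_freq_vector(g: Genotype) -> dict[object, float]:
    if g[0] == g[1]:
        return {g[0]: 1.0}
    return {g[0]: 0.5, g[1]: 0.5}


def genetic_distance(matrix: GenotypeMatrix, measure: str = "shared_allele") -> DistanceMatrix:
    """Pairwise individual distances with pairwise deletion of missing loci.

    ``nei1972``: D = -ln(Jxy / sqrt(Jx * Jy)) where J terms are means over
    co-genotyped loci of allele-frequency dot products (per-individual
    frequencies are 0, 0.5 or 1).
    ``shared_allele``: d = 1 - mean_l(shared alleles / 2).
    """
    if measure not in ("nei1972", "shared_allele"):
        raise ValueError(f"unknown measure {measure!r}")
    inds = matrix.individuals
    n = len(inds)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared_loci = [
                l for l in matrix.loci
                if matrix.genotype(inds[i], l) is not None
                and matrix.genotype(inds[j], l) is not None
            ]
            if not shared_loci:
                out[i, j] = out[j, i] = np.nan
                continue
            if measure == "shared_allele":
                acc = 0.0
                for l in shared_loci:
                    gx = matrix.genotype(inds[i], l)
                    gy = matrix.genotype(inds[j], l)
                    shared = sum(
                        min(gx.count(a), gy.count(a)) for a in set(gx)
                    )
                    acc += shared / 2.0
                d = 1.0 - acc / len(shared_loci)
            else:
                jxy = jx = jy = 0.0
                for l in shared_loci:
                    fx = _indiv_freq_vector(matrix.genotype(inds[i], l))
                    fy = _indiv_freq_vector(matrix.genotype(inds[j], l))
                    jxy += sum(fx[a] * fy.get(a, 0.0) for a in fx)
                    jx += sum(p * p for p in fx.values())
                    jy += sum(p * p for p in fy.values())
                L = len(shared_loci)
                ratio = (jxy / L) / math.sqrt((jx / L) * (jy / L))
                d = -math.log(ratio) if ratio < 1.0 else 0.0
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids=list(inds), values=out, measure=measure)


def haversine_distance(coords: dict[str, tuple[float, float]],
                       ids: Sequence[str]) -> DistanceMatrix:
    """Great-circle distances (km) from decimal-degree (lat, lon) pairs."""
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        lat1, lon1 = (math.radians(x) for x in coords[ids[i]])
        for j in range(i + 1, n):
            lat2, lon2 = (math.radians(x) for x in coords[ids[j]])
            a = (math.sin((lat2 - lat1) / 2) ** 2
                 + math.cos(lat1) * math.cos(lat2)
                 * math.sin((lon2 - lon1) / 2) ** 2)
            d = 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids=list(ids), values=out, measure="haversine_km")


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(d: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Pair choice minimizes Q(i,j) = (n-2) d(i,j) - r_i - r_j with ties
    broken by the smallest (i,j) index pair in the current node list.
    The last three nodes are joined at a single internal node whose three
    branch lengths solve the three pairwise equations exactly.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains missing entries")
    labels = [_quote_newick(x) for x in d.ids]
    dist = d.values.copy()
    active = list(range(n))
    subtrees = {i: labels[i] for i in range(n)}

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = dist[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dist[i, j] - li
        new = dist.shape[0]
        row = np.zeros((1, new))
        for k in active:
            if k in (i, j):
                continue
            row[0, k] = (dist[i, k] + dist[j, k] - dist[i, j]) / 2.0
        dist = np.vstack([dist, row[:, :new]])
        col = np.append(row[0], 0.0).reshape(-1, 1)
        dist = np.hstack([dist, col])
        subtrees[new] = f"({subtrees[i]}:{_fmt(li)},{subtrees[j]}:{_fmt(lj)})"
        active = [k for k in active if k not in (i, j)] + [new]

    a, b, c = active
    la = (dist[a, b] + dist[a, c] - dist[b, c]) / 2.0
    lb = (dist[a, b] + dist[b, c] - dist[a, c]) / 2.0
    lc = (dist[a, c] + dist[b, c] - dist[a, b]) / 2.0
    return (f"({subtrees[a]}:{_fmt(la)},{subtrees[b]}:{_fmt(lb)},"
            f"{subtrees[c]}:{_fmt(lc)});")


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def _quote_newick(label: str) -> str:
    if any(ch in label for ch in "(),:;[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Principal coordinates

@dataclass
class PCoAResult:
    ids: list[str]
    coordinates: np.ndarray     # individuals x positive axes
    eigenvalues: np.ndarray     # all eigenvalues, descending
    percent_variance: np.ndarray  # per positive axis

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            k = self.coordinates.shape[1]
            fh.write("individual\t" + "\t".join(f"axis{j+1}" for j in range(k)) + "\n")
            for i, name in enumerate(self.ids):
                fh.write(name + "\t"
                         + "\t".join(f"{x:.6f}" for x in self.coordinates[i]) + "\n")
            fh.write("#percent_variance\t"
                     + "\t".join(f"{x:.4f}" for x in self.percent_variance) + "\n")


def pcoa(d: DistanceMatrix) -> PCoAResult:
    """Classical metric scaling via Gower double centering.

    Negative eigenvalues are retained in the report but excluded from the
    percent-variance denominator and yield no coordinate axes. Axis signs
    are fixed so each axis's largest-magnitude loading is positive.
    """
    D = d.values
    if np.isnan(D).any():
        raise ValueError("distance matrix contains missing entries")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    for j in range(coords.shape[1]):
        k = int(np.argmax(np.abs(coords[:, j])))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigval[pos].sum()
    pct = 100.0 * eigval[pos] / pos_sum if pos_sum > 0 else eigval[pos]
    return PCoAResult(ids=list(d.ids), coordinates=coords,
                      eigenvalues=eigval, percent_variance=pct)


# ---------------------------------------------------------------------------
# Mantel test

@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None) -> MantelResult:
    """One-sided (greater) Mantel permutation test.

    p = (number of permuted r >= observed r, + 1) / (n_perm + 1); rows and
    columns of d2 are permuted jointly under a seeded generator.
    """
    if d1.ids != d2.ids:
        raise ValueError("matrices must index the same individuals in order")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = d1.condensed()
    n = len(d1.ids)
    if np.isnan(x).any() or np.isnan(d2.values).any():
        raise ValueError("missing entries not supported in mantel")
    if np.std(x) == 0 or np.std(d2.condensed()) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    iu = np.triu_indices(n, k=1)

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(d2.values)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(d2.values[np.ix_(perm, perm)]) >= r_obs:
            hits += 1
    return MantelResult(r=r_obs, p=(hits + 1) / (n_perm + 1), n_permutations=n_perm)
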