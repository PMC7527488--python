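"""Ground-truthed synthetic GBS data for end-to-end pipeline testing.

A small linear genome is assembled from per-locus units, each anchored at
a GCWGC cut site so the in-silico digest exposes the planted SSR tract at
a fixed position inside the read frame. Accession genotypes are drawn
from configured allele frequencies under a per-group inbreeding
coefficient, and error-bearing single-end reads (barcode + remnant +
fragment prefix) are emitted from the forward end of every fragment.
Substitution errors only; every read is traceable to its fragment through
the truth manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import iupac_find_all, revcomp
from .preprocess import GBSRead, BarcodeMap
from .ssr_detect import SSRThresholds, find_perfect_ssrs, is_primitive

ENZYME_SITE = "GCWGC"  # cut G^CWGC
REMNANTS = ("CAGC", "CTGC")


@dataclass(frozen=True)
class LocusSpec:
    """One planted SSR locus: motif and allele (repeat count) frequencies."""

    motif: str
    allele_freqs: dict[int, float]

    def __post_init__(self):
        if not is_primitive(self.motif):
            raise ValueError(f"motif {self.motif!r} is not primitive")
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")

    @property
    def polymorphic(self) -> bool:
        return len(self.allele_freqs) > 1


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_accessions: int
    inbreeding: float  # F in [0, 1]

    def __post_init__(self):
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding coefficient must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    loci: tuple[LocusSpec, ...]
    groups: tuple[GroupSpec, ...]
    seed: int
    read_length: int = 100
    depth: int = 15            # target reads per locus (split over haplotypes)
    error_rate: float = 0.001
    gc_fraction: float = 0.45
    left_flank_len: int = 26   # bases between remnant and tract
    right_fill_len: int = 70   # bases after the tract inside the fragment
    spacer_len: int = 30
    barcode_len: int = 6

    @property
    def n_accessions(self) -> int:
        return sum(g.n_accessions for g in self.groups)


@dataclass
class TruthLocus:
    locus_id: int
    motif: str
    alleles: list[int]                   # configured repeat counts
    read_left_flank: str                 # remnant + left flank, read frame
    right_flank: str                     # bases following the tract
    genotypes: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def polymorphic(self) -> bool:
        return len(self.alleles) > 1

    def sampled_alleles(self) -> list[int]:
        """Distinct repeat counts actually present among the genotypes."""
        return sorted({c for g in self.genotypes.values() for c in g})


@dataclass(frozen=True)
class TruthRead:
    read_id: str
    accession: str
    haplotype: int
    locus_id: int | None   # None = background (no SSR) fragment
    allele: int | None


@dataclass
class TruthManifest:
    loci: list[TruthLocus]
    reads: dict[str, TruthRead] = field(default_factory=dict)

    def write(self, loci_path: str | Path, reads_path: str | Path) -> None:
        with open(loci_path, "w") as fh:
            fh.write("locus_id\tmotif\talleles\tread_left_flank\tright_flank\t"
                     "genotypes\n")
            for loc in self.loci:
                geno = ";".join(f"{a}:{c1}/{c2}"
                                for a, (c1, c2) in sorted(loc.genotypes.items()))
                fh.write(f"{loc.locus_id}\t{loc.motif}\t"
                         f"{','.join(map(str, loc.alleles))}\t"
                         f"{loc.read_left_flank}\t{loc.right_flank}\t{geno}\n")
        with open(reads_path, "w") as fh:
            fh.write("read_id\taccession\thaplotype\tlocus_id\tallele\n")
            for tr in self.reads.values():
                fh.write(f"{tr.read_id}\t{tr.accession}\t{tr.haplotype}\t"
                         f"{'.' if tr.locus_id is None else tr.locus_id}\t"
                         f"{'.' if tr.allele is None else tr.allele}\n")


# ---------------------------------------------------------------------------
# Config builders

def random_locus_specs(
    rng: np.random.Generator,
    n_loci: int,
    n_polymorphic: int,
    thresholds: SSRThresholds | None = None,
) -> list[LocusSpec]:
    """Random primitive motifs over all length classes; polymorphic loci
    get 2-3 alleles with simple frequency patterns."""
    thresholds = thresholds or SSRThresholds()
    max_extra = {2: 5, 3: 3, 4: 1, 5: 1, 6: 1}
    specs: list[LocusSpec] = []
    seen_motifs: set[str] = set()
    while len(specs) < n_loci:
        m = int(rng.choice([2, 2, 2, 3, 3, 4, 5, 6]))  # di/tri-heavy mix
        motif = "".join(rng.choice(list("ACGT"), size=m))
        if not is_primitive(motif) or motif in seen_motifs:
            continue
        # a tract must not spawn enzyme cut sites of its own
        if iupac_find_all(motif * 4, ENZYME_SITE):
            continue
        seen_motifs.add(motif)
        base = thresholds[m] + int(rng.integers(0, max_extra[m] + 1))
        if len(specs) < n_polymorphic:
            n_alleles = int(rng.choice([2, 2, 3]))
            counts = [base + k for k in range(n_alleles)]
            if n_alleles == 2:
                p = float(rng.choice([0.5, 0.6, 0.7]))
                freqs = {counts[0]: p, counts[1]: round(1 - p, 10)}
            else:
                freqs = {counts[0]: 0.5, counts[1]: 0.3, counts[2]: 0.2}
        else:
            freqs = {base: 1.0}
        specs.append(LocusSpec(motif=motif, allele_freqs=freqs))
    return specs


def default_sim_config(seed: int, n_accessions: int = 20, n_loci: int = 50,
                       n_polymorphic: int = 30, depth: int = 15,
                       error_rate: float = 0.001) -> SimConfig:
    rng = np.random.default_rng(seed)
    specs = random_locus_specs(rng, n_loci, n_polymorphic)
    n_out = n_accessions // 2
    groups = (
        GroupSpec("outcrossing", n_out, inbreeding=0.1),
        GroupSpec("selfing", n_accessions - n_out, inbreeding=0.9),
    )
    return SimConfig(loci=tuple(specs), groups=groups, seed=seed,
                     depth=depth, error_rate=error_rate)


# ---------------------------------------------------------------------------
# Genome assembly

_BASES = np.array(list("ACGT"))


def _random_segment(rng: np.random.Generator, length: int, gc: float,
                    context: str, thresholds: SSRThresholds,
                    forbid_site_tail: bool = False) -> str:
    """Random sequence screened (with left context) to add no enzyme site
    and no detectable SSR; rejection-resampled.

    Sites/SSRs entirely inside the context are tolerated (the context may
    legitimately end with a planted cut site); anything extending into the
    new segment is not.
    """
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    boundary = len(context)
    for _ in range(1000):
        seg = "".join(rng.choice(_BASES, size=length, p=p))
        probe = context + seg
        if any(pos + len(ENZYME_SITE) > boundary
               for pos in iupac_find_all(probe, ENZYME_SITE)):
            continue
        if any(h.end > boundary for h in find_perfect_ssrs(probe, thresholds)):
            continue
        # a tail matching GCW would complete GCWGC with a following G+CWGC site
        if forbid_site_tail and seg[-3:] in ("GCA", "GCT"):
            continue
        return seg
    raise RuntimeError("could not sample a clean background segment")


@dataclass
class GenomeTemplate:
    """Parts-based genome: per-locus units whose tract length is swapped
    per haplotype when reads are generated."""

    prefix: str
    units: list[tuple[str, str, str]]  # (pre = site..left flank, motif, post)
    loci: list[TruthLocus]

    def haplotype(self, counts: list[int]) -> str:
        parts = [self.prefix]
        for (pre, motif, post), c in zip(self.units, counts):
            parts.append(pre + motif * c + post)
        return "".join(parts)

    def reference_counts(self) -> list[int]:
        return [max(loc.alleles) for loc in self.loci]


def make_genome(config: SimConfig,
                thresholds: SSRThresholds | None = None) -> GenomeTemplate:
    """Assemble the template genome with all planted tracts.

    Each unit is ``G + remnant + left flank + tract + right fill + spacer``;
    flank edges are constrained so the planted tract cannot extend into
    its flanks, keeping detector coordinates exact.
    """
    thresholds = thresholds or SSRThresholds()
    rng = np.random.default_rng(config.seed)
    prefix = _random_segment(rng, config.spacer_len, config.gc_fraction,
                             "", thresholds, forbid_site_tail=True)
    units: list[tuple[str, str, str]] = []
    loci: list[TruthLocus] = []
    context = prefix
    for locus_id, spec in enumerate(config.loci):
        motif = spec.motif
        ref_count = max(spec.allele_freqs)
        for _ in range(200):
            remnant = REMNANTS[int(rng.integers(0, 2))]
            site = "G" + remnant
            left = _random_segment(rng, config.left_flank_len,
                                   config.gc_fraction, context + site,
                                   thresholds)
            # forbid tract extension into the flanks
            if left[-1] == motif[-1]:
                left = left[:-1] + str(rng.choice(
                    [b for b in "ACGT" if b != motif[-1]]))
            fill = _random_segment(rng, config.right_fill_len,
                                   config.gc_fraction, "", thresholds)
            if fill[0] == motif[0]:
                fill = str(rng.choice(
                    [b for b in "ACGT" if b != motif[0]])) + fill[1:]
            spacer = _random_segment(rng, config.spacer_len,
                                     config.gc_fraction, fill[-15:],
                                     thresholds, forbid_site_tail=True)
            # verify the whole unit in context: exactly the planted tract,
            # exactly the unit's own cut site
            unit = site + left + motif * ref_count + fill + spacer
            probe = context + unit
            hits = find_perfect_ssrs(probe, thresholds)
            tract_at = len(context + site + left)
            if not (len(hits) == 1 and hits[0].motif == motif
                    and hits[0].repeat_count == ref_count
                    and hits[0].start == tract_at):
                continue
            if iupac_find_all(probe, ENZYME_SITE) != [len(context)]:
                continue
            break
        else:
            raise RuntimeError(
                f"could not place locus {locus_id} ({motif}) cleanly")
        pre = site + left
        post = fill + spacer
        units.append((pre, motif, post))
        loci.append(TruthLocus(
            locus_id=locus_id,
            motif=motif,
            alleles=sorted(spec.allele_freqs),
            read_left_flank=remnant + left,
            right_flank=fill,
        ))
        context = post[-15:]
    template = GenomeTemplate(prefix=prefix, units=units, loci=loci)

    # verify the reference genome yields exactly the planted tracts
    ref = template.haplotype(template.reference_counts())
    hits = find_perfect_ssrs(ref, thresholds)
    expected = sorted((loc.motif, max(loc.alleles)) for loc in loci)
    got = sorted((h.motif, h.repeat_count) for h in hits)
    if expected != got:
        raise RuntimeError("genome assembly produced unplanned or broken SSRs")
    return template


# ---------------------------------------------------------------------------
# Population sampling

def sample_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, list[tuple[int, int]]]:
    """Diploid genotypes per accession under per-group inbreeding F.

    P(hom ii) = p_i^2 + F p_i (1 - p_i); P(het ij) = 2 p_i p_j (1 - F).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    genotypes: dict[str, list[tuple[int, int]]] = {}
    for group in config.groups:
        for k in range(group.n_accessions):
            accession = f"{group.name}_{k + 1:02d}"
            gts = []
            for spec in config.loci:
                alleles = sorted(spec.allele_freqs)
                probs = [spec.allele_freqs[a] for a in alleles]
                if rng.random() < group.inbreeding:
                    a = alleles[_choice(rng, probs)]
                    gts.append((a, a))
                else:
                    a = alleles[_choice(rng, probs)]
                    b = alleles[_choice(rng, probs)]
                    gts.append((min(a, b), max(a, b)))
            genotypes[accession] = gts
    return genotypes


def _choice(rng: np.random.Generator, probs: list[float]) -> int:
    return int(rng.choice(len(probs), p=np.array(probs) / sum(probs)))


# ---------------------------------------------------------------------------
# Digestion and read generation

def generate_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct barcodes with pairwise Hamming distance >= 3."""
    out: list[str] = []
    while len(out) < n:
        cand = "".join(rng.choice(_BASES, size=length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= 3 for bc in out):
            out.append(cand)
    return out


def digest(genome: str) -> list[tuple[int, int]]:
    """Fragment intervals (0-based half-open) after cutting G^CWGC."""
    cuts = [pos + 1 for pos in iupac_find_all(genome, ENZYME_SITE)]
    bounds = [0] + cuts + [len(genome)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
            if bounds[i + 1] > bounds[i]]


def digest_and_read(
    config: SimConfig,
    template: GenomeTemplate,
    genotypes: dict[str, list[tuple[int, int]]],
) -> tuple[list[GBSRead], BarcodeMap, TruthManifest]:
    """Emit barcoded error-bearing reads from every fragment's forward end."""
    rng = np.random.default_rng(config.seed + 2)
    accessions = sorted(genotypes)
    barcodes = generate_barcodes(rng, len(accessions), config.barcode_len)
    barcode_map = BarcodeMap(dict(zip(barcodes, accessions)))
    acc_barcode = dict(zip(accessions, barcodes))

    manifest = TruthManifest(loci=list(template.loci))
    for accession, gts in genotypes.items():
        for locus, g in zip(manifest.loci, gts):
            locus.genotypes[accession] = g

    depth_per_hap = max(1, round(config.depth / 2))
    reads: list[GBSRead] = []
    counter = 0
    for accession in accessions:
        gts = genotypes[accession]
        barcode = acc_barcode[accession]
        insert_len = config.read_length - len(barcode)
        for hap in (0, 1):
            counts = [g[hap] for g in gts]
            genome = template.haplotype(counts)
            # locate each planted tract so reads can be traced back
            locus_at: dict[int, tuple[int, int]] = {}  # fragment start -> locus
            pos = len(template.prefix)
            for locus_id, ((pre, motif, post), c) in enumerate(
                    zip(template.units, counts)):
                locus_at[pos + 1] = (locus_id, c)  # cut is 1 into the site
                pos += len(pre) + len(motif) * c + len(post)
            for start, end in digest(genome):
                if end - start < insert_len:
                    continue
                insert = genome[start:start + insert_len]
                locus_id, allele = locus_at.get(start, (None, None))
                for _ in range(depth_per_hap):
                    counter += 1
                    read_id = f"r{counter}"
                    seq = barcode + insert
                    seq, qual = _apply_errors(rng, seq, config.error_rate)
                    reads.append(GBSRead(read_id=read_id, sequence=seq,
                                         quality=qual))
                    manifest.reads[read_id] = TruthRead(
                        read_id=read_id, accession=accession, haplotype=hap,
                        locus_id=locus_id, allele=allele)
    return reads, barcode_map, manifest


def _apply_errors(rng: np.random.Generator, seq: str,
                  rate: float) -> tuple[str, tuple[int, ...]]:
    qual = [30] * len(seq)
    if rate <= 0:
        return seq, tuple(qual)
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, tuple(qual)
    chars = list(seq)
    positions = rng.choice(len(seq), size=n_err, replace=False)
    for p in positions:
        p = int(p)
        chars[p] = str(rng.choice([b for b in "ACGT" if b != chars[p]]))
        qual[p] = 15
    return "".join(chars), tuple(qual)


def simulate(config: SimConfig) -> tuple[list[GBSRead], BarcodeMap, TruthManifest]:
    """Full simulation: genome, population, digest, reads."""
    template = make_genome(config)
    genotypes = sample_population(config)
    return digest_and_read(config, template, genotypes)


def match_clusters_to_truth(clusters, manifest: TruthManifest) -> dict[int, object]:
    """Map planted locus ids to recovered locus clusters by flank identity.

    A cluster matches a planted locus when any of its member records has
    exactly the planted read-frame left flank and a right flank that is a
    prefix of the planted one (reads are truncated, so the recovered right
    flank is shorter). Matching on members rather than the centroid keeps
    the mapping robust to rare error-stack centroids.
    """
    out: dict[int, object] = {}
    for loc in manifest.loci:
        for cluster in clusters:
            if any(rec.flank_left == loc.read_left_flank
                   and loc.right_flank.startswith(rec.flank_right)
                   for rec in cluster.records):
                out[loc.locus_id] = cluster
                break
    return out
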