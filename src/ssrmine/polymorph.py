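"""Cross-accession clustering of SSR-bearing loci and marker selection.

Allele-length variation at a locus would defeat plain sequence-identity
clustering, so each tract is first masked down to a single placeholder;
records whose masked flanks are near-identical (and whose motifs fall in
the same canonical class) are grouped into one locus cluster carrying a
per-accession table of observed repeat counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ssr_detect import SSRHit, canonical_class

MASK_CHAR = "*"


@dataclass(frozen=True)
class MaskedRecord:
    """One SSR-bearing sequence with its tract masked out.

    ``support`` maps accession -> read depth backing this record (a record
    may be shared by several accessions when their sequences are identical).
    """

    source_id: str
    masked: str          # flank_left + MASK_CHAR + flank_right
    motif: str
    repeat_count: int
    support: tuple[tuple[str, int], ...]  # ((accession, depth), ...)

    @property
    def canonical_class(self) -> str:
        return canonical_class(self.motif)

    @property
    def star(self) -> int:
        return self.masked.index(MASK_CHAR)

    @property
    def flank_left(self) -> str:
        return self.masked[: self.star]

    @property
    def flank_right(self) -> str:
        return self.masked[self.star + 1:]


@dataclass
class SSRLocusCluster:
    cluster_id: int
    centroid: MaskedRecord
    # accession -> sorted list of distinct repeat counts observed
    members: dict[str, list[int]] = field(default_factory=dict)
    records: list[MaskedRecord] = field(default_factory=list)

    @property
    def canonical_class(self) -> str:
        return self.centroid.canonical_class

    @property
    def motif_len(self) -> int:
        return len(self.centroid.motif)

    @property
    def support(self) -> int:
        """Number of accessions with at least one SSR-spanning observation."""
        return len(self.members)

    @property
    def alleles(self) -> list[int]:
        return sorted({c for counts in self.members.values() for c in counts})

    def add(self, record: MaskedRecord) -> None:
        self.records.append(record)
        for accession, _depth in record.support:
            lst = self.members.setdefault(accession, [])
            if record.repeat_count not in lst:
                lst.append(record.repeat_count)
                lst.sort()


def mask_ssr(sequence: str, hit: SSRHit) -> str:
    """Replace the tract by a single placeholder, keeping flanks verbatim."""
    if not (0 <= hit.start < hit.end <= len(sequence)):
        raise ValueError("hit does not lie within the sequence")
    return sequence[: hit.start] + MASK_CHAR + sequence[hit.end:]


def masked_identity(a: MaskedRecord, b: MaskedRecord) -> float:
    """Identity of two masked sequences, anchored at the mask.

    The placeholders are aligned on top of each other (an end-gap-free
    global alignment with no internal gaps: the tract sits at the same
    flank boundary in both), and identity is matches / overlap length
    over the flank positions that overlap.
    """
    la, ra = a.flank_left, a.flank_right
    lb, rb = b.flank_left, b.flank_right
    nl = min(len(la), len(lb))
    nr = min(len(ra), len(rb))
    overlap = nl + nr
    if overlap == 0:
        return 0.0
    matches = sum(la[-nl + i] == lb[-nl + i] for i in range(nl)) if nl else 0
    matches += sum(ra[i] == rb[i] for i in range(nr))
    return matches / overlap


def cluster_loci(
    records: Sequence[MaskedRecord],
    identity_threshold: float = 0.90,
) -> list[SSRLocusCluster]:
    """Greedy centroid clustering of masked records.

    Records are processed sorted by (masked length desc, masked asc,
    source_id); each joins the first centroid sharing its canonical motif
    class with identity >= threshold, else founds a new cluster.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.masked), r.masked, r.source_id))
    clusters: list[SSRLocusCluster] = []
    for rec in ordered:
        rec_class = rec.canonical_class
        for cluster in clusters:
            if cluster.canonical_class != rec_class:
                continue
            if masked_identity(cluster.centroid, rec) >= identity_threshold:
                cluster.add(rec)
                break
        else:
            cluster = SSRLocusCluster(cluster_id=len(clusters), centroid=rec)
            cluster.add(rec)
            clusters.append(cluster)
    return clusters


def call_polymorphic(
    cluster: SSRLocusCluster, min_allele_obs: int = 1
) -> tuple[bool, list[int]]:
    """A cluster is polymorphic iff >= 2 distinct repeat counts are each
    observed in at least ``min_allele_obs`` accessions."""
    if min_allele_obs < 1:
        raise ValueError("min_allele_obs must be >= 1")
    if not cluster.members:
        return False, []
    obs: dict[int, int] = {}
    for counts in cluster.members.values():
        for c in counts:
            obs[c] = obs.get(c, 0) + 1
    alleles = sorted(c for c, n in obs.items() if n >= min_allele_obs)
    return len(alleles) >= 2, sorted(obs)


@dataclass
class MarkerCandidate:
    cluster: SSRLocusCluster
    alleles: list[int]
    supporting_accessions: int
    expected_product_size: int | None  # for the longest allele; None = no primers
    primer_pair: object | None = None
    filters: dict[str, bool] = field(default_factory=dict)

    @property
    def allele_count(self) -> int:
        return len(self.alleles)

    @property
    def accepted(self) -> bool:
        return bool(self.filters) and all(self.filters.values())


def select_candidates(
    candidates: Iterable[MarkerCandidate],
    min_support: int = 20,
    product_range: tuple[int, int] = (80, 100),
) -> list[MarkerCandidate]:
    """Apply the support and product-size selection filters.

    Every candidate gets per-filter pass/fail flags; the returned list
    contains only the accepted ones (support >= min_support and expected
    product size inside the closed range, with a designable primer pair).
    """
    lo, hi = product_range
    accepted = []
    for cand in candidates:
        cand.filters["primer_designable"] = cand.expected_product_size is not None
        cand.filters["support"] = cand.supporting_accessions >= min_support
        cand.filters["product_size"] = (
            cand.expected_product_size is not None
            and lo <= cand.expected_product_size <= hi
        )
        if cand.accepted:
            accepted.append(cand)
    return accepted


# ---------------------------------------------------------------------------
# I/O

def write_allele_table(clusters: Sequence[SSRLocusCluster],
                       accessions: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmotif\tclass\t" + "\t".join(accessions) + "\n")
        for cl in clusters:
            cells = [
                ",".join(str(c) for c in cl.members[a]) if a in cl.members else "."
                for a in accessions
            ]
            fh.write(f"{cl.cluster_id}\t{cl.centroid.motif}\t{cl.canonical_class}\t"
                     + "\t".join(cells) + "\n")


def write_candidates_tsv(candidates: Sequence[MarkerCandidate],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmotif\talleles\tsupport\texpected_product\t"
                 "pass_primer\tpass_support\tpass_product\taccepted\n")
        for c in candidates:
            fh.write(
                f"{c.cluster.cluster_id}\t{c.cluster.centroid.motif}\t"
                f"{','.join(map(str, c.alleles))}\t{c.supporting_accessions}\t"
                f"{c.expected_product_size if c.expected_product_size else '.'}\t"
                f"{int(c.filters.get('primer_designable', False))}\t"
                f"{int(c.filters.get('support', False))}\t"
                f"{int(c.filters.get('product_size', False))}\t"
                f"{int(c.accepted)}\n"
            )


def write_centroids_fasta(clusters: Sequence[SSRLocusCluster],
                          path: str | Path) -> None:
    """Centroid masked sequences; the mask position is kept in the header."""
    with open(path, "w") as fh:
        for cl in clusters:
            c = cl.centroid
            fh.write(f">cluster_{cl.cluster_id} motif={c.motif} "
                     f"count={c.repeat_count} mask_at={c.star}\n{c.masked}\n")
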