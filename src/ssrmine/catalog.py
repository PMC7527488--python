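"""Reference-free stacking of identical reads and cross-accession cataloging.

Within an accession, identical reads collapse into depth-annotated unique
stacks; shallow stacks that are within a small Hamming distance of exactly
one deep stack are treated as sequencing-error copies and absorbed. Stacks
from all accessions are then greedily merged into consensus catalog loci.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._seq import hamming
from .preprocess import GBSRead

BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class UniqueStack:
    sequence: str
    depth: int
    accession: str


@dataclass
class CatalogLocus:
    locus_id: int
    consensus: str
    # accession -> list of (stack, mismatches to final consensus)
    members: dict[str, list[tuple[UniqueStack, int]]] = field(default_factory=dict)

    @property
    def accessions(self) -> list[str]:
        return sorted(self.members)

    @property
    def total_depth(self) -> int:
        return sum(s.depth for lst in self.members.values() for s, _ in lst)


def build_stacks(
    reads: Sequence[GBSRead],
    min_depth: int = 2,
    merge_distance: int = 2,
) -> list[UniqueStack]:
    """Collapse one accession's uniform-length reads into unique stacks.

    Sub-threshold stacks within ``merge_distance`` of exactly one
    >=min_depth stack are absorbed into it (depths summed, deep sequence
    kept); the rest are dropped. Output sorted by (depth desc, seq asc).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if merge_distance not in (0, 1, 2):
        raise ValueError("merge_distance must be in {0,1,2}")
    if not reads:
        return []
    accessions = {r.accession for r in reads}
    if len(accessions) != 1:
        raise ValueError(f"reads from mixed accessions: {sorted(accessions)}")
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        raise ValueError(f"reads of mixed lengths: {sorted(lengths)}")
    accession = accessions.pop()

    counts = Counter(r.sequence for r in reads)
    deep = {s: d for s, d in counts.items() if d >= min_depth}
    shallow = {s: d for s, d in counts.items() if d < min_depth}

    absorbed: dict[str, int] = defaultdict(int)
    if merge_distance > 0 and deep:
        deep_seqs = sorted(deep)  # deterministic scan order
        for seq, d in shallow.items():
            hits = [t for t in deep_seqs if hamming(seq, t) <= merge_distance]
            if len(hits) == 1:
                absorbed[hits[0]] += d

    stacks = [
        UniqueStack(sequence=s, depth=d + absorbed.get(s, 0), accession=accession)
        for s, d in deep.items()
    ]
    stacks.sort(key=lambda st: (-st.depth, st.sequence))
    return stacks


def _consensus(members: list[UniqueStack]) -> str:
    """Depth-weighted per-position majority base, ties broken A<C<G<T."""
    length = len(members[0].sequence)
    out = []
    for i in range(length):
        votes = {b: 0 for b in BASE_ORDER}
        for st in members:
            votes[st.sequence[i]] += st.depth
        out.append(max(BASE_ORDER, key=lambda b: (votes[b], -BASE_ORDER.index(b))))
    return "".join(out)


def build_catalog(
    stacks_by_accession: dict[str, Sequence[UniqueStack]],
    catalog_mismatch: int = 0,
) -> list[CatalogLocus]:
    """Greedy first-fit merge of stacks from all accessions into loci.

    Stacks are processed sorted by (depth desc, sequence asc, accession);
    a stack joins the first founded locus whose current consensus is
    within ``catalog_mismatch``, else founds a new locus. The consensus
    is recomputed after every addition.
    """
    if catalog_mismatch not in (0, 1, 2):
        raise ValueError("catalog_mismatch must be in {0,1,2}")
    pool: list[UniqueStack] = [
        s for stacks in stacks_by_accession.values() for s in stacks
    ]
    if not pool:
        return []
    lengths = {len(s.sequence) for s in pool}
    if len(lengths) != 1:
        raise ValueError("stacks of mixed lengths")
    pool.sort(key=lambda s: (-s.depth, s.sequence, s.accession))

    loci: list[CatalogLocus] = []
    member_lists: list[list[UniqueStack]] = []
    if catalog_mismatch == 0:
        by_seq: dict[str, int] = {}
        for st in pool:
            idx = by_seq.get(st.sequence)
            if idx is None:
                by_seq[st.sequence] = len(loci)
                loci.append(CatalogLocus(locus_id=len(loci), consensus=st.sequence))
                member_lists.append([st])
            else:
                member_lists[idx].append(st)
    else:
        for st in pool:
            for idx, locus in enumerate(loci):
                if hamming(st.sequence, locus.consensus) <= catalog_mismatch:
                    member_lists[idx].append(st)
                    locus.consensus = _consensus(member_lists[idx])
                    break
            else:
                loci.append(CatalogLocus(locus_id=len(loci), consensus=st.sequence))
                member_lists.append([st])

    for locus, members in zip(loci, member_lists):
        for st in members:
            locus.members.setdefault(st.accession, []).append(
                (st, hamming(st.sequence, locus.consensus))
            )
    return loci


# ---------------------------------------------------------------------------
# I/O

def write_stacks_tsv(stacks_by_accession: dict[str, Sequence[UniqueStack]],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tsequence\tdepth\n")
        for accession in sorted(stacks_by_accession):
            for st in stacks_by_accession[accession]:
                fh.write(f"{st.accession}\t{st.sequence}\t{st.depth}\n")


def read_stacks_tsv(path: str | Path) -> dict[str, list[UniqueStack]]:
    out: dict[str, list[UniqueStack]] = defaultdict(list)
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            accession, sequence, depth = line.rstrip("\n").split("\t")
            out[accession].append(
                UniqueStack(sequence=sequence, depth=int(depth), accession=accession)
            )
    return dict(out)


def write_catalog(loci: Iterable[CatalogLocus], fasta_path: str | Path,
                  members_path: str | Path) -> None:
    with open(fasta_path, "w") as fa, open(members_path, "w") as tsv:
        tsv.write("locus_id\taccession\tsequence\tdepth\tmismatches\n")
        for locus in loci:
            fa.write(f">locus_{locus.locus_id}\n{locus.consensus}\n")
            for accession in locus.accessions:
                for st, mm in locus.members[accession]:
                    tsv.write(f"{locus.locus_id}\t{accession}\t{st.sequence}\t"
                              f"{st.depth}\t{mm}\n")


def read_catalog(fasta_path: str | Path, members_path: str | Path) -> list[CatalogLocus]:
    loci: dict[int, CatalogLocus] = {}
    with open(fasta_path) as fa:
        locus_id = None
        for line in fa:
            line = line.rstrip("\n")
            if line.startswith(">"):
                locus_id = int(line[1:].split("_")[1])
            elif locus_id is not None:
                loci[locus_id] = CatalogLocus(locus_id=locus_id, consensus=line)
                locus_id = None
    with open(members_path) as tsv:
        tsv.readline()
        for line in tsv:
            lid, accession, sequence, depth, mm = line.rstrip("\n").split("\t")
            st = UniqueStack(sequence=sequence, depth=int(depth), accession=accession)
            loci[int(lid)].members.setdefault(accession, []).append((st, int(mm)))
    return [loci[k] for k in sorted(loci)]
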