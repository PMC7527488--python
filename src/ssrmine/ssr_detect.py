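"""Detection of perfect microsatellite tracts (motif length 2-6).

A tract is a maximal run of a primitive motif repeated end to end; runs
qualifying under a longer non-primitive period (e.g. ``(ATAT)3`` inside
``(AT)6``) are reported once, for the primitive motif. Coordinates are
0-based half-open internally; the MISA-style TSV writer emits 1-based
inclusive positions for interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._seq import revcomp

MOTIF_LENGTHS = (2, 3, 4, 5, 6)
REPEAT_BINS = ("5", "6", "7", "8", "9", "10", ">10")
CLASS_NAMES = {2: "Dinucleotide", 3: "Trinucleotide", 4: "Tetranucleotide",
               5: "Pentanucleotide", 6: "Hexanucleotide"}


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum repeat count by motif length; mononucleotides are excluded."""

    min_repeats: dict[int, int] = field(
        default_factory=lambda: {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
    )

    def __post_init__(self):
        for m, r in self.min_repeats.items():
            if m not in MOTIF_LENGTHS:
                raise ValueError(f"unsupported motif length {m}")
            if r < 2:
                raise ValueError("minimum repeat counts must be >= 2")

    def __getitem__(self, motif_len: int) -> int:
        return self.min_repeats[motif_len]


@dataclass(frozen=True)
class SSRHit:
    source_id: str
    motif: str
    repeat_count: int
    start: int
    end: int

    def __post_init__(self):
        if self.end - self.start != self.repeat_count * len(self.motif):
            raise ValueError("tract span inconsistent with motif x count")

    @property
    def canonical_class(self) -> str:
        return canonical_class(self.motif)

    @property
    def tract(self) -> str:
        return self.motif * self.repeat_count


def is_primitive(motif: str) -> bool:
    """True iff the motif is not itself a repetition of a shorter unit."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def find_perfect_ssrs(
    sequence: str,
    thresholds: SSRThresholds | None = None,
    source_id: str = "",
) -> list[SSRHit]:
    """All maximal perfect tandem repeats meeting the per-length thresholds.

    For each motif length m, the sequence is scanned for maximal runs of
    period m (positions where base i equals base i+m); a run of L such
    equalities spans L+m bases and holds ``(L+m)//m`` complete motifs.
    Partial trailing motifs never count toward the repeat number. N is
    never equal to anything, so uncalled bases break tracts.
    """
    thresholds = thresholds or SSRThresholds()
    seq = sequence.upper()
    n = len(seq)
    hits: list[SSRHit] = []
    for m in MOTIF_LENGTHS:
        threshold = thresholds[m]
        i = 0
        limit = n - m
        while i < limit:
            a, b = seq[i], seq[i + m]
            if a != b or a not in "ACGT":
                i += 1
                continue
            j = i
            while j < limit and seq[j] == seq[j + m] and seq[j] in "ACGT":
                j += 1
            run = j - i  # number of period-m equalities
            count = (run + m) // m
            motif = seq[i:i + m]
            if count >= threshold and is_primitive(motif):
                hits.append(SSRHit(
                    source_id=source_id, motif=motif, repeat_count=count,
                    start=i, end=i + count * m,
                ))
            i = j + 1
    hits.sort(key=lambda h: (h.start, len(h.motif)))
    return hits


def canonical_class(motif: str) -> str:
    """Motif equivalence class under cyclic rotation and reverse complement.

    The class label is the lexicographically smallest rotation among the
    motif and its reverse complement, joined with that string's reverse
    complement, e.g. GA/AG/TC/CT -> "AG/CT"; TA/AT -> "AT/AT".
    """
    if not 2 <= len(motif) <= 6:
        raise ValueError("motif length must be 2-6")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    candidates = set()
    for s in (motif, revcomp(motif)):
        for k in range(len(s)):
            candidates.add(s[k:] + s[:k])
    smallest = min(candidates)
    return f"{smallest}/{revcomp(smallest)}"


@dataclass
class SSRSummary:
    """Counts per motif-length class x repeat-count bin (5..10, >10)."""

    counts: dict[int, dict[str, int]] = field(
        default_factory=lambda: {m: {b: 0 for b in REPEAT_BINS} for m in MOTIF_LENGTHS}
    )

    @classmethod
    def from_class_totals(cls, totals: dict[int, int]) -> "SSRSummary":
        """Build a summary carrying only per-class totals (put in bin '5')."""
        s = cls()
        for m, total in totals.items():
            s.counts[m]["5"] = total
        return s

    def class_total(self, motif_len: int) -> int:
        return sum(self.counts[motif_len].values())

    @property
    def grand_total(self) -> int:
        return sum(self.class_total(m) for m in MOTIF_LENGTHS)

    def frequency_percent(self, motif_len: int) -> float:
        """Class share of all hits, as a percentage rounded to 2 decimals."""
        total = self.grand_total
        if total == 0:
            return 0.0
        return round(100.0 * self.class_total(motif_len) / total, 2)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("motif_class\t" + "\t".join(REPEAT_BINS)
                     + "\ttotal\tfrequency_pct\n")
            for m in MOTIF_LENGTHS:
                row = "\t".join(str(self.counts[m][b]) for b in REPEAT_BINS)
                fh.write(f"{CLASS_NAMES[m]}\t{row}\t{self.class_total(m)}\t"
                         f"{self.frequency_percent(m):.2f}\n")
            fh.write("Total\t"
                     + "\t".join(str(sum(self.counts[m][b] for m in MOTIF_LENGTHS))
                                 for b in REPEAT_BINS)
                     + f"\t{self.grand_total}\t100.00\n")


def summarize(hits: Iterable[SSRHit]) -> SSRSummary:
    summary = SSRSummary()
    for hit in hits:
        m = len(hit.motif)
        b = str(hit.repeat_count) if hit.repeat_count <= 10 else ">10"
        summary.counts[m][b] += 1
    return summary


def write_misa_tsv(hits: Sequence[SSRHit], path: str | Path) -> None:
    """MISA-style table; positions are 1-based inclusive in the file."""
    with open(path, "w") as fh:
        fh.write("ID\tSSR nr.\tSSR type\tSSR\tsize\tstart\tend\n")
        nr: dict[str, int] = {}
        for hit in hits:
            nr[hit.source_id] = nr.get(hit.source_id, 0) + 1
            fh.write(
                f"{hit.source_id}\t{nr[hit.source_id]}\tp{len(hit.motif)}\t"
                f"({hit.motif}){hit.repeat_count}\t{hit.end - hit.start}\t"
                f"{hit.start + 1}\t{hit.end}\n"
            )
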