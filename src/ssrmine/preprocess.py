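"""Demultiplexing, restriction-remnant verification and quality filtering.

Raw single-end reads carry an inline barcode followed by the enzyme cut
remnant (``CWGC`` for a G^CWGC cutter). This stage assigns each read to its
accession, trims the barcode, discards reads without the remnant or with
poor quality, and truncates survivors to a common length so that the
downstream exact-match stacking stage sees uniform sequences.
"""

from __future__ import annotations

import gzip
import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import matches_iupac

DEFAULT_REMNANT = "CWGC"
DEFAULT_TARGET_LENGTH = 90
DEFAULT_WINDOW_FRACTION = 0.15
DEFAULT_MIN_MEAN_Q = 10

UNASSIGNED = "unassigned"

# discard reasons
REASON_BARCODE = "barcode"
REASON_AMBIGUOUS = "ambiguous_barcode"
REASON_SITE = "restriction_site"
REASON_QUALITY = "quality"
REASON_LENGTH = "length"


@dataclass(frozen=True)
class GBSRead:
    """A single-end read; quality is a list of Phred scores, one per base."""

    read_id: str
    sequence: str
    quality: tuple[int, ...]
    accession: str = UNASSIGNED

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"{self.read_id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class BarcodeMap:
    """Barcode -> accession lookup; barcodes may differ in length.

    No barcode may be a prefix of another (that would make exact
    demultiplexing ambiguous) and accession names must be unique.
    """

    def __init__(self, mapping: dict[str, str]):
        if not mapping:
            raise ValueError("barcode map is empty")
        barcodes = sorted(mapping)
        for i, b in enumerate(barcodes):
            for other in barcodes[i + 1:]:
                if other.startswith(b):
                    raise ValueError(f"barcode {b!r} is a prefix of {other!r}")
        if len(set(mapping.values())) != len(mapping):
            raise ValueError("accession identifiers are not unique")
        self._map = dict(mapping)

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @property
    def accessions(self) -> list[str]:
        return sorted(self._map.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0].lower() == "barcode":
                    continue
                barcode, accession = fields[0], fields[1]
                mapping[barcode.upper()] = accession
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("barcode\taccession\n")
            for barcode in sorted(self._map):
                fh.write(f"{barcode}\t{self._map[barcode]}\n")


@dataclass
class FilterReport:
    """Per-accession read accounting; categories sum to the raw count."""

    raw: int = 0
    retained: int = 0
    discarded_barcode: int = 0
    discarded_ambiguous: int = 0
    discarded_site: int = 0
    discarded_quality: int = 0
    discarded_length: int = 0
    per_accession: dict[str, dict[str, int]] = field(default_factory=dict)

    _CATS = ("retained", "discarded_site", "discarded_quality", "discarded_length")

    def _acc(self, accession: str) -> dict[str, int]:
        return self.per_accession.setdefault(
            accession, {c: 0 for c in self._CATS} | {"nucleotides": 0}
        )

    def count(self, accession: str, category: str, nucleotides: int = 0) -> None:
        self.raw += 1
        if category == REASON_BARCODE:
            self.discarded_barcode += 1
            return
        if category == REASON_AMBIGUOUS:
            self.discarded_ambiguous += 1
            return
        rec = self._acc(accession)
        if category == "retained":
            self.retained += 1
            rec["retained"] += 1
            rec["nucleotides"] += nucleotides
        elif category == REASON_SITE:
            self.discarded_site += 1
            rec["discarded_site"] += 1
        elif category == REASON_QUALITY:
            self.discarded_quality += 1
            rec["discarded_quality"] += 1
        elif category == REASON_LENGTH:
            self.discarded_length += 1
            rec["discarded_length"] += 1
        else:  # pragma: no cover
            raise ValueError(f"unknown category {category!r}")

    @property
    def discarded_total(self) -> int:
        return (self.discarded_barcode + self.discarded_ambiguous
                + self.discarded_site + self.discarded_quality
                + self.discarded_length)

    def check(self) -> None:
        if self.raw != self.retained + self.discarded_total:
            raise AssertionError("filter report categories do not sum to raw")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("accession\traw_assigned\tclean_reads\tclean_nucleotides\t"
                     "discarded_site\tdiscarded_quality\tdiscarded_length\n")
            for accession in sorted(self.per_accession):
                rec = self.per_accession[accession]
                assigned = (rec["retained"] + rec["discarded_site"]
                            + rec["discarded_quality"] + rec["discarded_length"])
                fh.write(
                    f"{accession}\t{assigned}\t{rec['retained']}\t"
                    f"{rec['nucleotides']}\t{rec['discarded_site']}\t"
                    f"{rec['discarded_quality']}\t{rec['discarded_length']}\n"
                )
            fh.write(f"#raw\t{self.raw}\n")
            fh.write(f"#unknown_barcode\t{self.discarded_barcode}\n")
            fh.write(f"#ambiguous_barcode\t{self.discarded_ambiguous}\n")


def demultiplex(
    read: GBSRead, barcodes: BarcodeMap, max_barcode_mismatch: int = 0
) -> tuple[GBSRead | None, str | None]:
    """Assign a read to an accession by its inline barcode.

    Returns ``(trimmed_read, None)`` on success, ``(None, reason)`` on
    discard.  A mismatching barcode is rescued only when exactly one
    barcode lies at the minimum (nonzero) distance within tolerance.
    """
    if max_barcode_mismatch not in (0, 1):
        raise ValueError("max_barcode_mismatch must be 0 or 1")
    best: list[str] = []
    best_d = max_barcode_mismatch + 1
    for barcode in barcodes:
        n = len(barcode)
        if len(read.sequence) < n:
            continue
        prefix = read.sequence[:n]
        d = sum(x != y for x, y in zip(prefix, barcode))
        if d < best_d:
            best, best_d = [barcode], d
        elif d == best_d:
            best.append(barcode)
    if not best or best_d > max_barcode_mismatch:
        return None, REASON_BARCODE
    if len(best) > 1:
        return None, REASON_AMBIGUOUS
    barcode = best[0]
    accession = dict(barcodes.items())[barcode]
    n = len(barcode)
    return (
        replace(
            read,
            sequence=read.sequence[n:],
            quality=read.quality[n:],
            accession=accession,
        ),
        None,
    )


def check_restriction_remnant(read: GBSRead, remnant_pattern: str = DEFAULT_REMNANT) -> bool:
    """True iff the read begins with the enzyme remnant (IUPAC pattern)."""
    if len(read.sequence) < len(remnant_pattern):
        return False
    return matches_iupac(read.sequence[: len(remnant_pattern)], remnant_pattern)


def quality_filter(
    read: GBSRead,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    min_mean_q: int = DEFAULT_MIN_MEAN_Q,
) -> bool:
    """Sliding-window mean-quality filter; also rejects reads containing N.

    A read is discarded iff any window of size ``ceil(window_fraction *
    len)`` has mean Phred strictly below ``min_mean_q``.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    if "N" in read.sequence:
        return False
    n = len(read)
    if n == 0:
        return False
    w = math.ceil(window_fraction * n)
    q = read.quality
    window_sum = sum(q[:w])
    if window_sum < min_mean_q * w:
        return False
    for i in range(n - w):
        window_sum += q[i + w] - q[i]
        if window_sum < min_mean_q * w:
            return False
    return True


def truncate(read: GBSRead, target_length: int) -> GBSRead | None:
    """Cut a read down to ``target_length``; shorter reads are discarded."""
    if len(read) < target_length:
        return None
    if len(read) == target_length:
        return read
    return replace(
        read,
        sequence=read.sequence[:target_length],
        quality=read.quality[:target_length],
    )


def process_reads(
    reads: Iterable[GBSRead],
    barcodes: BarcodeMap,
    *,
    remnant: str = DEFAULT_REMNANT,
    max_barcode_mismatch: int = 0,
    window_fraction: float = DEFAULT_WINDOW_FRACTION,
    min_mean_q: int = DEFAULT_MIN_MEAN_Q,
    target_length: int = DEFAULT_TARGET_LENGTH,
) -> tuple[dict[str, list[GBSRead]], FilterReport]:
    """Run demultiplex -> remnant check -> quality filter -> truncate."""
    report = FilterReport()
    by_accession: dict[str, list[GBSRead]] = defaultdict(list)
    for accession in barcodes.accessions:
        by_accession[accession] = []
    for read in reads:
        trimmed, reason = demultiplex(read, barcodes, max_barcode_mismatch)
        if trimmed is None:
            report.count(UNASSIGNED, reason)
            continue
        if not check_restriction_remnant(trimmed, remnant):
            report.count(trimmed.accession, REASON_SITE)
            continue
        if not quality_filter(trimmed, window_fraction, min_mean_q):
            report.count(trimmed.accession, REASON_QUALITY)
            continue
        final = truncate(trimmed, target_length)
        if final is None:
            report.count(trimmed.accession, REASON_LENGTH)
            continue
        report.count(final.accession, "retained", nucleotides=len(final))
        by_accession[final.accession].append(final)
    report.check()
    return dict(by_accession), report


# ---------------------------------------------------------------------------
# FASTQ I/O

def read_fastq(path: str | Path) -> Iterator[GBSRead]:
    """Stream reads from a FASTQ file (gzipped or plain)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield GBSRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                quality=tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[GBSRead], path: str | Path) -> int:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(read.quality)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n
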