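"""Small shared sequence helpers."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff `seq` (ACGT) matches the IUPAC `pattern` base by base."""
    if len(seq) != len(pattern):
        return False
    return all(s in IUPAC[p] for s, p in zip(seq, pattern))


def iupac_find_all(seq: str, pattern: str) -> list[int]:
    """All start positions where the IUPAC pattern occurs in seq."""
    m = len(pattern)
    return [i for i in range(len(seq) - m + 1) if matches_iupac(seq[i:i + m], pattern)]


def max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best
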