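"""Flanking-primer enumeration under hard physicochemical constraints.

Melting temperatures use the unified nearest-neighbor thermodynamic
parameters (Allawi & SantaLucia) at fixed default conditions (50 mM
monovalent salt, 50 nM total primer), so results are deterministic to
0.01 degC. Candidate pairs are ranked by a simple additive penalty around
the optimum Tm; no secondary-structure thermodynamics is attempted —
dimer screening is a plain 3'-anchored complementarity count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ._seq import gc_fraction, max_homopolymer_run, revcomp
from .polymorph import SSRLocusCluster

R_GAS = 1.987  # cal / (mol K)

# Unified NN stacks: dimer (5'->3' top strand) -> (dH kcal/mol, dS cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}


def melting_temperature(
    primer: str, *, monovalent_mM: float = 50.0, primer_nM: float = 50.0
) -> float:
    """Nearest-neighbor duplex Tm in degC, rounded to 0.01.

    dS carries the salt correction 0.368*(N-1)*ln[Na+]; the concentration
    term uses CT/4 (non-self-complementary duplex, equal strand
    concentrations).
    """
    seq = primer.upper()
    if len(seq) < 8:
        raise ValueError("primer must be at least 8 nt")
    if any(b not in "ACGT" for b in seq):
        raise ValueError("primer must contain only A/C/G/T")
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i:i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM / 1000.0)
    ct = primer_nM * 1e-9
    tm_k = dh * 1000.0 / (ds + R_GAS * math.log(ct / 4.0))
    return round(tm_k - 273.15, 2)


@dataclass(frozen=True)
class PrimerConstraints:
    length_range: tuple[int, int] = (18, 23)
    product_range: tuple[int, int] = (50, 100)
    tm_range: tuple[float, float] = (52.0, 60.0)
    tm_optimum: float = 55.0
    gc_range: tuple[float, float] = (30.0, 67.0)  # percent
    max_run: int = 4
    max_end_complementarity: int = 3

    def __post_init__(self):
        for lo, hi in (self.length_range, self.product_range,
                       self.tm_range, self.gc_range):
            if lo >= hi:
                raise ValueError("constraint ranges must be non-degenerate")


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    tm_f: float
    tm_r: float
    gc_f: float   # percent
    gc_r: float
    product_size: int        # on the template used at design time
    penalty: float
    design_repeat_count: int  # allele (repeat count) the product was sized on


def end_complementarity(a: str, b: str) -> int:
    """Longest run of perfect complementarity anchored at both 3' ends."""
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        if a[-k:] == revcomp(b[-k:]):
            best = k
    return best


def _window_ok(seq: str, constraints: PrimerConstraints,
               fails: dict[str, int]) -> tuple[float, float] | None:
    gc = 100.0 * gc_fraction(seq)
    if not constraints.gc_range[0] <= gc <= constraints.gc_range[1]:
        fails["gc"] += 1
        return None
    if max_homopolymer_run(seq) > constraints.max_run:
        fails["run"] += 1
        return None
    tm = melting_temperature(seq)
    if not constraints.tm_range[0] <= tm <= constraints.tm_range[1]:
        fails["tm"] += 1
        return None
    if end_complementarity(seq, seq) > constraints.max_end_complementarity:
        fails["self_dimer"] += 1
        return None
    return tm, gc


def design_pair(
    cluster: SSRLocusCluster,
    constraints: PrimerConstraints | None = None,
) -> tuple[PrimerPair | None, dict[str, int]]:
    """Best primer pair flanking the cluster's tract, or None.

    Product sizes are computed on the template carrying the LONGEST
    observed allele, so every allele's product stays inside the range.
    Among feasible pairs the one minimizing

        |Tm_f - opt| + |Tm_r - opt| + |Tm_f - Tm_r|
        + 0.1 * |product - product-range midpoint|

    wins; ties break to the smaller product, then the lexicographically
    smaller forward primer.
    """
    constraints = constraints or PrimerConstraints()
    centroid = cluster.centroid
    left, right = centroid.flank_left, centroid.flank_right
    alleles = cluster.alleles or [centroid.repeat_count]
    longest = max(alleles)
    tract_len = longest * cluster.motif_len

    fails = {"gc": 0, "run": 0, "tm": 0, "self_dimer": 0,
             "product": 0, "cross_dimer": 0}
    lo_len, hi_len = constraints.length_range

    # forward candidates: windows fully inside the left flank
    fwd: list[tuple[int, str, float, float]] = []  # (start, seq, tm, gc)
    for ln in range(lo_len, hi_len + 1):
        for s in range(0, len(left) - ln + 1):
            seq = left[s:s + ln]
            res = _window_ok(seq, constraints, fails)
            if res:
                fwd.append((s, seq, res[0], res[1]))
    # reverse candidates: windows fully inside the right flank, reported
    # as the reverse complement (bottom strand, 5'->3')
    rev: list[tuple[int, str, float, float]] = []  # (end offset in right flank, seq, tm, gc)
    for ln in range(lo_len, hi_len + 1):
        for s in range(0, len(right) - ln + 1):
            seq = revcomp(right[s:s + ln])
            res = _window_ok(seq, constraints, fails)
            if res:
                rev.append((s + ln, seq, res[0], res[1]))

    lo_p, hi_p = constraints.product_range
    mid_p = (lo_p + hi_p) / 2.0
    best: tuple[float, int, str, PrimerPair] | None = None
    for fs, fseq, ftm, fgc in fwd:
        # product = left-flank remainder + tract + right-flank prefix
        base = (len(left) - fs) + tract_len
        for re_, rseq, rtm, rgc in rev:
            product = base + re_
            if not lo_p <= product <= hi_p:
                fails["product"] += 1
                continue
            if end_complementarity(fseq, rseq) > constraints.max_end_complementarity:
                fails["cross_dimer"] += 1
                continue
            penalty = (abs(ftm - constraints.tm_optimum)
                       + abs(rtm - constraints.tm_optimum)
                       + abs(ftm - rtm)
                       + 0.1 * abs(product - mid_p))
            key = (penalty, product, fseq)
            if best is None or key < (best[0], best[1], best[2]):
                pair = PrimerPair(
                    forward=fseq, reverse=rseq, tm_f=ftm, tm_r=rtm,
                    gc_f=round(fgc, 2), gc_r=round(rgc, 2),
                    product_size=product, penalty=round(penalty, 4),
                    design_repeat_count=longest,
                )
                best = (penalty, product, fseq, pair)
    return (best[3] if best else None), fails


def validate_pair(pair: PrimerPair, constraints: PrimerConstraints | None = None) -> bool:
    """Independent post-hoc check that a pair meets every hard constraint."""
    c = constraints or PrimerConstraints()
    for seq in (pair.forward, pair.reverse):
        if not c.length_range[0] <= len(seq) <= c.length_range[1]:
            return False
        gc = 100.0 * gc_fraction(seq)
        if not c.gc_range[0] <= gc <= c.gc_range[1]:
            return False
        if max_homopolymer_run(seq) > c.max_run:
            return False
        tm = melting_temperature(seq)
        if not c.tm_range[0] <= tm <= c.tm_range[1]:
            return False
        if end_complementarity(seq, seq) > c.max_end_complementarity:
            return False
    if end_complementarity(pair.forward, pair.reverse) > c.max_end_complementarity:
        return False
    return c.product_range[0] <= pair.product_size <= c.product_range[1]


def expected_products(pair: PrimerPair, alleles: Sequence[int], motif_len: int) -> list[int]:
    """Per-allele amplicon sizes from the design-time product size."""
    return [
        pair.product_size + (a - pair.design_repeat_count) * motif_len
        for a in alleles
    ]


def write_primer_table(rows: Sequence[tuple[int, str, int, PrimerPair]],
                       path: str | Path) -> None:
    """rows: (cluster_id, motif, repeat_count, pair)."""
    with open(path, "w") as fh:
        fh.write("locus\tforward\treverse\tmotif\ttm_f\ttm_r\tproduct_size\n")
        for cluster_id, motif, count, pair in rows:
            fh.write(f"cluster_{cluster_id}\t{pair.forward}\t{pair.reverse}\t"
                     f"({motif}){count}\t{pair.tm_f:.2f}\t{pair.tm_r:.2f}\t"
                     f"{pair.product_size}\n")
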