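"""Flanking-primer design for SSR loci.

A self-contained designer: candidate oligos are enumerated in the repeat's
flanks, filtered against melting-temperature, GC-content, run-length and
complementarity constraints, and pairs are ranked by a weighted penalty.
Melting temperatures come from the unified nearest-neighbor thermodynamic
parameters of Allawi & SantaLucia (1997) with the SantaLucia (1998)
entropic salt correction.

Secondary structure is screened by maximum perfect complementary run
(self-dimer and 3'-anchored), an intentional simplification of full
hairpin/dimer folding.  Amplicon sizes are inclusive of both primer
footprints.  Primer binding is exact-match only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .seqio import SequenceRecord
from .ssr_mining import SSRLocus, reverse_complement

# Allawi & SantaLucia (1997) unified NN parameters.
# dH in kcal/mol, dS in cal/(mol*K); one entry per dinucleotide (a stack and
# its reverse complement share a value by duplex symmetry).
_NN: dict[str, tuple[float, float]] = {
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
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)
_SYM = (0.0, -1.4)
_R = 1.987  # cal/(mol*K)


def melting_temp(
    oligo: str,
    na_mM: float = 50.0,
    dnac1_nM: float = 250.0,
    dnac2_nM: float = 250.0,
) -> float:
    """Nearest-neighbor duplex melting temperature in °C.

    Defaults: 50 mM monovalent cation, 250 nM of each strand.  Deterministic
    and symmetric under reverse complement.
    """
    oligo = oligo.upper()
    if len(oligo) < 8:
        raise ValueError("oligo must be at least 8 nt for NN Tm")
    if set(oligo) - set("ACGT"):
        raise ValueError(f"ambiguous bases in oligo {oligo!r}")
    dh = 0.0
    ds = 0.0
    for end in (oligo[0], oligo[-1]):
        ih, is_ = _INIT_AT if end in "AT" else _INIT_GC
        dh += ih
        ds += is_
    for i in range(len(oligo) - 1):
        h, s = _NN[oligo[i : i + 2]]
        dh += h
        ds += s
    selfcomp = oligo == reverse_complement(oligo)
    if selfcomp:
        dh += _SYM[0]
        ds += _SYM[1]
        ct = dnac1_nM * 1e-9
    else:
        ct = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    ds += 0.368 * (len(oligo) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * dh / (ds + _R * math.log(ct)) - 273.15


def gc_content(oligo: str) -> float:
    """GC percentage of an oligo."""
    oligo = oligo.upper()
    return 100.0 * sum(oligo.count(b) for b in "GC") / len(oligo)


def max_homopolymer_run(oligo: str) -> int:
    best = run = 1
    for a, b in zip(oligo, oligo[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def max_complementary_run(a: str, b: str) -> int:
    """Longest perfect duplex between oligos a and b (longest common
    substring of a and revcomp(b))."""
    rb = reverse_complement(b)
    best = 0
    prev = [0] * (len(rb) + 1)
    for ca in a:
        cur = [0] * (len(rb) + 1)
        for j, cb in enumerate(rb, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def three_prime_complementary_run(a: str, b: str) -> int:
    """Longest 3'-terminal stretch of ``a`` perfectly complementary to some
    window of ``b`` (primer-dimer extension risk)."""
    rb = reverse_complement(b)
    for run in range(len(a), 0, -1):
        if a[-run:] in rb:
            return run
    return 0


@dataclass(frozen=True)
class PrimerParams:
    """Design constraints and scoring weights."""

    min_len: int = 18
    max_len: int = 24
    tm_min: float = 55.0
    tm_max: float = 60.0
    tm_opt: float = 57.5
    gc_min: float = 40.0
    gc_max: float = 60.0
    product_min: int = 100
    product_max: int = 400
    max_self_comp: int = 5
    max_three_prime_comp: int = 3
    max_homopolymer: int = 4
    # penalty weights: per-degree Tm deviation, per-percent GC deviation
    # from 50, per-bp product deviation from mid-range, per-bp of the worst
    # complementarity run
    w_tm: float = 1.0
    w_gc: float = 0.2
    w_product: float = 0.02
    w_comp: float = 0.5

    def __post_init__(self) -> None:
        if not (8 <= self.min_len <= self.max_len):
            raise ValueError("invalid primer length range")
        if self.tm_min > self.tm_max or self.gc_min > self.gc_max:
            raise ValueError("empty Tm or GC range")
        if not (0 < self.product_min <= self.product_max):
            raise ValueError("invalid product size range")


@dataclass(frozen=True)
class PrimerPair:
    """A scored forward/reverse oligo pair on a template.

    ``forward_start`` / ``reverse_end`` are 1-based template positions of
    the forward 5' end and the reverse primer's 3'-most template position
    (= the last base of the amplicon); ``product_size`` spans both primer
    footprints inclusively.  The reverse oligo is given 5'→3' on the
    opposite strand.
    """

    forward: str
    reverse: str
    forward_start: int
    reverse_end: int
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    penalty: float
    product_size: int
    locus: SSRLocus | None = None

    def __post_init__(self) -> None:
        if self.product_size != self.reverse_end - self.forward_start + 1:
            raise ValueError("product_size inconsistent with primer positions")


class InsufficientFlankWarning(UserWarning):
    """The locus lies too close to a template end to fit a primer."""


def _candidate_oligos(
    template: str, lo: int, hi: int, params: PrimerParams
) -> list[tuple[int, str, float, float]]:
    """All constraint-passing oligos fully inside template[lo:hi).

    Returns (start0, oligo, tm, gc), oligo on the + strand.
    """
    out = []
    for start in range(lo, hi):
        for ln in range(params.min_len, params.max_len + 1):
            if start + ln > hi:
                break
            oligo = template[start : start + ln]
            if "N" in oligo:
                continue
            gc = gc_content(oligo)
            if not (params.gc_min <= gc <= params.gc_max):
                continue
            if max_homopolymer_run(oligo) > params.max_homopolymer:
                continue
            tm = melting_temp(oligo)
            if not (params.tm_min <= tm <= params.tm_max):
                continue
            out.append((start, oligo, tm, gc))
    return out


def _oligo_self_ok(oligo: str, params: PrimerParams) -> bool:
    return (
        max_complementary_run(oligo, oligo) <= params.max_self_comp
        and three_prime_complementary_run(oligo, oligo)
        <= params.max_three_prime_comp
    )


def design_primer_pairs(
    template: SequenceRecord,
    locus: SSRLocus,
    params: PrimerParams | None = None,
    n_best: int = 1,
) -> list[PrimerPair]:
    """Design up to ``n_best`` non-redundant primer pairs flanking a locus.

    Pairs satisfy every PrimerParams constraint, never overlap the repeat
    run, and come back sorted by ascending penalty.  An infeasible locus
    (e.g. insufficient flank) yields an empty list with a warning, not an
    exception.
    """
    params = params or PrimerParams()
    seq = template.sequence
    locus_lo = locus.start - 1  # 0-based
    locus_hi = locus.end  # exclusive
    if locus_lo < params.min_len + 1 or len(seq) - locus_hi < params.min_len + 1:
        warnings.warn(
            f"locus {locus.signature} at {template.id}:{locus.start}-"
            f"{locus.end}: flank shorter than a minimal primer",
            InsufficientFlankWarning,
        )
        return []

    # restrict the search window so products can stay within range
    left_lo = max(0, locus_hi - params.product_max)
    fwd = [
        c
        for c in _candidate_oligos(seq, left_lo, locus_lo, params)
        if _oligo_self_ok(c[1], params)
    ]
    right_hi = min(len(seq), locus_lo + params.product_max)
    rev_plus = [
        c
        for c in _candidate_oligos(seq, locus_hi, right_hi, params)
        if _oligo_self_ok(reverse_complement(c[1]), params)
    ]

    mid_product = (params.product_min + params.product_max) / 2.0
    scored: list[PrimerPair] = []
    for f_start, f_oligo, f_tm, f_gc in fwd:
        for r_start, r_plus, r_tm, r_gc in rev_plus:
            product = r_start + len(r_plus) - f_start
            if not (params.product_min <= product <= params.product_max):
                continue
            r_oligo = reverse_complement(r_plus)
            cross = max_complementary_run(f_oligo, r_oligo)
            if cross > params.max_self_comp:
                continue
            three = max(
                three_prime_complementary_run(f_oligo, r_oligo),
                three_prime_complementary_run(r_oligo, f_oligo),
            )
            if three > params.max_three_prime_comp:
                continue
            worst_comp = max(
                cross,
                max_complementary_run(f_oligo, f_oligo),
                max_complementary_run(r_oligo, r_oligo),
            )
            penalty = (
                params.w_tm * (abs(f_tm - params.tm_opt) + abs(r_tm - params.tm_opt))
                + params.w_gc * (abs(f_gc - 50.0) + abs(r_gc - 50.0))
                + params.w_product * abs(product - mid_product)
                + params.w_comp * worst_comp
            )
            scored.append(
                PrimerPair(
                    forward=f_oligo,
                    reverse=r_oligo,
                    forward_start=f_start + 1,
                    reverse_end=r_start + len(r_plus),
                    tm_forward=f_tm,
                    tm_reverse=r_tm,
                    gc_forward=f_gc,
                    gc_reverse=r_gc,
                    penalty=penalty,
                    product_size=product,
                    locus=locus,
                )
            )
    scored.sort(key=lambda p: (p.penalty, p.forward_start, p.reverse_end))
    out: list[PrimerPair] = []
    seen: set[tuple[str, str]] = set()
    for pair in scored:
        key = (pair.forward, pair.reverse)
        if key in seen:
            continue
        seen.add(key)
        out.append(pair)
        if len(out) == n_best:
            break
    return out


@dataclass(frozen=True)
class ProductPrediction:
    """In-silico PCR result on one template (exact-match binding)."""

    status: str  # "unique" | "non-specific" | "no_amplification"
    sizes: tuple[int, ...] = ()

    @property
    def size(self) -> int | None:
        return self.sizes[0] if self.sizes else None


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def predict_product_size(
    template: SequenceRecord,
    pair: PrimerPair,
    product_range: tuple[int, int] | None = None,
) -> ProductPrediction:
    """Predict amplicon size(s) by exact primer matching.

    Valid pairings place the forward site strictly before the reverse
    site's complement and, when ``product_range`` is given, keep the size
    within it.  More than one valid pairing flags the pair non-specific;
    an absent oligo gives "no_amplification".
    """
    seq = template.sequence
    f_sites = _find_all(seq, pair.forward.upper())
    r_sites = _find_all(seq, reverse_complement(pair.reverse.upper()))
    if not f_sites or not r_sites:
        return ProductPrediction("no_amplification")
    sizes = []
    for f in f_sites:
        for r in r_sites:
            end = r + len(pair.reverse)
            size = end - f
            if size < len(pair.forward) + len(pair.reverse):
                continue  # overlapping or inverted sites cannot amplify
            if product_range and not (product_range[0] <= size <= product_range[1]):
                continue
            sizes.append(size)
    if not sizes:
        return ProductPrediction("no_amplification")
    sizes.sort()
    status = "unique" if len(sizes) == 1 else "non-specific"
    return ProductPrediction(status, tuple(sizes))


@dataclass(frozen=True)
class MarkerName:
    """A marker identifier like ``TJIB.Eo_001``."""

    prefix: str
    serial: int

    def __str__(self) -> str:
        return f"{self.prefix}_{self.serial:03d}"


def assign_marker_names(
    pairs: Sequence[PrimerPair], prefix: str = "TJIB.Eo"
) -> list[tuple[MarkerName, PrimerPair]]:
    """Serially number primer pairs in input order (001, 002, ...)."""
    return [(MarkerName(prefix, i), p) for i, p in enumerate(pairs, 1)]
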