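"""Microsatellite (SSR) detection and summary statistics.

The miner finds perfect tandem repeats of primitive motifs (default unit
length 2-10 bp, at least 5 copies), merges nearby runs into compound loci,
groups motifs with their reverse complements for strand-agnostic counting,
and produces the inventory-level summary (counts by motif-length class,
grouped motif unit and total SSR length).

Detection model
---------------
For each motif length k, a maximal periodic interval is a run of positions
where seq[i] == seq[i-k]; the reported locus covers the whole copies of the
unit anchored at the interval's left end.  Motifs that are themselves a
power of a shorter unit are skipped (the shorter period reports them).
Runs are broken at N.  When candidate runs of different unit lengths
overlap, the longer run wins; ties go to the shorter motif, then to the
leftmost start.  Coordinates are 1-based inclusive on the forward strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from .seqio import SequenceRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MOTIF_CLASS_NAMES = {
    1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta",
    6: "hexa", 7: "hepta", 8: "octa", 9: "nona", 10: "deca",
}


def reverse_complement(seq: str) -> str:
    if set(seq) - set("ACGT"):
        raise ValueError(f"invalid alphabet in motif {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True iff the motif is not a whole-number power of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return False
    return True


def default_min_repeats() -> dict[int, int]:
    """Minimum copy number per unit length: 5 for 2-10 bp units, 10 for 1 bp."""
    out = {k: 5 for k in range(2, 11)}
    out[1] = 10
    return out


@dataclass(frozen=True)
class MiningConfig:
    """Detection thresholds.

    ``min_motif_len=1`` enables mono-nucleotide runs (off by default); the
    per-unit-length copy threshold then defaults to 10 for 1 bp units and
    5 for everything else.
    """

    min_motif_len: int = 2
    max_motif_len: int = 10
    min_repeats: Mapping[int, int] = field(default_factory=default_min_repeats)
    compound_max_gap: int = 25

    def __post_init__(self) -> None:
        if not (1 <= self.min_motif_len <= self.max_motif_len <= 10):
            raise ValueError("need 1 <= min_motif_len <= max_motif_len <= 10")
        if self.compound_max_gap < 0:
            raise ValueError("compound_max_gap must be >= 0")
        for k in range(self.min_motif_len, self.max_motif_len + 1):
            if self.min_repeats.get(k, 0) < 2:
                raise ValueError(f"min_repeats[{k}] must be >= 2")


@dataclass(frozen=True)
class SSRLocus:
    """One perfect microsatellite run (1-based inclusive coordinates)."""

    seq_id: str
    start: int
    end: int
    motif: str
    n_repeats: int

    def __post_init__(self) -> None:
        if self.length != self.n_repeats * len(self.motif):
            raise ValueError(
                f"{self.seq_id}:{self.start}-{self.end}: length "
                f"{self.length} != {self.n_repeats} x {len(self.motif)}"
            )
        if not is_primitive(self.motif):
            raise ValueError(f"motif {self.motif!r} is not primitive")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def signature(self) -> str:
        return f"({self.motif}){self.n_repeats}"


@dataclass(frozen=True)
class CompoundSSR:
    """Two or more SSR runs separated by short non-repetitive spacers.

    Rendered as the concatenation of "(motif)n" parts with the spacer
    sequences interleaved in lower case, e.g. ``(CAT)7cttg(CTC)5``.
    """

    seq_id: str
    parts: tuple[SSRLocus, ...]
    gaps: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.parts) < 2:
            raise ValueError("compound SSR needs >= 2 parts")
        if len(self.gaps) != len(self.parts) - 1:
            raise ValueError("need exactly one spacer between consecutive parts")
        for a, b, gap in zip(self.parts, self.parts[1:], self.gaps):
            if b.start <= a.end:
                raise ValueError("compound parts must be ascending, non-overlapping")
            if b.start - a.end - 1 != len(gap):
                raise ValueError("spacer length does not match part coordinates")

    @property
    def start(self) -> int:
        return self.parts[0].start

    @property
    def end(self) -> int:
        return self.parts[-1].end

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def signature(self) -> str:
        out = [self.parts[0].signature]
        for gap, part in zip(self.gaps, self.parts[1:]):
            out.append(gap.lower())
            out.append(part.signature)
        return "".join(out)


AnySSR = Union[SSRLocus, CompoundSSR]


def _periodic_candidates(
    seq: str, seg_start: int, seg_end: int, k: int, min_rep: int
) -> Iterable[tuple[int, int, str, int]]:
    """Yield (start0, end0-exclusive, motif, n) for maximal period-k runs
    inside seq[seg_start:seg_end] with at least min_rep whole copies of a
    primitive unit.  0-based half-open coordinates."""
    s = seg_start
    i = seg_start + k
    while i <= seg_end:
        if i < seg_end and seq[i] == seq[i - k]:
            i += 1
            continue
        # close the interval [s, i)
        n = (i - s) // k
        if n >= min_rep:
            motif = seq[s : s + k]
            if is_primitive(motif):
                yield s, s + n * k, motif, n
        s = i - k + 1
        i += 1


def find_ssrs(record: SequenceRecord, config: MiningConfig | None = None) -> list[SSRLocus]:
    """Detect perfect SSRs in one sequence.

    Returns non-overlapping loci in left-to-right order after resolving
    competing runs of different unit lengths (longest run wins, ties to
    the shorter motif, then to the leftmost start).
    """
    config = config or MiningConfig()
    seq = record.sequence
    # split at N: repeats never span unknown bases
    segments: list[tuple[int, int]] = []
    pos = 0
    for chunk in seq.split("N"):
        if chunk:
            segments.append((pos, pos + len(chunk)))
        pos += len(chunk) + 1

    candidates: list[tuple[int, int, str, int]] = []
    for seg_start, seg_end in segments:
        for k in range(config.min_motif_len, config.max_motif_len + 1):
            if seg_end - seg_start < k * 2:
                continue
            min_rep = config.min_repeats.get(k, 5)
            candidates.extend(
                _periodic_candidates(seq, seg_start, seg_end, k, min_rep)
            )

    # overlap resolution: greedy by (length desc, motif length asc, start asc)
    candidates.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    taken: list[tuple[int, int]] = []
    chosen: list[tuple[int, int, str, int]] = []
    for cand in candidates:
        s, e = cand[0], cand[1]
        if all(e <= ts or s >= te for ts, te in taken):
            taken.append((s, e))
            chosen.append(cand)
    chosen.sort(key=lambda c: c[0])
    return [
        SSRLocus(record.id, s + 1, e, motif, n) for s, e, motif, n in chosen
    ]


def merge_compound(
    loci: Sequence[SSRLocus], record: SequenceRecord, max_gap: int = 25
) -> list[AnySSR]:
    """Merge consecutive loci whose spacer is at most ``max_gap`` nt.

    Loci must be sorted and non-overlapping; unmerged loci pass through.
    """
    for a, b in zip(loci, loci[1:]):
        if b.start <= a.end:
            raise ValueError("loci must be sorted and non-overlapping")
    out: list[AnySSR] = []
    group: list[SSRLocus] = []

    def _flush() -> None:
        if not group:
            return
        if len(group) == 1:
            out.append(group[0])
        else:
            gaps = []
            for a, b in zip(group, group[1:]):
                if b.start - 1 > len(record.sequence):
                    raise IndexError("spacer extends past sequence end")
                gaps.append(record.sequence[a.end : b.start - 1])
            out.append(CompoundSSR(record.id, tuple(group), tuple(gaps)))

    for locus in loci:
        if group and locus.start - group[-1].end - 1 <= max_gap:
            group.append(locus)
        else:
            _flush()
            group = [locus]
    _flush()
    return out


def group_motif(motif: str) -> str:
    """Strand-agnostic motif label pairing a motif with its reverse complement.

    The lexicographically smaller of the two comes first ("AG/CT"); cyclic
    rotations are NOT merged, so "GA" labels as "GA/TC", distinct from
    "AG/CT".  A self-reverse-complementary motif yields "X/X".
    """
    rc = reverse_complement(motif.upper())
    a, b = sorted((motif.upper(), rc))
    return f"{a}/{b}"


@dataclass
class SSRSummary:
    """Inventory-level SSR statistics.

    ``n_ssrs`` counts repeat units: each run inside a compound locus counts
    individually.  ``n_loci`` counts table entries (a compound locus is one
    entry).  Class counts sum to ``n_ssrs``.
    """

    n_sequences_examined: int
    total_bases: int
    n_ssrs: int
    n_loci: int
    n_compound: int
    n_sequences_with_ssr: int
    n_sequences_with_multiple_ssr: int
    by_motif_class: dict[str, int]
    by_motif_group: dict[str, int]
    by_total_length: dict[int, int]

    def motif_class_percentages(self) -> dict[str, float]:
        return motif_class_percentages(self.by_motif_class)


def motif_class_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentages of each class among all SSRs, to 2 decimals."""
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


def _units(entry: AnySSR) -> tuple[SSRLocus, ...]:
    return entry.parts if isinstance(entry, CompoundSSR) else (entry,)


def summarize_ssrs(
    loci: Sequence[AnySSR], records: Sequence[SequenceRecord]
) -> SSRSummary:
    """Summarize a mined SSR set over the sequences it came from."""
    per_seq: Counter[str] = Counter()
    by_class: Counter[str] = Counter()
    by_group: Counter[str] = Counter()
    by_len: Counter[int] = Counter()
    n_units = 0
    n_compound = 0
    for entry in loci:
        if isinstance(entry, CompoundSSR):
            n_compound += 1
        for unit in _units(entry):
            n_units += 1
            per_seq[unit.seq_id] += 1
            by_class[MOTIF_CLASS_NAMES[len(unit.motif)]] += 1
            by_group[group_motif(unit.motif)] += 1
            by_len[unit.length] += 1
    return SSRSummary(
        n_sequences_examined=len(records),
        total_bases=sum(len(r) for r in records),
        n_ssrs=n_units,
        n_loci=len(loci),
        n_compound=n_compound,
        n_sequences_with_ssr=len(per_seq),
        n_sequences_with_multiple_ssr=sum(1 for v in per_seq.values() if v > 1),
        by_motif_class=dict(by_class),
        by_motif_group=dict(by_group),
        by_total_length=dict(by_len),
    )


def mine_fasta(
    records: Sequence[SequenceRecord], config: MiningConfig | None = None
) -> tuple[list[AnySSR], SSRSummary]:
    """Convenience: mine every record, merge compounds, summarize."""
    config = config or MiningConfig()
    all_loci: list[AnySSR] = []
    for rec in records:
        simple = find_ssrs(rec, config)
        all_loci.extend(merge_compound(simple, rec, config.compound_max_gap))
    return all_loci, summarize_ssrs(all_loci, records)


def ssr_table_rows(loci: Sequence[AnySSR]) -> list[dict[str, object]]:
    """Rows for the SSR table TSV (one row per locus entry)."""
    rows = []
    for entry in loci:
        if isinstance(entry, CompoundSSR):
            rows.append(
                dict(
                    seq_id=entry.seq_id, start=entry.start, end=entry.end,
                    motif=";".join(p.motif for p in entry.parts),
                    n_repeats=";".join(str(p.n_repeats) for p in entry.parts),
                    length=entry.length, type="compound",
                    signature=entry.signature,
                )
            )
        else:
            rows.append(
                dict(
                    seq_id=entry.seq_id, start=entry.start, end=entry.end,
                    motif=entry.motif, n_repeats=entry.n_repeats,
                    length=entry.length, type="simple",
                    signature=entry.signature,
                )
            )
    return rows
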