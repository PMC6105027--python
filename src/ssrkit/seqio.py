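"""Sequence I/O and read-quality filtering.

FASTA and FASTQ parsing/writing are delegated to Biopython's ``SeqIO``;
this module adds the alphabet policy (upper-case {A,C,G,T,N} only), gzip
transparency, and the two-rule quality filter used to produce clean reads
from raw transcriptome sequencing output: a read is discarded when more
than ``max_unknown_frac`` of its bases are N, or when more than
``low_q_frac`` of its bases have Phred quality ≤ ``low_q_value``.  Both
thresholds are strict (a read sitting exactly on a threshold is kept).
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_ALPHABET = frozenset("ACGTN")

#: FASTQ is read as Sanger/Illumina-1.8+ (Phred+33).  Scores above this are
#: taken as evidence of a legacy Phred+64 file and rejected outright.
MAX_PLAUSIBLE_PHRED = 62


class DuplicateIdError(ValueError):
    """Two records in one file share an id (strict mode)."""


class AlphabetError(ValueError):
    """A sequence contains a character outside {A,C,G,T,N} (strict mode)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named nucleotide sequence (upper-case A/C/G/T/N)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QualityRead:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: negative Phred score")


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzip-compressed text transparently (magic-byte sniff)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _normalize(seq: str, rec_id: str, strict: bool) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_ALPHABET
    if not bad:
        return seq
    if strict:
        offender = sorted(bad)[0]
        pos = seq.index(offender) + 1
        raise AlphabetError(
            f"record {rec_id!r}: invalid character {offender!r} at "
            f"sequence position {pos} (strict mode)"
        )
    return "".join(c if c in VALID_ALPHABET else "N" for c in seq)


def read_fasta(path: str | Path, strict: bool = True) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file.

    In strict mode characters outside {A,C,G,T,N} and duplicate ids raise;
    in lenient mode invalid characters map to N and duplicate ids get a
    numeric suffix (``id.2``, ``id.3``, ...).
    """
    with _open_text(path) as fh:
        bio_records = list(SeqIO.parse(fh, "fasta"))
    if not bio_records:
        raise ValueError(f"{path}: no FASTA records found")
    seen: Counter[str] = Counter()
    records: list[SequenceRecord] = []
    for rec in bio_records:
        rec_id = rec.id
        seen[rec_id] += 1
        if seen[rec_id] > 1:
            if strict:
                raise DuplicateIdError(f"{path}: duplicate record id {rec_id!r}")
            rec_id = f"{rec_id}.{seen[rec_id]}"
        desc = rec.description[len(rec.id):].strip()
        records.append(
            SequenceRecord(
                id=rec_id,
                sequence=_normalize(str(rec.seq), rec_id, strict),
                description=desc,
            )
        )
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 60
) -> None:
    """Write records as multi-line FASTA; round-trips through read_fasta."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[QualityRead]:
    """Read a (possibly gzipped) Phred+33 FASTQ file."""
    reads: list[QualityRead] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            if quals and max(quals) > MAX_PLAUSIBLE_PHRED:
                raise ValueError(
                    f"{path}: read {rec.id!r} has Phred score {max(quals)} — "
                    "file looks like a legacy Phred+64 encoding; only "
                    "Phred+33 is supported"
                )
            reads.append(
                QualityRead(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=quals,
                )
            )
    return reads


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> None:
    """Write reads as 4-line Phred+33 FASTQ."""
    bio = []
    for r in reads:
        rec = _BioRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        bio.append(rec)
    with open(path, "wt") as fh:
        SeqIO.write(bio, fh, "fastq")


def filter_reads(
    reads: Sequence[QualityRead],
    max_unknown_frac: float = 0.10,
    low_q_value: int = 5,
    low_q_frac: float = 0.50,
) -> tuple[list[QualityRead], dict[str, int]]:
    """Apply the clean-read filter.

    A read is removed iff frac(N) > ``max_unknown_frac`` OR
    frac(Q <= ``low_q_value``) > ``low_q_frac``.  Both comparisons are
    strictly greater-than.  Returns the kept reads (input order, unmodified)
    and a per-reason rejection count; a read failing both rules is counted
    once, under "unknown_fraction".
    """
    kept: list[QualityRead] = []
    report = {"unknown_fraction": 0, "low_quality": 0}
    for read in reads:
        n = len(read.sequence)
        if n == 0:
            kept.append(read)
            continue
        if read.sequence.upper().count("N") / n > max_unknown_frac:
            report["unknown_fraction"] += 1
        elif sum(1 for q in read.qualities if q <= low_q_value) / n > low_q_frac:
            report["low_quality"] += 1
        else:
            kept.append(read)
    return kept, report


def write_filter_report(report: dict[str, int], path: str | Path) -> None:
    """Write the rejection-reason counts as a two-column TSV."""
    with open(path, "wt") as fh:
        fh.write("reason\tcount\n")
        for reason, count in report.items():
            fh.write(f"{reason}\t{count}\n")
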