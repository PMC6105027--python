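"""Marker screening: amplification matrices and polymorphism classification.

A screening experiment records, for each candidate marker and each
accession, whether PCR produced a band ('+'/'-') and, when sized, the
observed fragment lengths.  Classification uses dominant-type scoring:
amplification in some but not all accessions already counts as
polymorphism, and any difference between observed band-size multisets does
too.  Band intensity is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

PRESENT = "+"
ABSENT = "-"


@dataclass
class AmplificationMatrix:
    """markers × accessions presence/absence matrix.

    Cells are '+', '-' or missing (NaN); missing collapses to '-' for
    counting.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate marker ids")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate accession ids")
        values = {
            v for v in self.data.to_numpy().ravel() if isinstance(v, str)
        }
        if not values <= {PRESENT, ABSENT}:
            raise ValueError(f"invalid cell values: {values - {PRESENT, ABSENT}}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AmplificationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")

    @property
    def markers(self) -> list[str]:
        return list(self.data.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.data.columns)


def count_amplification(matrix: AmplificationMatrix) -> dict[str, object]:
    """Amplification summary: markers amplifying in any / all / no accessions.

    ``n_any + n_none == n_markers`` always holds.
    """
    df = matrix.data
    if df.empty:
        raise ValueError("empty amplification matrix")
    present = df.fillna(ABSENT) == PRESENT
    n_any = int(present.any(axis=1).sum())
    n_all = int(present.all(axis=1).sum())
    n_none = int((~present.any(axis=1)).sum())
    return {
        "n_markers": len(df),
        "n_any": n_any,
        "n_all": n_all,
        "n_none": n_none,
        "per_accession": {c: int(present[c].sum()) for c in df.columns},
    }


def classify_marker(profile: Mapping[str, Sequence[int]]) -> str:
    """Classify one marker from its per-accession band-size lists.

    An empty list means no amplification in that accession.  Returns
    'failed' (no accession amplified), 'polymorphic' (band profiles differ,
    or amplification is present in some but not all accessions) or
    'monomorphic'.
    """
    if len(profile) < 2:
        raise ValueError("classification needs at least 2 accessions")
    observed = {acc: tuple(sorted(bands)) for acc, bands in profile.items()}
    amplified = {acc: bands for acc, bands in observed.items() if bands}
    if not amplified:
        return "failed"
    if len(amplified) < len(observed):
        return "polymorphic"
    if len(set(amplified.values())) > 1:
        return "polymorphic"
    return "monomorphic"


def classify_all(
    profiles: Mapping[str, Mapping[str, Sequence[int]]]
) -> tuple[dict[str, str], dict[str, int]]:
    """Classify every marker; returns per-marker labels and summary counts."""
    labels = {m: classify_marker(p) for m, p in profiles.items()}
    counts = {"failed": 0, "monomorphic": 0, "polymorphic": 0}
    for lab in labels.values():
        counts[lab] += 1
    return labels, counts


def read_band_profiles(
    path: str | Path,
) -> dict[str, dict[str, tuple[int, ...]]]:
    """Read a band-profile TSV (rows=markers, columns=accessions, cells
    semicolon-joined sizes; empty cell = no amplification)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out: dict[str, dict[str, tuple[int, ...]]] = {}
    for marker, row in df.iterrows():
        prof = {}
        for acc, cell in row.items():
            if pd.isna(cell) or not str(cell).strip():
                prof[acc] = ()
            else:
                prof[acc] = tuple(
                    sorted(int(x) for x in str(cell).split(";"))
                )
        out[str(marker)] = prof
    return out
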