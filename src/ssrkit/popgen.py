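"""Codominant diversity statistics and Nei genetic distances.

Per-locus statistics over a diploid genotype table (alleles are fragment-
size labels):

* Na — number of distinct alleles
* Ne — effective number of alleles, 1 / Σ Pi²
* Ho — observed heterozygosity, heterozygous typed individuals / typed
* He — expected heterozygosity, 1 − Σ Pi²
* I  — Shannon's information index, −Σ Pi ln Pi (natural log)
* PIC — two variants: ``pic_simple`` = 1 − Σ Pi² (identical to He, the
  simple formula widespread in marker-development reports) and
  ``pic_botstein`` = 1 − Σ Pi² − Σ_{i<j} 2 Pi² Pj² (Botstein et al. 1980)

Nei genetic distance D = −ln I with I = Jxy/√(Jx·Jy), averaging gene
identities over loci (Nei 1972), or with the small-sample correction of
within-population identities (Nei 1978 "unbiased").  When individual
accessions are clustered, each accession is treated as a population of one
diploid individual (allele frequencies in {0, 0.5, 1}).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "./."


class NoSharedAllelesError(ValueError):
    """Two frequency sets share no alleles at any locus (Jxy = 0)."""


@dataclass
class GenotypeTable:
    """accessions × loci table of unordered diploid allele pairs.

    Cells are ``(allele_a, allele_b)`` tuples of string labels or None for
    missing; a homozygote repeats the same label.
    """

    data: pd.DataFrame  # object cells: tuple[str, str] | None

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate accession ids")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate locus ids")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeTable":
        """Read rows=accessions, columns=loci, cells like "165/171" or "./."."""
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(raw.map(_parse_cell))

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.map(
            lambda c: MISSING if c is None else f"{c[0]}/{c[1]}"
        )
        out.to_csv(path, sep="\t")

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    @property
    def loci(self) -> list[str]:
        return list(self.data.columns)

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        df = self.data.loc[:, list(loci)]
        # resampled locus sets may repeat a locus; keep columns unique
        df = df.set_axis(
            [f"{c}.{i}" for i, c in enumerate(df.columns)], axis=1
        )
        return GenotypeTable(df)


def _parse_cell(cell: object) -> tuple[str, str] | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if not text or text == MISSING or text in {".", "-"}:
        return None
    parts = text.split("/")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"malformed genotype cell {text!r}")
    return (parts[0], parts[1])


@dataclass(frozen=True)
class AlleleFrequencies:
    """Allele frequencies at one locus with the typed-sample size."""

    freqs: Mapping[str, float]
    n_typed: int

    def __post_init__(self) -> None:
        if self.n_typed > 0:
            total = sum(self.freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"frequencies sum to {total}, not 1")


def allele_frequencies(table: GenotypeTable, locus: str) -> AlleleFrequencies:
    """Estimate Pi = allele count / (2 × typed individuals) at one locus."""
    column = table.data[locus]
    counts: dict[str, int] = {}
    n_typed = 0
    for cell in column:
        if cell is None:
            continue
        n_typed += 1
        for allele in cell:
            counts[allele] = counts.get(allele, 0) + 1
    if n_typed == 0:
        raise ValueError(f"locus {locus!r}: all genotypes missing")
    total = 2 * n_typed
    return AlleleFrequencies(
        {a: c / total for a, c in sorted(counts.items())}, n_typed
    )


@dataclass(frozen=True)
class LocusStats:
    na: int
    ne: float
    ho: float
    he: float
    shannon_i: float
    pic_simple: float
    pic_botstein: float


def _stats_from_freqs(p: Sequence[float]) -> tuple[float, float, float, float]:
    p = np.asarray(p, dtype=float)
    sum_sq = float(np.sum(p**2))
    ne = 1.0 / sum_sq
    he = 1.0 - sum_sq
    shannon = float(-np.sum(p[p > 0] * np.log(p[p > 0])))
    botstein = he - float(
        sum(
            2.0 * p[i] ** 2 * p[j] ** 2
            for i, j in itertools.combinations(range(len(p)), 2)
        )
    )
    return ne, he, shannon, botstein


def locus_stats(
    freqs: AlleleFrequencies,
    table: GenotypeTable | None = None,
    locus: str | None = None,
) -> LocusStats:
    """Per-locus diversity statistics from allele frequencies.

    Ho needs the genotypes themselves; when ``table``/``locus`` are omitted
    it is reported as NaN.
    """
    p = list(freqs.freqs.values())
    ne, he, shannon, botstein = _stats_from_freqs(p)
    if table is not None and locus is not None:
        column = table.data[locus]
        typed = [c for c in column if c is not None]
        ho = sum(1 for c in typed if c[0] != c[1]) / len(typed)
    else:
        ho = float("nan")
    return LocusStats(
        na=len(p),
        ne=ne,
        ho=ho,
        he=he,
        shannon_i=shannon,
        pic_simple=he,
        pic_botstein=botstein,
    )


def summarize_loci(table: GenotypeTable) -> pd.DataFrame:
    """Per-locus statistics table (columns na, ne, ho, he, i, pic, pic_botstein)."""
    rows = []
    for locus in table.loci:
        freqs = allele_frequencies(table, locus)
        st = locus_stats(freqs, table, locus)
        rows.append(
            dict(
                locus=locus, na=st.na, ne=st.ne, ho=st.ho, he=st.he,
                i=st.shannon_i, pic=st.pic_simple,
                pic_botstein=st.pic_botstein, n_typed=freqs.n_typed,
            )
        )
    return pd.DataFrame(rows).set_index("locus")


def allele_sharing(table: GenotypeTable) -> dict[str, object]:
    """Partition locus-scoped alleles into collection-specific vs shared.

    An allele is collection-specific iff exactly one accession carries it.
    """
    occupancy: dict[tuple[str, str], set[str]] = {}
    for locus in table.loci:
        for accession, cell in table.data[locus].items():
            if cell is None:
                continue
            for allele in cell:
                occupancy.setdefault((locus, allele), set()).add(str(accession))
    specific = sum(1 for accs in occupancy.values() if len(accs) == 1)
    return {
        "collection_specific": specific,
        "shared": len(occupancy) - specific,
        "total": len(occupancy),
        "occupancy": {k: sorted(v) for k, v in occupancy.items()},
    }


FreqSet = Mapping[str, Mapping[str, float]]  # locus -> allele -> Pi


def nei_distance(
    freqs_x: FreqSet,
    freqs_y: FreqSet,
    loci: Iterable[str] | None = None,
    variant: str = "nei1972",
    n_x: int | None = None,
    n_y: int | None = None,
    on_zero_identity: str = "error",
    cap: float = 10.0,
) -> float:
    """Nei genetic distance between two populations' frequency sets.

    ``variant`` is "nei1972" (D = −ln(Jxy/√(Jx·Jy)), J terms averaged over
    loci) or "nei1978_unbiased" (within-population identities corrected to
    (2n Σx² − 1)/(2n − 1); requires sample sizes ``n_x``/``n_y``).  With no
    shared alleles Jxy = 0 and D is undefined (−ln 0): raises by default;
    ``on_zero_identity="inf"`` returns inf, ``"cap"`` returns ``cap`` (a
    finite stand-in larger than any realistic distance, so downstream
    clustering stays defined).
    """
    if variant not in ("nei1972", "nei1978_unbiased"):
        raise ValueError(f"unknown variant {variant!r}")
    loci = list(loci) if loci is not None else sorted(
        set(freqs_x) & set(freqs_y)
    )
    if not loci:
        raise ValueError("no shared loci")
    jxy = jx = jy = 0.0
    for locus in loci:
        px = freqs_x[locus]
        py = freqs_y[locus]
        jxy += sum(px.get(a, 0.0) * py.get(a, 0.0) for a in px)
        sx = sum(v * v for v in px.values())
        sy = sum(v * v for v in py.values())
        if variant == "nei1978_unbiased":
            if not n_x or not n_y:
                raise ValueError("nei1978_unbiased requires sample sizes")
            sx = (2 * n_x * sx - 1) / (2 * n_x - 1)
            sy = (2 * n_y * sy - 1) / (2 * n_y - 1)
        jx += sx
        jy += sy
    L = len(loci)
    jxy /= L
    jx /= L
    jy /= L
    if jxy <= 0:
        if on_zero_identity == "inf":
            return float("inf")
        if on_zero_identity == "cap":
            return cap
        raise NoSharedAllelesError(
            "no shared alleles at any compared locus (Jxy = 0)"
        )
    identity = jxy / math.sqrt(jx * jy)
    return -math.log(identity)


def accession_frequencies(table: GenotypeTable, accession: str) -> FreqSet:
    """Single-individual allele 'frequencies' (values in {0.5, 1}) per locus."""
    out: dict[str, dict[str, float]] = {}
    for locus in table.loci:
        cell = table.data.at[accession, locus]
        if cell is None:
            continue
        a, b = cell
        out[locus] = {a: 1.0} if a == b else {a: 0.5, b: 0.5}
    return out


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if list(d.index) != list(d.columns):
            raise ValueError("row and column ids differ")
        arr = d.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(arr), 0.0):
            raise ValueError("nonzero diagonal")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")

    def to_phylip(self, path: str | Path) -> None:
        """Lower-triangular PHYLIP-style text."""
        ids = list(self.data.index)
        with open(path, "wt") as fh:
            fh.write(f"{len(ids)}\n")
            for i, name in enumerate(ids):
                row = " ".join(
                    f"{self.data.iat[i, j]:.6f}" for j in range(i)
                )
                fh.write(f"{name}\t{row}\n".rstrip() + "\n")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)


def distance_matrix(
    table: GenotypeTable,
    variant: str = "nei1972",
    missing: str = "pairwise",
    on_zero_identity: str = "error",
    cap: float = 10.0,
) -> DistanceMatrix:
    """All-pairs Nei distance over accessions (population of one diploid each).

    ``missing="pairwise"`` drops, for each accession pair, the loci missing
    in either member; ``missing="complete"`` restricts every pair to loci
    typed in all accessions.
    """
    if len(table.accessions) < 2:
        raise ValueError("need at least 2 accessions")
    per_acc = {a: accession_frequencies(table, a) for a in table.accessions}
    if missing == "complete":
        common = set(table.loci)
        for fs in per_acc.values():
            common &= set(fs)
        per_acc = {
            a: {l: fs[l] for l in fs if l in common} for a, fs in per_acc.items()
        }
    elif missing != "pairwise":
        raise ValueError(f"unknown missing-data policy {missing!r}")
    ids = table.accessions
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for x, y in itertools.combinations(ids, 2):
        shared = sorted(set(per_acc[x]) & set(per_acc[y]))
        d = nei_distance(
            per_acc[x], per_acc[y], loci=shared, variant=variant,
            n_x=1, n_y=1, on_zero_identity=on_zero_identity, cap=cap,
        )
        mat.at[x, y] = mat.at[y, x] = d
    return DistanceMatrix(mat)
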