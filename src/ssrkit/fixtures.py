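"""Packaged validation data and seeded synthetic generators.

Two published validation panels for the TJIB.Eo centipedegrass
(*Eremochloa ophiuroides*) SSR marker set ship with the package:

* the screening panel — 100 primer pairs (marker name, SSR signature,
  oligos, expected product size) with their PCR amplification results
  ('+'/'-') in four accessions (E092-1, E092, E022, E039) and the
  polymorphism flags assigned after band inspection;
* the diversity panel — per-locus Na/Ne/Ho/I/PIC statistics of the 50
  polymorphic markers genotyped across 43 core-collection accessions.

The synthetic generators provide ground truth the published data cannot:
``plant_ssrs`` writes repeats at known coordinates into otherwise
repeat-free random sequence, and ``simulate_genotypes`` draws diploid
genotypes from specified allele frequencies under Hardy-Weinberg
proportions.  Both are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popgen import GenotypeTable
from .screening import AmplificationMatrix
from .seqio import SequenceRecord
from .ssr_mining import MiningConfig, SSRLocus, find_ssrs

_ACCESSIONS = ["E092-1", "E092", "E022", "E039"]


def _data_path(name: str):
    return resources.files("ssrkit").joinpath("data").joinpath(name)


def load_screening_panel() -> tuple[pd.DataFrame, AmplificationMatrix, pd.Series]:
    """The 100-marker screening panel.

    Returns the primer table (marker, seq_id, ssr, forward, reverse,
    product_size), the 100×4 amplification matrix, and the boolean
    polymorphism flags.
    """
    with resources.as_file(_data_path("marker_screening.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.set_index("marker")
    primers = df[["seq_id", "ssr", "forward", "reverse", "product_size"]].copy()
    primers["product_size"] = primers["product_size"].astype(int)
    matrix = AmplificationMatrix(df[_ACCESSIONS].copy())
    flags = df["polymorphic"] == "yes"
    return primers, matrix, flags


def load_diversity_panel() -> pd.DataFrame:
    """The 50-marker diversity panel (columns na, ne, ho, i, pic)."""
    with resources.as_file(_data_path("marker_diversity.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    df = df.set_index("marker")
    df["na"] = df["na"].astype(int)
    for col in ("ne", "ho", "i", "pic"):
        df[col] = df[col].astype(float)
    return df


@dataclass(frozen=True)
class PlantRequest:
    """One repeat to write into a generated sequence.

    ``start`` is an optional 1-based position; omitted positions are spread
    evenly along the sequence.
    """

    motif: str
    n_repeats: int
    start: int | None = None


@dataclass
class PlantingManifest:
    """Ground truth of planted repeats: one SSRLocus per planted run."""

    loci: list[SSRLocus] = field(default_factory=list)


def plant_ssrs(
    requests: Mapping[str, Sequence[PlantRequest]],
    seq_length: int = 500,
    seed: int | None = None,
    config: MiningConfig | None = None,
    max_tries: int = 200,
) -> tuple[list[SequenceRecord], PlantingManifest]:
    """Generate sequences containing exactly the requested repeats.

    ``requests`` maps sequence id → planted repeats.  Spacer sequence is
    drawn uniformly from ACGT and resampled until the miner, run with the
    same config used by the caller, detects exactly the planted loci — so
    planted truth equals detectable truth by construction.
    """
    config = config or MiningConfig()
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    manifest = PlantingManifest()
    for seq_id, reqs in requests.items():
        placed = _place(reqs, seq_length)
        for attempt in range(max_tries):
            seq = _fill(placed, seq_length, rng)
            rec = SequenceRecord(id=seq_id, sequence=seq)
            expected = [
                SSRLocus(seq_id, start, start + len(r.motif) * r.n_repeats - 1,
                         r.motif, r.n_repeats)
                for start, r in placed
            ]
            if find_ssrs(rec, config) == expected:
                records.append(rec)
                manifest.loci.extend(expected)
                break
        else:
            raise RuntimeError(
                f"{seq_id}: could not generate repeat-free spacers in "
                f"{max_tries} tries (packing too tight?)"
            )
    return records, manifest


def _place(
    reqs: Sequence[PlantRequest], seq_length: int
) -> list[tuple[int, PlantRequest]]:
    """Assign 1-based start positions, spreading unplaced requests evenly."""
    placed: list[tuple[int, PlantRequest]] = []
    auto = [r for r in reqs if r.start is None]
    fixed = [(r.start, r) for r in reqs if r.start is not None]
    slots = len(auto) + 1
    cursor = 1
    spacing = seq_length // slots if auto else 0
    for i, r in enumerate(auto, 1):
        placed.append((i * spacing - len(r.motif) * r.n_repeats // 2, r))
    placed.extend(fixed)
    placed.sort(key=lambda t: t[0])
    prev_end = 0
    for start, r in placed:
        length = len(r.motif) * r.n_repeats
        if start <= prev_end:
            raise ValueError("planted repeats overlap")
        if start + length - 1 > seq_length:
            raise ValueError("planted repeat does not fit in sequence")
        prev_end = start + length - 1
    return placed


def _fill(
    placed: Sequence[tuple[int, PlantRequest]], seq_length: int,
    rng: np.random.Generator,
) -> str:
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=seq_length))
    for start, r in placed:
        run = (r.motif * r.n_repeats)
        seq[start - 1 : start - 1 + len(run)] = list(run)
    return "".join(seq)


@dataclass(frozen=True)
class SimSpec:
    """A genotype-simulation request.

    ``loci`` maps locus id → allele-frequency mapping (must sum to 1).
    Genotypes are two independent draws per individual (Hardy-Weinberg);
    cells are masked missing at ``missing_rate``.
    """

    n_accessions: int
    loci: Mapping[str, Mapping[str, float]]
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_accessions < 1:
            raise ValueError("need at least one accession")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        for locus, freqs in self.loci.items():
            if not freqs:
                raise ValueError(f"locus {locus!r}: empty frequency vector")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"locus {locus!r}: negative frequency")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"locus {locus!r}: frequencies must sum to 1")


def simulate_genotypes(spec: SimSpec) -> GenotypeTable:
    """Draw a diploid genotype table from the spec's allele frequencies."""
    rng = np.random.default_rng(spec.seed)
    accessions = [f"acc{i+1:03d}" for i in range(spec.n_accessions)]
    data: dict[str, list[tuple[str, str] | None]] = {}
    for locus, freqs in spec.loci.items():
        alleles = sorted(freqs)
        p = np.array([freqs[a] for a in alleles])
        p = p / p.sum()
        draws = rng.choice(len(alleles), size=(spec.n_accessions, 2), p=p)
        mask = rng.random(spec.n_accessions) < spec.missing_rate
        cells: list[tuple[str, str] | None] = []
        for i in range(spec.n_accessions):
            if mask[i]:
                cells.append(None)
            else:
                a, b = sorted((alleles[draws[i, 0]], alleles[draws[i, 1]]))
                cells.append((a, b))
        data[locus] = cells
    df = pd.DataFrame(data, index=accessions, dtype=object)
    return GenotypeTable(df)


def two_cluster_spec(
    n_per_cluster: int = 10,
    n_loci: int = 20,
    divergence: float = 0.9,
    seed: int | None = None,
) -> tuple[SimSpec, SimSpec]:
    """Specs for two diverged populations sharing a locus set.

    Each locus is biallelic; cluster A has the first allele at frequency
    ``divergence``, cluster B at ``1 - divergence``.  Useful for testing
    that clustering recovers planted structure.
    """
    loci = {
        f"L{i+1:02d}": {"150": divergence, "156": 1.0 - divergence}
        for i in range(n_loci)
    }
    loci_b = {
        locus: {"150": 1.0 - divergence, "156": divergence}
        for locus in loci
    }
    seed_a, seed_b = (None, None) if seed is None else (seed, seed + 1)
    return (
        SimSpec(n_per_cluster, loci, seed=seed_a),
        SimSpec(n_per_cluster, loci_b, seed=seed_b),
    )


def merge_tables(a: GenotypeTable, b: GenotypeTable, prefixes=("A", "B")) -> GenotypeTable:
    """Stack two genotype tables over the same loci, prefixing accession ids."""
    da = a.data.rename(index=lambda s: f"{prefixes[0]}_{s}")
    db = b.data.rename(index=lambda s: f"{prefixes[1]}_{s}")
    return GenotypeTable(pd.concat([da, db]))
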