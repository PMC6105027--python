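"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles, by exhaustive
enumeration, instead of sharing code with the package.
"""

from __future__ import annotations

import itertools
import math


def brute_force_ssrs(
    seq: str,
    min_motif_len: int,
    max_motif_len: int,
    min_repeats: dict[int, int],
) -> list[tuple[int, int, str, int]]:
    """Quadratic SSR scan testing every (start, motif_len) pair.

    Returns non-overlapping loci as (start1, end1, motif, n_repeats) with
    1-based inclusive coordinates, after the same published resolution
    rule: longest run wins, ties to shorter motif, then leftmost.
    """
    n = len(seq)
    candidates = []
    for k in range(min_motif_len, max_motif_len + 1):
        for s in range(0, n - 2 * k + 1):
            motif = seq[s : s + k]
            if "N" in motif:
                continue
            # primitive motifs only
            if any(
                k % d == 0 and motif[: d] * (k // d) == motif
                for d in range(1, k)
            ):
                continue
            # left-maximality: the periodic run must not extend left
            if s > 0 and seq[s - 1] == seq[s + k - 1]:
                continue
            reps = 1
            while seq[s + reps * k : s + (reps + 1) * k] == motif:
                reps += 1
            if reps >= min_repeats.get(k, 5):
                candidates.append((s, s + reps * k, motif, reps))
    candidates.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    chosen: list[tuple[int, int, str, int]] = []
    for cand in candidates:
        if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
            chosen.append(cand)
    chosen.sort()
    return [(s + 1, e, m, r) for s, e, m, r in chosen]


def brute_force_upgma(labels: list[str], d: list[list[float]]):
    """UPGMA that recomputes every cluster-pair mean from raw leaf
    distances at each step.  Returns (clade frozenset -> height) map."""
    clusters: list[frozenset[str]] = [frozenset([l]) for l in labels]
    idx = {l: i for i, l in enumerate(labels)}
    heights: dict[frozenset[str], float] = {}

    def cdist(a: frozenset[str], b: frozenset[str]) -> float:
        return sum(d[idx[x]][idx[y]] for x in a for y in b) / (len(a) * len(b))

    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            key = (cdist(clusters[i], clusters[j]), i, j)
            if best is None or key < best:
                best = key
        dist, i, j = best
        merged = clusters[i] | clusters[j]
        heights[merged] = dist / 2.0
        clusters = [c for t, c in enumerate(clusters) if t not in (i, j)]
        clusters.append(merged)
    return heights


def nn_tm_oracle(oligo: str, na_mM=50.0, dnac1_nM=250.0, dnac2_nM=250.0) -> float:
    """Hand-summed nearest-neighbor Tm (Allawi & SantaLucia 1997 unified
    table, SantaLucia 1998 entropic salt correction), written independently
    of the package."""
    dH = {"AA": -7.9, "AT": -7.2, "TA": -7.2, "CA": -8.5, "GT": -8.4,
          "CT": -7.8, "GA": -8.2, "CG": -10.6, "GC": -9.8, "GG": -8.0}
    dS = {"AA": -22.2, "AT": -20.4, "TA": -21.3, "CA": -22.7, "GT": -22.4,
          "CT": -21.0, "GA": -22.2, "CG": -27.2, "GC": -24.4, "GG": -19.9}
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}

    def canon(pair: str) -> str:
        if pair in dH:
            return pair
        return comp[pair[1]] + comp[pair[0]]

    h = s = 0.0
    for end in (oligo[0], oligo[-1]):
        if end in "AT":
            h += 2.3
            s += 4.1
        else:
            h += 0.1
            s += -2.8
    for i in range(len(oligo) - 1):
        key = canon(oligo[i : i + 2])
        h += dH[key]
        s += dS[key]
    rc = "".join(comp[c] for c in reversed(oligo))
    if oligo == rc:
        s += -1.4
        ct = dnac1_nM * 1e-9
    else:
        ct = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    s += 0.368 * (len(oligo) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * h / (s + 1.987 * math.log(ct)) - 273.15


def random_test_sequence(rng, length: int) -> str:
    """A sequence mixing uniform stretches with repeat-rich stretches (copy
    numbers straddling the detection threshold) and occasional Ns."""
    out = []
    pos = 0
    while pos < length:
        mode = rng.random()
        if mode < 0.5:
            chunk = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 60))))
        elif mode < 0.9:
            k = int(rng.integers(1, 7))
            motif = "".join(rng.choice(list("ACGT"), size=k))
            reps = int(rng.integers(2, 10))
            chunk = motif * reps
        else:
            chunk = "N" * int(rng.integers(1, 4))
        out.append(chunk)
        pos += len(chunk)
    seq = "".join(out)[:length]
    # avoid a trailing lone fragment shorter than a motif
    return seq if seq.strip("N") else "ACGT" * (length // 4 + 1)
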