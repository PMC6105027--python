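import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssrkit.fixtures import SimSpec, simulate_genotypes
from ssrkit.popgen import (
    AlleleFrequencies,
    DistanceMatrix,
    GenotypeTable,
    NoSharedAllelesError,
    allele_frequencies,
    allele_sharing,
    distance_matrix,
    locus_stats,
    nei_distance,
    summarize_loci,
)


def freq_set(p: list[float]) -> AlleleFrequencies:
    return AlleleFrequencies({f"a{i}": v for i, v in enumerate(p)}, n_typed=10)


class TestAlleleFrequencies:
    def test_two_heterozygotes(self):
        df = pd.DataFrame({"L": [("A", "B"), ("A", "B")]}, index=["x", "y"],
                          dtype=object)
        f = allele_frequencies(GenotypeTable(df), "L")
        assert f.freqs == {"A": 0.5, "B": 0.5} and f.n_typed == 2

    def test_missing_excluded_from_denominator(self):
        df = pd.DataFrame({"L": [("A", "A"), ("A", "B"), None]},
                          index=["x", "y", "z"], dtype=object)
        f = allele_frequencies(GenotypeTable(df), "L")
        assert f.freqs == {"A": 0.75, "B": 0.25} and f.n_typed == 2

    def test_frequencies_sum_to_one(self, rng):
        spec = SimSpec(30, {"L": {"a": 0.2, "b": 0.3, "c": 0.5}}, seed=5)
        table = simulate_genotypes(spec)
        f = allele_frequencies(table, "L")
        assert sum(f.freqs.values()) == pytest.approx(1.0, abs=1e-12)
        step = 1.0 / (2 * f.n_typed)
        for v in f.freqs.values():
            assert (v / step) == pytest.approx(round(v / step), abs=1e-9)

    def test_all_missing_locus_rejected(self):
        df = pd.DataFrame({"L": [None, None]}, index=["x", "y"], dtype=object)
        with pytest.raises(ValueError):
            allele_frequencies(GenotypeTable(df), "L")

    def test_tsv_round_trip(self, tmp_path, tiny_genotypes):
        p = tmp_path / "g.tsv"
        tiny_genotypes.to_tsv(p)
        again = GenotypeTable.from_tsv(p)
        assert again.data.equals(tiny_genotypes.data)


class TestLocusStats:
    def test_symmetric_biallelic_closed_form(self):
        st_ = locus_stats(freq_set([0.5, 0.5]))
        assert st_.na == 2
        assert st_.ne == pytest.approx(2.0)
        assert st_.he == st_.pic_simple == pytest.approx(0.5)
        assert st_.shannon_i == pytest.approx(math.log(2))
        assert st_.pic_botstein == pytest.approx(0.375)

    def test_monomorphic_locus(self):
        st_ = locus_stats(freq_set([1.0]))
        assert (st_.na, st_.ne, st_.he, st_.shannon_i, st_.pic_botstein) == (
            1, 1.0, 0.0, 0.0, 0.0)

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_uniform_k_alleles(self, k):
        st_ = locus_stats(freq_set([1.0 / k] * k))
        assert st_.ne == pytest.approx(k)
        assert st_.shannon_i == pytest.approx(math.log(k))
        assert st_.he == pytest.approx(1 - 1 / k)

    def test_observed_heterozygosity_from_genotypes(self, tiny_genotypes):
        f = allele_frequencies(tiny_genotypes, "L1")
        st_ = locus_stats(f, tiny_genotypes, "L1")
        assert st_.ho == pytest.approx(1 / 3)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8)
    )
    def test_botstein_pic_never_exceeds_he(self, raw):
        p = [v / sum(raw) for v in raw]
        st_ = locus_stats(freq_set(p))
        assert st_.pic_botstein <= st_.pic_simple + 1e-12
        assert 1.0 <= st_.ne <= st_.na + 1e-9
        assert st_.shannon_i <= math.log(st_.na) + 1e-9

    def test_invariant_under_allele_relabeling(self):
        a = locus_stats(freq_set([0.2, 0.3, 0.5]))
        b = locus_stats(AlleleFrequencies({"z": 0.5, "q": 0.2, "m": 0.3}, 10))
        assert a.ne == pytest.approx(b.ne)
        assert a.shannon_i == pytest.approx(b.shannon_i)

    def test_parameter_recovery_at_n500(self):
        true_he = 0.5
        spec = SimSpec(500, {"L": {"a": 0.5, "b": 0.5}}, seed=123)
        table = simulate_genotypes(spec)
        stats = summarize_loci(table)
        assert abs(stats.loc["L", "he"] - true_he) < 0.05
        assert abs(stats.loc["L", "ho"] - 0.5) < 0.07  # HW expectation 2pq


class TestAlleleSharing:
    def test_planted_private_allele(self):
        df = pd.DataFrame(
            {"L": [("A", "Z"), ("A", "A"), ("A", "A")]},
            index=["x", "y", "z"], dtype=object,
        )
        res = allele_sharing(GenotypeTable(df))
        assert res["collection_specific"] == 1  # Z only in x
        assert res["shared"] == 1  # A in all

    def test_partition_equals_total_na(self, rng):
        spec = SimSpec(
            20,
            {f"L{i}": {"a": 0.4, "b": 0.35, "c": 0.25} for i in range(5)},
            seed=9,
        )
        table = simulate_genotypes(spec)
        res = allele_sharing(table)
        total_na = int(summarize_loci(table)["na"].sum())
        assert res["collection_specific"] + res["shared"] == total_na

    def test_occupancy_manifest(self):
        df = pd.DataFrame(
            {"L1": [("A", "A"), ("B", "B")], "L2": [("C", "C"), ("C", "C")]},
            index=["x", "y"], dtype=object,
        )
        res = allele_sharing(GenotypeTable(df))
        assert res["occupancy"][("L1", "A")] == ["x"]
        assert res["occupancy"][("L2", "C")] == ["x", "y"]


class TestNeiDistance:
    def test_identical_populations_zero(self):
        f = {"L1": {"a": 0.3, "b": 0.7}, "L2": {"c": 1.0}}
        assert nei_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_single_locus_example(self):
        x = {"L": {"a": 1.0, "b": 0.0}}
        y = {"L": {"a": 0.5, "b": 0.5}}
        # Jxy=0.5, Jx=1, Jy=0.5, I=0.5/sqrt(0.5), D=-ln I = ln sqrt(2)
        assert nei_distance(x, y) == pytest.approx(0.34657359, abs=1e-4)

    def test_disjoint_alleles_flagged(self):
        x = {"L": {"a": 1.0}}
        y = {"L": {"b": 1.0}}
        with pytest.raises(NoSharedAllelesError):
            nei_distance(x, y)
        assert nei_distance(x, y, on_zero_identity="inf") == math.inf

    def test_unbiased_variant_needs_sizes_and_corrects(self):
        x = {"L": {"a": 0.6, "b": 0.4}}
        y = {"L": {"a": 0.5, "b": 0.5}}
        with pytest.raises(ValueError):
            nei_distance(x, y, variant="nei1978_unbiased")
        d72 = nei_distance(x, y)
        d78 = nei_distance(x, y, variant="nei1978_unbiased", n_x=20, n_y=20)
        # the correction shrinks within-population identity, so D drops
        assert d78 < d72

    def test_hand_computed_three_accession_matrix(self):
        df = pd.DataFrame(
            {
                "L1": [("A", "A"), ("A", "B"), ("B", "B")],
                "L2": [("C", "C"), ("C", "C"), ("C", "D")],
            },
            index=["x", "y", "z"], dtype=object,
        )
        dm = distance_matrix(GenotypeTable(df))
        # x: L1 {A:1}, L2 {C:1};  y: L1 {A:.5,B:.5}, L2 {C:1}
        # Jxy=(0.5+1)/2=0.75, Jx=(1+1)/2=1, Jy=(0.5+1)/2=0.75
        # I=0.75/sqrt(0.75)=sqrt(0.75), D=-0.5*ln(0.75)
        assert dm.data.at["x", "y"] == pytest.approx(-0.5 * math.log(0.75), abs=1e-12)
        # x vs z: L1 disjoint ({A:1} vs {B:1}), L2 {C:1} vs {C:.5,D:.5}
        # Jxy=(0+0.5)/2=0.25, Jx=(1+1)/2=1, Jz=(1+0.5)/2=0.75
        assert dm.data.at["x", "z"] == pytest.approx(
            -math.log(0.25 / math.sqrt(0.75)), abs=1e-12
        )

    def test_matrix_symmetric_zero_diagonal(self):
        spec = SimSpec(8, {f"L{i}": {"a": 0.5, "b": 0.5} for i in range(6)},
                       seed=3)
        table = simulate_genotypes(spec)
        dm = distance_matrix(table, on_zero_identity="inf")
        arr = dm.data.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)

    def test_identical_accessions_zero_off_diagonal(self):
        df = pd.DataFrame(
            {"L1": [("A", "B"), ("A", "B")], "L2": [("C", "C"), ("C", "C")]},
            index=["x", "y"], dtype=object,
        )
        dm = distance_matrix(GenotypeTable(df))
        assert dm.data.at["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_pairwise_missing_policy(self):
        df = pd.DataFrame(
            {"L1": [("A", "A"), ("A", "A"), ("B", "B")],
             "L2": [("C", "C"), None, ("C", "C")]},
            index=["x", "y", "z"], dtype=object,
        )
        dm = distance_matrix(GenotypeTable(df), on_zero_identity="inf")
        # x-y compare on L1 only -> identical
        assert dm.data.at["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_accession_order_invariance(self, tiny_genotypes):
        dm1 = distance_matrix(tiny_genotypes)
        shuffled = GenotypeTable(tiny_genotypes.data.iloc[[2, 0, 1]])
        dm2 = distance_matrix(shuffled)
        for a in "xyz":
            for b in "xyz":
                assert dm1.data.at[a, b] == pytest.approx(dm2.data.at[a, b])

    def test_phylip_output(self, tmp_path, tiny_genotypes):
        dm = distance_matrix(tiny_genotypes)
        p = tmp_path / "d.phy"
        dm.to_phylip(p)
        lines = p.read_text().splitlines()
        assert lines[0] == "3"
        assert lines[1].startswith("x")
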