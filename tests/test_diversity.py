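"""Diversity estimators: h, k, pi, and the frequency tables."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hv1pop.diversity import (
    DiversityError,
    FrequencySpectrum,
    haplogroup_table,
    haplotype_diversity,
    mean_pairwise_differences,
    mean_pairwise_differences_from_spectrum,
    nucleotide_diversity,
    nucleotide_diversity_variance,
    round_half_up,
)
from hv1pop.haplotyping import CallResult, hamming_distance


def _call(sample_id, name):
    return CallResult(sample_id, name, name[0], None, False, 0, frozenset())


counts_strategy = st.dictionaries(
    st.text(alphabet="ABC", min_size=1, max_size=3).map(lambda s: "A" + s),
    st.integers(min_value=1, max_value=20),
    min_size=1,
    max_size=6,
)


class TestHaplotypeDiversity:
    def test_monomorphic_is_zero(self):
        h, sd = haplotype_diversity(FrequencySpectrum({"A1": 7}))
        assert h == 0.0 and sd == 0.0

    def test_two_haplotypes_n4(self):
        """Uniform two-haplotype spectrum at n=4: h = (4/3)(1 - 1/2) = 2/3,
        cross-checked by enumerating ordered pairs (8 of 12 differ)."""
        h, _ = haplotype_diversity(FrequencySpectrum({"A1": 2, "A2": 2}))
        assert h == pytest.approx(2 / 3, abs=1e-12)
        labels = ["A1", "A1", "A2", "A2"]
        pairs = [(i, j) for i in range(4) for j in range(4) if i != j]
        # fraction of differing *ordered* pairs is the unbiased estimate itself
        frac_diff = sum(labels[i] != labels[j] for i, j in pairs) / len(pairs)
        assert frac_diff == pytest.approx(h)

    def test_n2_sd_closed_form(self):
        # counts {1,1}: sum p^2 = 1/2, sum p^3 = 1/4
        # V = (2/(2*1)) * (0 + 1/2 - 1/4) = 1/4 -> sd = 1/2
        h, sd = haplotype_diversity(FrequencySpectrum({"A1": 1, "A2": 1}))
        assert h == 1.0
        assert sd == pytest.approx(0.5, abs=1e-12)

    def test_n_below_2_is_error(self):
        with pytest.raises(DiversityError):
            haplotype_diversity(FrequencySpectrum({"A1": 1}))

    @given(counts_strategy)
    def test_invariant_under_relabeling(self, counts):
        if sum(counts.values()) < 2:
            counts["A1"] = counts.get("A1", 0) + 2
        relabeled = {f"X{i}": c for i, c in enumerate(counts.values())}
        assert haplotype_diversity(FrequencySpectrum(counts)) == pytest.approx(
            haplotype_diversity(FrequencySpectrum(relabeled))
        )

    @given(counts_strategy)
    def test_uniform_spectrum_maximises_h(self, counts):
        """For fixed H and n, h is maximal at the (near-)uniform spectrum."""
        n, H = sum(counts.values()), len(counts)
        if n < 2:
            return
        h, _ = haplotype_diversity(FrequencySpectrum(counts))
        base, extra = divmod(n, H)
        uniform = {f"U{i}": base + (1 if i < extra else 0) for i in range(H)}
        h_uni, _ = haplotype_diversity(FrequencySpectrum(uniform))
        assert h <= h_uni + 1e-12


class TestPairwiseDifferences:
    def test_two_sequences(self):
        k, _ = mean_pairwise_differences(["AAATTT", "AAAGGG"])
        assert k == 3.0

    def test_three_sequences_brute_force(self):
        seqs = ["AAAA", "AAAT", "AATT"]
        k, _ = mean_pairwise_differences(seqs)
        pairs = list(itertools.combinations(seqs, 2))
        oracle = sum(hamming_distance(a, b) for a, b in pairs) / len(pairs)
        assert k == pytest.approx(oracle) == pytest.approx(4 / 3)

    def test_spectrum_route_matches_sequence_route(self):
        """k from (spectrum, haplotype distance matrix) equals the
        sequence-by-sequence computation."""
        rng = np.random.default_rng(5)
        haps = {f"A{i}": "".join(rng.choice(list("ACGT"), 12)) for i in range(4)}
        counts = {"A0": 3, "A1": 1, "A2": 4, "A3": 2}
        seqs = [haps[name] for name, c in counts.items() for _ in range(c)]
        k_seq, _ = mean_pairwise_differences(seqs)
        distances = {
            (a, b): hamming_distance(haps[a], haps[b])
            for a, b in itertools.combinations(haps, 2)
        }
        k_spec = mean_pairwise_differences_from_spectrum(
            FrequencySpectrum(counts), distances
        )
        assert k_spec == pytest.approx(k_seq, abs=1e-12)

    def test_variance_formula_value(self):
        # V(k) = [3n(n+1)k + 2(n^2+n+3)k^2] / [11(n^2-7n+6)] at k=2, n=10
        k, sd = mean_pairwise_differences(["AATT"] * 5 + ["AAGG"] * 5)
        assert k == pytest.approx(2 * 25 / 45)
        n = 10
        expected = (3 * n * 11 * k + 2 * (n * n + n + 3) * k * k) / (11 * (n * n - 70 + 6))
        assert sd == pytest.approx(math.sqrt(expected))


class TestNucleotideDiversity:
    def test_definition(self):
        pi, _ = nucleotide_diversity(["AAATTT" + "A" * 576, "AAAGGG" + "A" * 576], 582)
        assert pi == pytest.approx(3 / 582)

    def test_identical_sequences(self):
        pi, sd = nucleotide_diversity(["ACGT"] * 4, 4)
        assert pi == 0.0 and sd == 0.0

    def test_pi_times_length_equals_k(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(8)]
        k, _ = mean_pairwise_differences(seqs)
        pi, _ = nucleotide_diversity(seqs, 40)
        assert pi * 40 == pytest.approx(k, abs=1e-12)

    def test_variance_requires_valid_inputs(self):
        with pytest.raises(DiversityError):
            nucleotide_diversity_variance(0.01, 1, 582)
        with pytest.raises(DiversityError):
            nucleotide_diversity_variance(0.01, 10, 0)


class TestHaplogroupTable:
    def test_toy_counts_and_percentages(self):
        calls = [_call("s1", "A1"), _call("s2", "A2"), _call("s3", "B1")]
        grouping = {"s1": "G", "s2": "G", "s3": "G"}
        table = haplogroup_table(calls, grouping)
        row = table[table.group == "G"].iloc[0]
        assert row["n_A"] == 2 and row["pct_A"] == 66.7
        assert row["n_B"] == 1 and row["pct_B"] == 33.3
        assert row["nHT"] == 3

    def test_unique_haplotype_counts(self):
        calls = [_call("s1", "A1"), _call("s2", "A1"), _call("s3", "B1")]
        grouping = {"s1": "G1", "s2": "G2", "s3": "G2"}
        table = haplogroup_table(calls, grouping).set_index("group")
        assert table.loc["G1", "nUnique"] == 0  # A1 shared with G2
        assert table.loc["G2", "nUnique"] == 1  # B1 only in G2
        assert table.loc["Total", "nHT"] == 2

    def test_missing_sample_is_error(self):
        with pytest.raises(DiversityError, match="s2"):
            haplogroup_table([_call("s1", "A1"), _call("s2", "A1")], {"s1": "G"})

    def test_rounding_half_up(self):
        assert round_half_up(5.45, 1) == 5.5
        assert round_half_up(90.909, 1) == 90.9
        assert round_half_up(15.1515, 1) == 15.2
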