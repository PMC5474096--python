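"""Abundance normalisation, diversity, Bray-Curtis and the Mantel test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from marvd import (
    AbundanceMatrix,
    CoverageTable,
    DistanceMatrix,
    alpha_diversity,
    bray_curtis,
    mantel,
    normalize_abundance,
)

from _oracles import brute_force_mantel_p


def coverage_table(rows, read_bases, lengths):
    return CoverageTable(
        rows=pd.DataFrame(rows, columns=["sample_id", "contig_id", "depth_sum"]),
        sample_read_bases=read_bases,
        contig_lengths=lengths,
    )


class TestNormalizeAbundance:
    def test_stated_formula_hand_arithmetic(self):
        cov = coverage_table([("s1", "p1", 10_000.0)], {"s1": 1e9}, {"p1": 10_000})
        linear = normalize_abundance(cov, scale=1e9)
        assert linear.values.loc["p1", "s1"] == pytest.approx(1.0)
        logged = normalize_abundance(cov, scale=1e9, log=True)
        assert logged.values.loc["p1", "s1"] == pytest.approx(math.log10(2), abs=1e-4)

    def test_zero_coverage_maps_to_zero_in_both_transforms(self):
        cov = coverage_table([("s1", "p1", 0.0)], {"s1": 1e9}, {"p1": 5_000})
        assert normalize_abundance(cov).values.loc["p1", "s1"] == 0.0
        assert normalize_abundance(cov, log=True).values.loc["p1", "s1"] == 0.0

    def test_ratio_invariance_under_joint_doubling(self):
        cov1 = coverage_table([("s1", "p1", 4000.0)], {"s1": 2e8}, {"p1": 8_000})
        cov2 = coverage_table([("s1", "p1", 8000.0)], {"s1": 4e8}, {"p1": 8_000})
        v1 = normalize_abundance(cov1).values.loc["p1", "s1"]
        v2 = normalize_abundance(cov2).values.loc["p1", "s1"]
        assert v1 == pytest.approx(v2)

    def test_zero_length_or_read_bases_named_in_error(self):
        cov = coverage_table([("s1", "p1", 10.0)], {"s1": 1e9}, {"p1": 0})
        with pytest.raises(ValueError, match="p1"):
            normalize_abundance(cov)
        cov = coverage_table([("s1", "p1", 10.0)], {"s1": 0.0}, {"p1": 100})
        with pytest.raises(ValueError, match="s1"):
            normalize_abundance(cov)

    def test_missing_pairs_filled_with_zero(self):
        cov = coverage_table([("s1", "p1", 100.0), ("s2", "p2", 50.0)],
                             {"s1": 1e8, "s2": 1e8}, {"p1": 1000, "p2": 1000})
        m = normalize_abundance(cov)
        assert m.values.loc["p2", "s1"] == 0.0 and m.values.loc["p1", "s2"] == 0.0


class TestAlphaDiversity:
    def test_uniform_vector(self):
        d = alpha_diversity([1, 1, 1, 1])
        assert d.richness == 4
        assert d.shannon == pytest.approx(math.log(4))
        assert d.pielou == pytest.approx(1.0)

    def test_single_population_has_undefined_evenness(self):
        d = alpha_diversity([2, 0, 0])
        assert (d.richness, d.shannon, d.pielou) == (1, 0.0, None)

    def test_all_zero_vector(self):
        d = alpha_diversity([0.0, 0.0])
        assert (d.richness, d.shannon, d.pielou) == (0, 0.0, None)

    def test_four_to_one_split_hand_arithmetic(self):
        d = alpha_diversity([4, 1])
        expected = -(0.8 * math.log(0.8) + 0.2 * math.log(0.2))
        assert d.shannon == pytest.approx(expected, abs=1e-4)
        assert d.pielou == pytest.approx(expected / math.log(2), abs=1e-4)

    def test_log_base_option(self):
        d = alpha_diversity([1, 1], base=2)
        assert d.shannon == pytest.approx(1.0)

    @given(arrays(float, st.integers(2, 12),
                  elements=st.floats(0.0, 1e6, allow_nan=False)))
    def test_shannon_bounded_by_log_richness(self, x):
        d = alpha_diversity(x)
        if d.richness >= 1:
            assert d.shannon <= math.log(d.richness) + 1e-9
        if d.pielou is not None:
            assert 0.0 <= d.pielou <= 1.0 + 1e-9

    def test_shannon_agrees_with_scipy_entropy(self):
        from scipy.stats import entropy

        x = np.array([5.0, 3.0, 0.0, 2.0, 1.0])
        d = alpha_diversity(x)
        assert d.shannon == pytest.approx(entropy(x[x > 0] / x[x > 0].sum()))


def matrix_from(values, samples):
    frame = pd.DataFrame(values, columns=samples)
    frame.index = [f"p{i}" for i in range(len(frame))]
    return AbundanceMatrix(values=frame, transform="linear")


class TestBrayCurtis:
    def test_identity_and_disjoint_support(self):
        m = matrix_from({"s1": [1.0, 2.0, 0.0], "s2": [1.0, 2.0, 0.0],
                         "s3": [0.0, 0.0, 5.0]}, ["s1", "s2", "s3"])
        d = bray_curtis(m)
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        m = matrix_from({"x": [1.0, 2.0], "y": [3.0, 0.0]}, ["x", "y"])
        # fails DistanceMatrix needs >= 2 samples; 2 is fine
        d = bray_curtis(m)
        assert d.values[0, 1] == pytest.approx(4.0 / 6.0, abs=1e-6)

    def test_empty_samples_zero_by_convention(self):
        m = matrix_from({"a": [0.0, 0.0], "b": [0.0, 0.0], "c": [1.0, 0.0]},
                        ["a", "b", "c"])
        d = bray_curtis(m)
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == 1.0

    @given(arrays(float, (4, 5), elements=st.floats(0.0, 1e3, allow_nan=False)))
    def test_output_satisfies_distance_matrix_invariants(self, data):
        m = matrix_from(pd.DataFrame(data.T, columns=list("abcd")).to_dict("list"),
                        list("abcd"))
        d = bray_curtis(m)  # DistanceMatrix validates symmetry/diagonal itself
        assert np.all(d.values >= -1e-12) and np.all(d.values <= 1.0 + 1e-12)

    def test_rejects_log_transformed_matrix(self):
        frame = pd.DataFrame({"s1": [0.1], "s2": [0.2]}, index=["p0"])
        with pytest.raises(ValueError):
            bray_curtis(AbundanceMatrix(values=frame, transform="log10"))


def random_distance(rng, n, labels=None):
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = rng.uniform(0.05, 1.0, size=len(iu[0]))
    m += m.T
    return DistanceMatrix(values=m, labels=tuple(labels or (f"s{i}" for i in range(n))))


class TestMantel:
    def test_identical_matrices_give_r_one(self):
        d = random_distance(np.random.default_rng(0), 6)
        r, p = mantel(d, d, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_affine_transform_gives_r_one(self):
        d1 = random_distance(np.random.default_rng(1), 6)
        d2 = DistanceMatrix(values=0.5 * d1.values + 0.2 * (d1.values > 0),
                            labels=d1.labels)
        r, _ = mantel(d1, d2, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)

    def test_label_mismatch_is_an_error(self):
        d1 = random_distance(np.random.default_rng(2), 4, labels=list("abcd"))
        d2 = random_distance(np.random.default_rng(3), 4, labels=list("abce"))
        with pytest.raises(ValueError, match="labels"):
            mantel(d1, d2)

    def test_p_value_in_half_open_unit_interval_and_seeded(self):
        rng = np.random.default_rng(4)
        d1, d2 = random_distance(rng, 6), random_distance(rng, 6)
        r1, p1 = mantel(d1, d2, n_perm=199, seed=11)
        r2, p2 = mantel(d1, d2, n_perm=199, seed=11)
        assert (r1, p1) == (r2, p2)
        assert 0.0 < p1 <= 1.0

    def test_r_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(5)
        d1, d2 = random_distance(rng, 5), random_distance(rng, 5)
        perm = np.array([3, 1, 4, 0, 2])
        relabel = lambda d: DistanceMatrix(
            values=d.values[np.ix_(perm, perm)],
            labels=tuple(d.labels[i] for i in perm))
        r_base, _ = mantel(d1, d2, n_perm=49, seed=0)
        r_perm, _ = mantel(relabel(d1), relabel(d2), n_perm=49, seed=0)
        assert r_base == pytest.approx(r_perm)

    def test_monte_carlo_p_tracks_exhaustive_permutation_p(self):
        """With many permutations the estimate approaches the exact p over all n!."""
        rng = np.random.default_rng(6)
        d1, d2 = random_distance(rng, 5), random_distance(rng, 5)
        r_obs, p_mc = mantel(d1, d2, n_perm=4999, seed=7)
        p_exact = brute_force_mantel_p(d1.values, d2.values, r_obs)
        assert p_mc == pytest.approx(p_exact, abs=0.03)

    def test_too_few_samples_rejected(self):
        d = random_distance(np.random.default_rng(7), 2)
        with pytest.raises(ValueError, match="at least 3"):
            mantel(d, d)
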