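"""Model core: cell probabilities, likelihoods, and exact moments."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tolmpt import (
    CELLS,
    ClassMixture,
    Dataset,
    MPTParams,
    SubjectCounts,
    cell_success_probability,
    enumerate_support,
    expected_cell_means,
    mixture_log_likelihood,
    model_covariance,
    subject_log_likelihood,
)

from conftest import random_mixture

probability = st.floats(0.0, 1.0, allow_nan=False)


class TestCellProbability:
    @pytest.mark.parametrize(
        "params, cell_idx, expected",
        [
            ((0.76, 0.82, 0.78), 0, 0.76),        # baseline cell returns b
            ((0.71, 0.78, 0.0), 2, 0.0),          # s = 0 floors the SD cell
            ((0.76, 0.82, 0.78), 3, 0.486096),    # HH multiplies all three
            ((0.5, 1.0, 1.0), 1, 0.5),            # g = 1 leaves GA at baseline
        ],
    )
    def test_known_values(self, params, cell_idx, expected):
        p = MPTParams(*params)
        assert cell_success_probability(p, CELLS[cell_idx]) == pytest.approx(expected, abs=1e-12)

    @given(b=probability, g=probability, s=probability)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_probabilities_stay_in_unit_interval(self, b, g, s):
        probs = MPTParams(b, g, s).cell_probabilities()
        assert np.all(probs >= 0.0) and np.all(probs <= 1.0)
        # g = s = 1 collapses every cell to the baseline
        flat = MPTParams(b, 1.0, 1.0).cell_probabilities()
        assert np.allclose(flat, b)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MPTParams(1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            MPTParams(0.5, -0.1, 0.5)


class TestSubjectLogLikelihood:
    def test_certain_success(self):
        ll = subject_log_likelihood(SubjectCounts((2, 2, 2, 2)), MPTParams(1, 1, 1))
        assert ll == 0.0

    def test_hand_computed_half(self):
        # per cell P(x=1 | T=2, p=.5) = .5, so the total is 4 ln(.5)
        ll = subject_log_likelihood(SubjectCounts((1, 1, 1, 1)), MPTParams(0.5, 1, 1))
        assert ll == pytest.approx(4 * math.log(0.5), abs=1e-12)

    def test_impossible_observation_is_minus_inf(self):
        ll = subject_log_likelihood(SubjectCounts((0, 0, 1, 0)), MPTParams(0.71, 0.78, 0.0))
        assert ll == -np.inf

    def test_count_validation(self):
        with pytest.raises(ValueError):
            SubjectCounts((3, 0, 0, 0), T=2)


class TestMixtureLogLikelihood:
    def test_single_class_equals_sum_of_subject_logliks(self, small_dataset, one_class_mixture):
        expected = sum(
            subject_log_likelihood(x, one_class_mixture.params[0], T=2)
            for x in small_dataset.counts
        )
        assert mixture_log_likelihood(small_dataset, one_class_mixture) == pytest.approx(expected)

    def test_degenerate_weight_reduces_to_one_class(self, small_dataset):
        p1, p2 = MPTParams(0.8, 0.9, 0.7), MPTParams(0.3, 0.4, 0.5)
        mix = ClassMixture((1.0, 0.0), (p1, p2), T=2)
        only1 = ClassMixture((1.0,), (p1,), T=2)
        assert mixture_log_likelihood(small_dataset, mix) == pytest.approx(
            mixture_log_likelihood(small_dataset, only1)
        )

    def test_matches_brute_force_pmf(self, small_dataset, study_mixture):
        # oracle: exact mixture pmf per subject from first principles
        total = 0.0
        for x in small_dataset.counts:
            prob = 0.0
            for w, p in zip(study_mixture.weights, study_mixture.params):
                cellp = p.cell_probabilities()
                term = w
                for xc, pc in zip(x, cellp):
                    term *= math.comb(2, xc) * pc**xc * (1 - pc) ** (2 - xc)
                prob += term
            total += math.log(prob)
        assert mixture_log_likelihood(small_dataset, study_mixture) == pytest.approx(total, rel=1e-12)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            Dataset(np.empty((0, 4), dtype=int), T=2)


class TestMoments:
    def test_expected_means_single_class(self):
        mix = ClassMixture((1.0,), (MPTParams(0.76, 1, 1),), T=2)
        assert expected_cell_means(mix)[0] == pytest.approx(1.52)

    def test_identical_classes_collapse(self):
        p = MPTParams(0.7, 0.8, 0.9)
        two = ClassMixture((0.3, 0.7), (p, p), T=2)
        one = ClassMixture((1.0,), (p,), T=2)
        assert np.allclose(expected_cell_means(two), expected_cell_means(one))
        assert np.allclose(model_covariance(two), model_covariance(one))

    def test_floor_class_contributes_nothing_to_high_sd_cells(self):
        mix = ClassMixture((1.0,), (MPTParams(0.71, 0.78, 0.0),), T=2)
        mu = expected_cell_means(mix)
        assert mu[2] == 0.0 and mu[3] == 0.0

    def test_one_class_covariance_is_diagonal_binomial(self):
        cov = model_covariance(ClassMixture((1.0,), (MPTParams(0.5, 1, 1),), T=2))
        assert np.allclose(cov, np.eye(4) * 0.5)

    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_moments_match_enumeration_oracle(self, K):
        rng = np.random.default_rng(2024 + K)
        for _ in range(5):
            mix = random_mixture(rng, K)
            outcomes, pmf = enumerate_support(mix)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
            mu = (pmf[:, None] * outcomes).sum(axis=0)
            dev = outcomes - mu
            cov = np.einsum("m,mc,md->cd", pmf, dev, dev)
            assert np.allclose(mu, expected_cell_means(mix), atol=1e-10)
            assert np.allclose(cov, model_covariance(mix), atol=1e-10)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_covariance_symmetric_psd(self, seed):
        rng = np.random.default_rng(seed)
        mix = random_mixture(rng, int(rng.integers(1, 4)))
        cov = model_covariance(mix)
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_flat_demands_make_cells_exchangeable(self):
        mix = ClassMixture(
            (0.4, 0.6), (MPTParams(0.8, 1.0, 1.0), MPTParams(0.3, 1.0, 1.0)), T=2
        )
        mu = expected_cell_means(mix)
        cov = model_covariance(mix)
        assert np.allclose(mu, mu[0])
        assert np.allclose(np.diag(cov), cov[0, 0])
        off = cov[~np.eye(4, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_point_mass_when_all_parameters_one(self):
        outcomes, pmf = enumerate_support(ClassMixture((1.0,), (MPTParams(1, 1, 1),), T=2))
        top = np.all(outcomes == 2, axis=1)
        assert pmf[top] == pytest.approx(1.0)
        assert pmf[~top].max() == pytest.approx(0.0, abs=1e-15)

    def test_support_guard(self):
        big = ClassMixture((1.0,), (MPTParams(0.5, 0.5, 0.5),), T=100)
        with pytest.raises(ValueError):
            enumerate_support(big)
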