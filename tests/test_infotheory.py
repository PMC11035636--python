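import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import halolipidome as hl
from halolipidome.composition import CompositionProfile
from halolipidome.io import ValidationError

from oracles import naive_infotheory


def _freq(values, lipids=None, samples=None):
    values = np.asarray(values, dtype=float)
    lipids = lipids or [f"l{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return hl.FrequencyMatrix(P=pd.DataFrame(values, index=lipids, columns=samples))


def _random_freq(rng, m=20, t=6):
    raw = rng.random((m, t))
    return _freq(raw / raw.sum(axis=0))


class TestDiversity:
    def test_uniform_eight_lipids_is_three_bits(self):
        H = hl.diversity(_freq(np.full((8, 1), 1 / 8)))
        assert H.iloc[0] == 3.0

    def test_degenerate_distribution_is_zero(self):
        H = hl.diversity(_freq([[1.0], [0.0]]))
        assert H.iloc[0] == 0.0

    def test_half_quarter_quarter(self):
        H = hl.diversity(_freq([[0.5], [0.25], [0.25]]))
        assert H.iloc[0] == pytest.approx(1.5, abs=1e-15)


class TestSpecificity:
    def test_equal_frequency_lipid_has_zero_specificity(self):
        S, _ = hl.specificity(_freq(np.full((4, 5), 1 / 4)))
        assert np.allclose(S.to_numpy(), 0.0)

    def test_private_lipid_reaches_log2_t(self):
        # one lipid present in exactly 1 of 8 samples
        P = np.full((2, 8), 1.0 / 1)
        P[0] = [1.0] + [0.0] * 7
        P[1] = [0.0] + [1.0] * 7
        S, _ = hl.specificity(_freq(P))
        assert S.iloc[0] == 3.0  # log2(8), exact

    def test_two_sample_closed_form(self):
        # frequencies (0.2, 0.1): S = (1/2)[(4/3)log2(4/3) + (2/3)log2(2/3)]
        P = np.array([[0.2, 0.1], [0.8, 0.9]])
        S, S_cond = hl.specificity(_freq(P))
        expected = 0.5 * ((4 / 3) * math.log2(4 / 3) + (2 / 3) * math.log2(2 / 3))
        assert S.iloc[0] == pytest.approx(expected, abs=1e-15)
        assert expected == pytest.approx(0.0817042, abs=1e-7)
        # S_ij is the un-averaged summand
        assert S_cond.iloc[0, 0] == pytest.approx((4 / 3) * math.log2(4 / 3), abs=1e-15)

    def test_absent_lipids_dropped_with_warning(self):
        P = _freq([[1.0, 1.0], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="absent"):
            S, _ = hl.specificity(P)
        assert list(S.index) == ["l0"]


class TestSpecialization:
    def test_ubiquitous_uniform_lipidome_has_zero_delta(self):
        freq = _freq(np.full((6, 4), 1 / 6))
        S, _ = hl.specificity(freq)
        delta = hl.specialization(freq, S)
        assert np.allclose(delta.to_numpy(), 0.0)

    def test_disjoint_ownership_reaches_log2_t(self):
        freq = _freq(np.eye(8))
        S, _ = hl.specificity(freq)
        delta = hl.specialization(freq, S)
        assert np.all(delta.to_numpy() == 3.0)  # log2(8), exact

    def test_delta_is_convex_combination_of_specificities(self):
        rng = np.random.default_rng(4)
        freq = _random_freq(rng)
        S, _ = hl.specificity(freq)
        delta = hl.specialization(freq, S)
        assert (delta.to_numpy() >= S.min() - 1e-12).all()
        assert (delta.to_numpy() <= S.max() + 1e-12).all()

    def test_dimension_mismatch_rejected(self):
        freq = _freq(np.full((3, 2), 1 / 3))
        with pytest.raises(ValidationError):
            hl.specialization(freq, pd.Series([0.1], index=["l0"]))


class TestAgainstNaiveOracle:
    def test_matches_loop_implementation_to_1e12(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            freq = _random_freq(rng)
            H_o, _, S_o, S_cond_o, delta_o = naive_infotheory(freq.P.to_numpy())
            assert np.allclose(hl.diversity(freq).to_numpy(), H_o, atol=1e-12, rtol=0)
            S, S_cond = hl.specificity(freq)
            assert np.allclose(S.to_numpy(), S_o, atol=1e-12, rtol=0)
            assert np.allclose(S_cond.to_numpy(), S_cond_o, atol=1e-12, rtol=0)
            assert np.allclose(
                hl.specialization(freq, S).to_numpy(), delta_o, atol=1e-12, rtol=0
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 99_999))
    def test_bounds_and_label_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        m, t = int(rng.integers(2, 15)), int(rng.integers(2, 8))
        raw = rng.random((m, t)) + 1e-12
        freq = _freq(raw / raw.sum(axis=0))
        H = hl.diversity(freq)
        S, _ = hl.specificity(freq)
        delta = hl.specialization(freq, S)
        assert ((H.to_numpy() >= -1e-12) & (H.to_numpy() <= math.log2(m) + 1e-9)).all()
        assert ((S.to_numpy() >= -1e-12) & (S.to_numpy() <= math.log2(t) + 1e-9)).all()
        assert ((delta.to_numpy() >= -1e-12) & (delta.to_numpy() <= math.log2(t) + 1e-9)).all()
        # permuting sample labels permutes H and delta identically
        perm = rng.permutation(t)
        freq_p = _freq(freq.P.to_numpy()[:, perm])
        assert np.allclose(hl.diversity(freq_p).to_numpy(), H.to_numpy()[perm])
        S_p, _ = hl.specificity(freq_p)
        assert np.allclose(
            hl.specialization(freq_p, S_p).to_numpy(), delta.to_numpy()[perm]
        )


class TestFrequencyMatrix:
    def _profile(self, values, features):
        rel = pd.DataFrame(values, index=features, columns=["s1", "s2"], dtype=float)
        return CompositionProfile(relative_abundance=rel)

    def test_identity_when_already_closed(self):
        prof = self._profile([[0.5, 0.3], [0.5, 0.7]], ["a", "b"])
        freq = hl.frequency_matrix(prof)
        pd.testing.assert_frame_equal(freq.P, prof.relative_abundance)

    def test_universe_restriction_recloses_columns(self):
        prof = self._profile([[0.5, 0.3], [0.25, 0.4], [0.25, 0.3]], ["a", "b", "c"])
        freq = hl.frequency_matrix(prof, universe=["a", "b"])
        assert np.allclose(freq.P.sum(axis=0).to_numpy(), 1.0)
        assert freq.m == 2

    def test_mean_frequency_definition(self):
        prof = self._profile([[0.6, 0.2], [0.4, 0.8]], ["a", "b"])
        Pi = hl.frequency_matrix(prof).mean_frequency()
        assert Pi["a"] == pytest.approx(0.4)

    def test_empty_universe_sample_is_an_error(self):
        prof = self._profile([[1.0, 0.0], [0.0, 1.0]], ["a", "b"])
        with pytest.raises(ValidationError, match="zero total"):
            hl.frequency_matrix(prof, universe=["a"])


class TestErrorbars:
    def _profile_for(self, H_targets):
        # build samples with controlled diversity by varying evenness
        cols = {}
        for i, target in enumerate(H_targets):
            cols[f"s{i}"] = target
        rel = pd.DataFrame(cols, index=[f"l{j}" for j in range(len(H_targets[0]))])
        return CompositionProfile(relative_abundance=rel)

    def test_identical_replicates_have_zero_sd(self):
        prof = self._profile_for([[0.5, 0.5], [0.5, 0.5]])
        out = hl.bootstrap_errorbars(prof, {"g": ["s0", "s1"]})
        assert out.loc["g", "H_sd"] == 0.0

    def test_mean_and_sd_of_two_known_replicates(self):
        # H(s0)=2 bits (uniform over 4), H(s1)=4 bits (uniform over 16)
        col0 = [0.25] * 4 + [0.0] * 12
        col1 = [1 / 16] * 16
        prof = self._profile_for([col0, col1])
        out = hl.bootstrap_errorbars(prof, {"g": ["s0", "s1"]})
        assert out.loc["g", "H_mean"] == pytest.approx(3.0)
        assert out.loc["g", "H_sd"] == pytest.approx(math.sqrt(2.0))

    def test_single_replicate_sd_is_missing_not_zero(self):
        prof = self._profile_for([[0.5, 0.5]])
        out = hl.bootstrap_errorbars(prof, {"g": ["s0"]})
        assert np.isnan(out.loc["g", "H_sd"])

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(0)
        raw = rng.random((10, 4))
        rel = pd.DataFrame(raw / raw.sum(axis=0), columns=[f"s{i}" for i in range(4)])
        prof = CompositionProfile(relative_abundance=rel)
        groups = {"g": [f"s{i}" for i in range(4)]}
        a = hl.bootstrap_errorbars(prof, groups, n_boot=50, seed=9)
        b = hl.bootstrap_errorbars(prof, groups, n_boot=50, seed=9)
        pd.testing.assert_frame_equal(a, b)
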