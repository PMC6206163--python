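"""Walk statistics: estimator contracts and oracle equivalence on small inputs.

The heavy simulation-based checks (Brownian Hurst, DFA scaling laws, fGn
recovery, logistic-map Lyapunov) live in test_acceptance.py; here each
estimator is pinned to its definition and its brute-force oracle.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, reject, settings
from hypothesis import strategies as st

from enhwalk import (
    WALK_FEATURE_NAMES,
    autocorrelation,
    build_walk,
    dfa_exponent,
    extended_stats,
    hurst_rs,
    lyapunov_max,
    rvntsl,
    sample_entropy,
    walk_features,
)
from enhwalk.errors import DegenerateSeriesError
from enhwalk.walkfeat import SampEnParams, pairwise_feature_correlation

from oracles import naive_autocorrelation, naive_extended_stats, naive_sample_entropy

dna = st.text(alphabet="ACGT", min_size=428, max_size=600)


def _random_walk(rng, n=500):
    return np.cumsum(rng.choice([-1.0, 1.0], size=n))


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        assert autocorrelation(_random_walk(rng), 0) == 1.0

    def test_constant_series_undefined(self):
        with pytest.raises(DegenerateSeriesError):
            autocorrelation(np.ones(200), 100)

    def test_too_short_for_lag(self):
        with pytest.raises(DegenerateSeriesError):
            autocorrelation(np.arange(50.0), 100)

    @pytest.mark.parametrize("lag", [1, 37, 100])
    def test_matches_two_loop_oracle(self, rng, lag):
        w = _random_walk(rng, 500)
        assert autocorrelation(w, lag) == pytest.approx(
            naive_autocorrelation(w, lag), abs=1e-9
        )

    def test_bounded(self, rng):
        w = _random_walk(rng, 1500)
        for lag in (100, 200, 300):
            assert -1.0 <= autocorrelation(w, lag) <= 1.0


class TestRvntsl:
    def test_examples(self):
        assert rvntsl(build_walk("CC").walk) == 1.0
        assert rvntsl(build_walk("CACA").walk) == 0.5

    def test_empty(self):
        with pytest.raises(DegenerateSeriesError):
            rvntsl(np.array([]))

    def test_uncorrelated_walk_magnitude(self, rng):
        # enhancer-length (428-1500 bp) uncorrelated walks attain a few
        # percent of their length as distinct levels
        lens = rng.integers(428, 1501, size=200)
        vals = [rvntsl(np.cumsum(rng.choice([-1, 1], size=L))) for L in lens]
        assert 0.03 <= np.mean(vals) <= 0.10


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.ones(50), SampEnParams(m=2, r=0.5)) == 0.0

    def test_ramp_matches_bruteforce(self):
        x = np.arange(1.0, 101.0)
        r = 0.2 * x.std(ddof=1)
        assert sample_entropy(x, SampEnParams(m=2, r=r)) == pytest.approx(
            naive_sample_entropy(x, 2, r), abs=1e-12, nan_ok=True
        )

    def test_walk_matches_bruteforce(self, random_seq):
        w = build_walk(random_seq(500)).walk.astype(float)
        r = 0.2 * w.std(ddof=1)
        assert sample_entropy(w, SampEnParams(m=2, r=r)) == pytest.approx(
            naive_sample_entropy(w, 2, r), abs=1e-12
        )

    def test_periodicity_lowers_entropy(self, rng):
        noise = rng.standard_normal(400)
        periodic = np.sin(np.arange(400) * 0.3)
        assert sample_entropy(periodic) < sample_entropy(noise)

    def test_too_short(self):
        with pytest.raises(DegenerateSeriesError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), SampEnParams(m=2, r=1.0))


class TestHurst:
    def test_degenerate_homopolymer(self):
        with pytest.raises(DegenerateSeriesError):
            hurst_rs(build_walk("C" * 1500).steps.astype(float))

    def test_fit_exposes_curve(self, rng):
        fit = hurst_rs(rng.choice([-1.0, 1.0], size=1024))
        assert list(fit.chunk_sizes) == [8, 16, 32, 64, 128, 256, 512]
        assert np.all(fit.rescaled_ranges > 0)
        assert np.isfinite(fit.K)

    def test_uncorrected_exceeds_corrected_on_brownian(self, rng):
        # the raw R/S slope carries a positive finite-sample bias
        steps = rng.choice([-1.0, 1.0], size=1500)
        assert hurst_rs(steps, corrected=False).K > hurst_rs(steps, corrected=True).K


class TestDFA:
    def test_exactly_detrendable_input_is_degenerate(self):
        # a constant input has an identically-zero profile: every scale's
        # fluctuation vanishes and is dropped, leaving nothing to fit
        with pytest.raises(DegenerateSeriesError):
            dfa_exponent(np.full(400, 3.0))

    def test_too_short(self):
        with pytest.raises(DegenerateSeriesError):
            dfa_exponent(np.ones(50))

    def test_fit_structure(self, rng):
        fit = dfa_exponent(rng.standard_normal(1000))
        assert fit.poly_order == 1
        assert np.all(fit.fluctuations > 0)
        assert len(fit.window_sizes) >= 4
        assert fit.window_sizes.max() <= 250


class TestLyapunov:
    def test_sinusoid_not_chaotic(self):
        t = np.sin(np.linspace(0, 60 * np.pi, 2000))
        fit = lyapunov_max(t, lag=1, emb_dim=10, min_tsep=40, fit_range=(1, 10))
        assert fit.lambda_max <= 0.05

    def test_matches_allpairs_oracle(self, random_seq):
        from oracles import naive_lyapunov_curve

        w = build_walk(random_seq(300)).walk.astype(float)
        fit = lyapunov_max(w, lag=2, emb_dim=5, min_tsep=2, traj_len=10, fit_range=(1, 10))
        oracle_curve = naive_lyapunov_curve(w, lag=2, emb_dim=5, min_tsep=2, traj_len=10)
        np.testing.assert_allclose(fit.divergence_curve, oracle_curve, atol=1e-9)
        ks = np.arange(1, 11)
        lam = np.polyfit(ks, oracle_curve, 1)[0]
        assert fit.lambda_max == pytest.approx(lam, abs=1e-9)

    def test_too_short_to_embed(self):
        with pytest.raises(DegenerateSeriesError):
            lyapunov_max(np.arange(30.0), lag=5, emb_dim=10)


class TestExtendedStats:
    def test_mean_crossing_of_alternating_walk(self):
        x = np.tile([1.0, 0.0], 50)
        assert extended_stats(x)["mean_crossing_rate"] == 1.0

    def test_zero_crossing_of_symmetric_walk(self):
        x = np.tile([1.0, -1.0], 50)
        assert extended_stats(x)["zero_crossing_rate"] == 1.0

    def test_matches_direct_formulas(self, rng):
        w = _random_walk(rng, 500)
        got = extended_stats(w)
        want = naive_extended_stats(w)
        assert set(got) == set(want)
        for key in want:
            assert got[key] == pytest.approx(want[key], abs=1e-9), key

    def test_degenerate_moments_missing(self):
        out = extended_stats(np.zeros(100))
        assert np.isnan(out["skewness"]) and np.isnan(out["kurtosis"])
        assert np.isnan(out["spectral_entropy"])
        assert out["zero_crossing_rate"] == 0.0

    def test_pairwise_correlation_shape(self, rng):
        rows = rng.standard_normal((40, 5))
        C = pairwise_feature_correlation(rows)
        assert C.shape == (5, 5)
        np.testing.assert_allclose(np.diag(C), 1.0)


class TestWalkFeatures:
    def test_canonical_order_and_count(self, random_seq):
        wf = walk_features(build_walk(random_seq(1500)))
        names = tuple(f.name for f in dataclasses.fields(wf))
        assert names == WALK_FEATURE_NAMES
        assert len(names) == 8

    def test_deterministic(self, random_seq):
        w = build_walk(random_seq(800))
        a, b = walk_features(w), walk_features(w)
        np.testing.assert_array_equal(a.as_array(), b.as_array())

    def test_homopolymer_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            walk_features(build_walk("C" * 1500))

    def test_too_short(self, random_seq):
        with pytest.raises(DegenerateSeriesError):
            walk_features(build_walk(random_seq(301)))

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(dna)
    def test_finite_on_enhancer_length_sequences(self, seq):
        try:
            wf = walk_features(build_walk(seq))
        except DegenerateSeriesError:
            reject()  # near-homopolymer draws are legitimately undefined
        arr = wf.as_array()
        assert np.all(np.isfinite(arr))
        assert 0 < wf.rvntsl <= 1
        for v in (wf.ac, wf.ac_200, wf.ac_300):
            assert -1 <= v <= 1
        assert wf.sampen >= 0
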