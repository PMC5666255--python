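import numpy as np
import pytest

from haplostat import Alignment, coalsim, mismatch
from haplostat.errors import DomainError, IdentifiabilityError
from haplostat.mismatch import MismatchHistogram


class TestObservedMismatch:
    def test_identical_sequences_all_zero_class(self):
        aln = Alignment.from_dict({f"s{i}": "ACGT" for i in range(1, 5)})
        h = mismatch.observed_mismatch(aln)
        assert list(h.counts) == [6]
        assert h.n_pairs == 6

    def test_toy4_histogram(self, toy4):
        h = mismatch.observed_mismatch(toy4)
        assert list(h.counts) == [1, 3, 2]

    def test_mean_equals_pi_bar_contract(self, toy4):
        from haplostat import pairwise_diversity

        h = mismatch.observed_mismatch(toy4)
        assert h.mean == pytest.approx(pairwise_diversity(toy4)[0])

    def test_expansion_histograms_unimodal_on_average(self, rng):
        """Recent-expansion simulations yield smooth unimodal mismatch waves."""
        spec = coalsim.SimulationSpec(
            n_per_deme=(60,), theta=None, theta0=0.05, theta1=30.0, tau=4.0
        )
        acc = np.zeros(60)
        for _ in range(60):
            c = coalsim.simulate_mismatch(spec, rng)
            acc[: c.size] += c / c.sum()
        acc /= 60
        peak = int(np.argmax(acc))
        assert 1 <= peak <= 8  # a mode away from zero...
        assert np.all(np.diff(acc[peak:20]) <= 1e-3)  # ...decaying beyond it


class TestExpectedSudden:
    def test_tau_zero_collapses_to_initial_equilibrium(self):
        out = mismatch.expected_sudden(0.0, 0.5, 10.0, 25, normalize=False)
        assert np.allclose(out, mismatch.equilibrium_mismatch(0.5, 25))

    def test_large_tau_converges_to_final_equilibrium(self):
        out = mismatch.expected_sudden(1e3, 0.5, 4.0, 30, normalize=False)
        assert np.allclose(out, mismatch.equilibrium_mismatch(4.0, 30), atol=1e-9)

    @pytest.mark.parametrize("theta", [0.5, 1.0, 8.9])
    def test_equilibrium_sums_to_one_untruncated(self, theta):
        # geometric series: truncation point chosen far into the tail
        total = mismatch.equilibrium_mismatch(theta, 2000).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_proper_distribution_on_parameter_grid(self):
        """Raw model mass is non-negative with partial sums bounded by 1."""
        for tau in (0.0, 0.5, 3.0, 10.0, 25.0):
            for theta0, theta1 in ((0.1, 10.0), (1.0, 1.0), (5.0, 0.5), (0.0, 50.0)):
                out = mismatch.expected_sudden(tau, theta0, theta1, 400, normalize=False)
                assert np.all(out >= 0)
                assert np.all(np.cumsum(out) <= 1 + 1e-9)

    def test_negative_parameters_rejected(self):
        with pytest.raises(DomainError):
            mismatch.expected_sudden(-1.0, 0.1, 10.0, 20)

    def test_theta1_zero_limit(self):
        out = mismatch.expected_sudden(2.0, 0.5, 0.0, 10)
        assert out[0] == pytest.approx(1.0)


class TestExpectedSpatial:
    def test_panmictic_limit_matches_sudden(self):
        spa = mismatch.expected_spatial(3.0, 1.0, 1e6, 60)
        sud = mismatch.expected_sudden(3.0, 1.0, 1e9, 60)
        assert np.abs(spa - sud).max() < 1e-4

    def test_tau_zero_is_deme_equilibrium(self):
        spa = mismatch.expected_spatial(0.0, 2.0, 7.0, 40, normalize=False)
        assert np.allclose(spa, mismatch.equilibrium_mismatch(2.0, 40), atol=1e-12)

    def test_normalized_at_study_scale_parameters(self):
        out = mismatch.expected_spatial(3.1, 0.001, 5.0, 40)
        assert out.sum() == pytest.approx(1.0)
        assert np.all(out >= 0)


class TestRaggedness:
    def test_single_spike(self):
        assert mismatch.raggedness(np.array([1.0])) == pytest.approx(1.0)

    def test_uniform_distribution_boundary_term(self):
        # only the trailing boundary term contributes: (0 - 0.1)^2
        assert mismatch.raggedness(np.full(10, 0.1)) == pytest.approx(0.01)

    def test_smooth_below_jagged(self):
        smooth = mismatch.expected_sudden(3.0, 0.1, 10.0, 9)
        jagged = np.array([0.3, 0.0, 0.3, 0.0, 0.2, 0.0, 0.1, 0.0, 0.1, 0.0])
        assert mismatch.raggedness(smooth) < mismatch.raggedness(jagged)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(DomainError):
            mismatch.raggedness(np.array([0.5, 0.2]))


def _hist_from_model(tau, th0, th1, n_pairs=10**7, d_max=40):
    probs = mismatch.expected_sudden(tau, th0, th1, d_max)
    counts = np.rint(probs * n_pairs).astype(np.int64)
    return MismatchHistogram(counts, int(counts.sum()))


class TestFitExpansion:
    def test_self_consistency_recovers_generating_tau(self):
        h = _hist_from_model(3.0, 0.1, 10.0)
        fit = mismatch.fit_expansion(h)
        assert fit.tau == pytest.approx(3.0, abs=0.1)
        assert fit.SSD < 1e-6

    def test_degenerate_histogram_raises(self):
        h = MismatchHistogram(np.array([10]), 10)
        with pytest.raises(IdentifiabilityError):
            mismatch.fit_expansion(h)

    def test_no_uphill_return(self):
        h = _hist_from_model(2.0, 0.5, 20.0)
        starts = mismatch._starting_points("demographic", h.mean)
        fit = mismatch.fit_expansion(h)
        obs = np.zeros(fit.d_max + 1)
        obs[: h.counts.size] = h.relative
        for x0 in starts:
            assert fit.SSD <= mismatch._ssd("demographic", x0, obs) + 1e-15

    def test_star_variant_fixes_theta1(self):
        h = _hist_from_model(3.0, 0.05, 1e5)
        fit = mismatch.fit_expansion(h, star=True)
        assert fit.theta1 == mismatch.LARGE_THETA1
        assert fit.theta1_inf
        assert fit.tau == pytest.approx(3.0, abs=0.15)

    def test_spatial_fit_runs(self):
        probs = mismatch.expected_spatial(3.0, 0.5, 5.0, 30)
        counts = np.rint(probs * 10**6).astype(np.int64)
        h = MismatchHistogram(counts, int(counts.sum()))
        fit = mismatch.fit_expansion(h, model="spatial")
        assert fit.model == "spatial"
        assert fit.M is not None
        assert fit.SSD < 1e-4


class TestBootstrapGof:
    def test_boundary_conventions_and_ci_order(self):
        spec = coalsim.SimulationSpec(
            n_per_deme=(40,), theta=None, theta0=0.05, theta1=50.0, tau=3.0
        )
        c = coalsim.simulate_mismatch(spec, np.random.default_rng(3))
        h = MismatchHistogram(c, int(c.sum()))
        fit = mismatch.fit_expansion(h, star=True)
        out = mismatch.bootstrap_gof(fit, (40, 554), B=100, seed=9)
        assert 0.0 <= out.p_SSD <= 1.0
        assert 0.0 <= out.p_RAG <= 1.0
        assert out.B == 100
        lo, hi = out.ci["tau"]
        assert lo <= hi

    def test_raw_proportion_denominator(self):
        # observed SSD of ~0 -> every replicate >= observed -> p = 1.0 exactly
        spec = coalsim.SimulationSpec(
            n_per_deme=(40,), theta=None, theta0=0.05, theta1=50.0, tau=3.0
        )
        c = coalsim.simulate_mismatch(spec, np.random.default_rng(3))
        h = MismatchHistogram(c, int(c.sum()))
        fit = mismatch.fit_expansion(h, star=True)
        tiny = type(fit)(**{**fit.__dict__, "SSD": 0.0})
        out = mismatch.bootstrap_gof(tiny, (40, 554), B=100, seed=9)
        assert out.p_SSD == pytest.approx(1.0)
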