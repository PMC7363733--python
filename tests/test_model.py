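"""Burst-size distributions, feedback responses and model configuration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import burstwkb as bw
from burstwkb.config import ConfigError, model_from_dict, model_to_dict


class TestBurstFamilies:
    @pytest.mark.parametrize(
        "mean,fano,tag",
        [
            (1.0, 0.0, "fixed"),
            (4.0, 0.0, "fixed"),
            (2.0, 0.5, "binomial"),
            (1.0, 1.0, "poisson"),
            (4.0, 5.0, "negative_binomial"),  # geometric: fano = 1 + mean
            (2.0, 3.0, "negative_binomial"),
        ],
    )
    def test_pmf_moments_match_parameters(self, mean, fano, tag):
        d = bw.make_burst_distribution(mean, fano)
        assert d.family_tag == tag
        j = np.arange(d.pmf.size)
        pmf_mean = d.pmf @ j
        pmf_var = d.pmf @ (j - pmf_mean) ** 2
        assert pmf_mean == pytest.approx(mean, abs=1e-8)
        assert pmf_var == pytest.approx(fano * mean, abs=1e-7)

    def test_fixed_burst_of_one_is_point_mass(self):
        d = bw.make_burst_distribution(1, 0)
        assert np.allclose(d.pmf, [0.0, 1.0])

    def test_binomial_example_mean2_fano_half(self):
        # four trials at p = 1/2: brute-force expansion of (1/2 + e^t/2)^4
        d = bw.make_burst_distribution(2, 0.5)
        assert np.allclose(d.pmf, np.array([1, 4, 6, 4, 1]) / 16.0)

    def test_geometric_mgf_closed_form(self):
        mean = 4.0
        d = bw.make_burst_distribution(mean, 1.0 + mean)
        for theta in (-1.0, -0.2, 0.0, 0.1):
            expected = 1.0 / (1.0 + mean * (1.0 - math.exp(theta)))
            assert bw.mgf(d, theta) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "mean,fano",
        [(1.5, 0.0), (2.0, 0.4), (-1.0, 1.0), (2.0, -0.5)],
    )
    def test_invalid_parameters_raise(self, mean, fano):
        with pytest.raises(ValueError):
            bw.make_burst_distribution(mean, fano)

    def test_poisson_limit_from_both_sides(self):
        """The family pmf converges pointwise to Poisson as fano -> 1."""
        mean = 2.0
        ref = bw.make_burst_distribution(mean, 1.0)
        for fano in (1.0 - 1e-6, 1.0 + 1e-6):
            d = bw.make_burst_distribution(mean, fano, mgf_only=fano < 1)
            for theta in (-1.0, 0.5):
                assert bw.mgf(d, theta) == pytest.approx(
                    bw.mgf(ref, theta), rel=1e-5
                )
        # above 1 a pmf exists: compare it cell by cell
        d = bw.make_burst_distribution(mean, 1.0 + 1e-6)
        n = min(d.pmf.size, ref.pmf.size)
        assert np.allclose(d.pmf[:n], ref.pmf[:n], atol=1e-5)

    def test_mgf_only_object_refuses_lattice_operations(self):
        d = bw.make_burst_distribution(1.0, 0.25, mgf_only=True)
        assert not d.has_pmf
        with pytest.raises(ValueError, match="MGF level"):
            d.require_pmf()

    def test_explicit_distribution_moments(self):
        d = bw.explicit_burst_distribution([0.1, 0.5, 0.4])
        assert d.family_tag == "explicit"
        assert d.mean == pytest.approx(1.3)


class TestMGF:
    @pytest.mark.parametrize("mean,fano", [(1, 0), (2, 0.5), (3, 1), (4, 5)])
    def test_normalisation_and_first_moment(self, mean, fano):
        d = bw.make_burst_distribution(mean, fano)
        assert bw.mgf(d, 0.0, 0) == pytest.approx(1.0, abs=1e-14)
        assert bw.mgf(d, 0.0, 1) == pytest.approx(mean, rel=1e-12)
        assert bw.mgf(d, 0.0, 2) == pytest.approx(mean * (mean + fano), rel=1e-12)

    def test_fixed_burst_mgf_value(self):
        d = bw.make_burst_distribution(4, 0)
        assert bw.mgf(d, 0.5) == pytest.approx(math.exp(2.0), rel=1e-14)

    @pytest.mark.parametrize(
        "mean,fano,theta_top",
        # the negative-binomial MGF only converges for e^theta < F/(F-1),
        # so its comparison range stays well inside that radius
        [(1, 0, 1.0), (2, 0.5, 1.0), (1, 1, 1.0), (4, 5, 0.1), (2, 3, 0.1)],
    )
    def test_closed_form_agrees_with_pmf_summation(self, mean, fano, theta_top):
        """Family closed forms and direct pmf sums agree inside the MGF's
        domain of convergence."""
        d = bw.make_burst_distribution(mean, fano)
        explicit = bw.explicit_burst_distribution(d.pmf)
        for theta in np.linspace(-2, theta_top, 7):
            for order in (0, 1, 2):
                # rel tolerance covers the 1e-12 tail truncation of the pmf,
                # amplified by j^2 e^(j theta) in the second derivative
                assert bw.mgf(d, theta, order) == pytest.approx(
                    bw.mgf(explicit, theta, order), rel=1e-4, abs=1e-10
                )

    def test_invalid_order(self):
        d = bw.make_burst_distribution(1, 0)
        with pytest.raises(ValueError):
            bw.mgf(d, 0.0, 3)

    @settings(derandomize=True, max_examples=30)
    @given(
        mean=st.integers(min_value=1, max_value=8),
        fano=st.floats(min_value=1.0, max_value=6.0),
        theta=st.floats(min_value=-2.0, max_value=0.5),
    )
    def test_mgf_convexity_in_theta(self, mean, fano, theta):
        """M is log-convex: M''(t) M(t) >= M'(t)^2 (Cauchy-Schwarz)."""
        d = bw.make_burst_distribution(float(mean), fano)
        m0, m1, m2 = (bw.mgf(d, theta, k) for k in (0, 1, 2))
        assert m2 * m0 >= m1**2 - 1e-12 * m2 * m0


class TestFeedback:
    def test_step_response_values(self):
        fb = bw.make_step_response(20, 6, 2.0, 10.0)
        assert fb.rates[5] == 2.0
        assert fb.rates[6] == 10.0
        assert fb.rates.size == 21

    def test_threshold_below_and_above_range(self):
        assert np.all(bw.make_step_response(20, 0, 7, 3).rates == 3.0)
        assert np.all(bw.make_step_response(20, 21, 7, 3).rates == 7.0)

    def test_negative_rates_raise(self):
        with pytest.raises(ValueError):
            bw.make_step_response(20, 6, -1.0, 2.0)


class TestChooseSmax:
    @pytest.mark.parametrize(
        "mean,max_rate,expected", [(1, 10, 20), (4, 2.5, 20), (1, 0.5, 1)]
    )
    def test_two_times_max_production_rule(self, mean, max_rate, expected):
        d = bw.make_burst_distribution(mean, 0)
        assert bw.choose_smax(d, max_rate) == expected

    def test_nonpositive_rate_raises(self):
        with pytest.raises(ValueError):
            bw.choose_smax(bw.make_burst_distribution(1, 0), 0.0)


class TestConfig:
    def test_round_trip(self, pos_fb_fig4):
        rebuilt = model_from_dict(model_to_dict(pos_fb_fig4))
        assert rebuilt.s_max == pos_fb_fig4.s_max
        assert rebuilt.epsilon == pos_fb_fig4.epsilon
        assert np.allclose(rebuilt.feedback.rates, pos_fb_fig4.feedback.rates)
        assert rebuilt.burst.mean == pos_fb_fig4.burst.mean

    def test_auto_smax(self):
        cfg = {
            "burst": {"mean": 1, "fano": 0},
            "feedback": {"s_thresh": 6, "a0": 2, "a1": 10},
            "model": {"s_max": "auto", "epsilon": 0.1},
        }
        assert model_from_dict(cfg).s_max == 20

    @pytest.mark.parametrize(
        "broken,key",
        [
            ({"feedback": {"s_thresh": 6, "a0": 1, "a1": 2}, "model": {"epsilon": 0.1}}, "burst"),
            (
                {
                    "burst": {"mean": 1, "fano": 0},
                    "feedback": {"s_thresh": 6, "a0": 1},
                    "model": {"epsilon": 0.1},
                },
                "a1",
            ),
            (
                {
                    "burst": {"mean": 1, "fano": 0},
                    "feedback": {"s_thresh": 6, "a0": 1, "a1": 2},
                    "model": {"s_max": 20},
                },
                "epsilon",
            ),
        ],
    )
    def test_malformed_config_names_offending_key(self, broken, key):
        with pytest.raises(ConfigError, match=key):
            model_from_dict(broken)

    def test_yaml_file_round_trip(self, tmp_path, neg_fb_fig3):
        path = tmp_path / "model.yaml"
        bw.dump_config(neg_fb_fig3, path)
        rebuilt = bw.load_config(path)
        assert np.allclose(rebuilt.feedback.rates, neg_fb_fig3.feedback.rates)
        assert rebuilt.epsilon == neg_fb_fig3.epsilon


class TestModelSpec:
    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bw.ModelSpec(
                bw.make_burst_distribution(1, 0),
                bw.make_step_response(10, 3, 1, 2),
                s_max=20,
                epsilon=0.1,
            )

    def test_nonpositive_epsilon_raises(self):
        with pytest.raises(ValueError):
            bw.ModelSpec(
                bw.make_burst_distribution(1, 0),
                bw.make_step_response(20, 6, 1, 2),
                s_max=20,
                epsilon=0.0,
            )
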