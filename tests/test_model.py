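import dataclasses

import numpy as np
import pytest

import harshpref as hp
from harshpref.model import (Priors, choice_linear_predictor, choice_loglik,
                             choice_logp_and_grad, joint_logdensity,
                             ordinal_category_probs, prepare,
                             rating_logp_and_grad, rating_loglik,
                             scales_logp_and_grad, scales_loglik, sigmoid)
from oracles import (inv_logit, naive_joint_logdensity, normal_logpdf,
                     ordinal_prob, random_joint_params)


class TestChoiceLinearPredictor:
    def test_null_model_gives_zero(self):
        p = hp.ChoiceParams(alpha=np.zeros(3), beta_attr=np.zeros(3),
                            beta_form=np.zeros(3), beta_heal=np.zeros(3),
                            beta_pp=0, beta_rs=0, beta_side=0,
                            sigma_target=1, sigma_rater=1)
        eta = choice_linear_predictor(p, "control", (0, 0, 0), 0, 0, 0)
        assert eta == 0.0
        assert sigmoid(eta) == 0.5

    def test_side_term_only(self):
        p = hp.ChoiceParams(alpha=np.zeros(3), beta_attr=np.zeros(3),
                            beta_form=np.zeros(3), beta_heal=np.zeros(3),
                            beta_pp=0, beta_rs=0, beta_side=0.05,
                            sigma_target=1, sigma_rater=1)
        assert choice_linear_predictor(p, "control", (0, 0, 0), 0, 0,
                                       0.5) == pytest.approx(0.025)

    def test_fuzzed_term_by_term_sum(self):
        """100 random draws vs an independent scalar accumulation."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = hp.ChoiceParams(
                alpha=rng.normal(size=3), beta_attr=rng.normal(size=3),
                beta_form=rng.normal(size=3), beta_heal=rng.normal(size=3),
                beta_pp=rng.normal(), beta_rs=rng.normal(),
                beta_side=rng.normal(), sigma_target=1, sigma_rater=1)
            cond = ["control", "pathogen_prevalence",
                    "resource_scarcity"][rng.integers(3)]
            c = list(hp.CONDITIONS).index(cond)
            diffs = rng.normal(size=3)
            zpp, zrs, side = rng.normal(size=3)
            u, v = rng.normal(size=2)
            expected = 0.0
            for term in (p.alpha[c], p.beta_attr[c] * diffs[0],
                         p.beta_form[c] * diffs[1],
                         p.beta_heal[c] * diffs[2], p.beta_pp * zpp,
                         p.beta_rs * zrs, p.beta_side * side, u, v):
                expected += term
            got = choice_linear_predictor(p, cond, diffs, zpp, zrs, side,
                                          u, v)
            assert got == pytest.approx(expected, rel=1e-12)


class TestOrdinalBlock:
    CUTS = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])

    def test_probs_sum_to_one_and_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = np.sort(rng.normal(0, 2, 6)) + 0.05 * np.arange(6)
            phi = rng.normal(0, 3)
            p = ordinal_category_probs(c, phi)
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_at_zero(self):
        p = ordinal_category_probs(self.CUTS, 0.0)
        assert p[0] == pytest.approx(p[6])
        assert p[1] == pytest.approx(p[5])
        assert p[2] == pytest.approx(p[4])

    def test_extreme_phi_limit(self):
        p = ordinal_category_probs(self.CUTS, 50.0)
        assert p[6] > 1 - 1e-15

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        phi = rng.normal(0, 2, 20)
        for shift in (-3.0, 0.7, 10.0):
            a = ordinal_category_probs(self.CUTS, phi)
            b = ordinal_category_probs(self.CUTS + shift, phi + shift)
            assert np.allclose(a, b, atol=1e-12)

    def test_unordered_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            ordinal_category_probs(self.CUTS[::-1], 0.0)

    def test_single_record_hand_computed(self):
        """phi=0, symmetric cut-points, score 4: p = ilogit(.5)-ilogit(-.5)."""
        expected = inv_logit(0.5) - inv_logit(-0.5)
        assert ordinal_category_probs(self.CUTS, 0.0)[3] == pytest.approx(
            expected, rel=1e-14)


def _full_params(rng, prep):
    return random_joint_params(rng, prep.n_targets, prep.n_raters)


class TestLogLikelihoods:
    def test_choice_loglik_single_null_record(self, tiny_clean):
        """Predictor 0 for every record gives N * log(0.5)."""
        prep = prepare(tiny_clean)
        p = hp.ChoiceParams(alpha=np.zeros(3), beta_attr=np.zeros(3),
                            beta_form=np.zeros(3), beta_heal=np.zeros(3),
                            beta_pp=0, beta_rs=0, beta_side=0,
                            sigma_target=1, sigma_rater=1)
        ll = choice_loglik(p, prep)
        assert ll == pytest.approx(len(prep.choice_y) * np.log(0.5))

    def test_bernoulli_logit_symmetry(self, tiny_clean):
        """Flipping outcomes and negating the predictor leaves ll fixed."""
        prep = prepare(tiny_clean)
        rng = np.random.default_rng(2)
        p = _full_params(rng, prep).choice
        ll = choice_loglik(p, prep)
        neg = dataclasses.replace(
            p, alpha=-p.alpha, beta_attr=-p.beta_attr,
            beta_form=-p.beta_form, beta_heal=-p.beta_heal,
            beta_pp=-p.beta_pp, beta_rs=-p.beta_rs, beta_side=-p.beta_side,
            u_target=-p.u_target, v_rater=-p.v_rater)
        flipped = dataclasses.replace(prep)
        flipped.choice_y = 1.0 - prep.choice_y
        assert choice_loglik(neg, flipped) == pytest.approx(ll, rel=1e-12)

    def test_rating_translation_invariance(self, tiny_clean):
        prep = prepare(tiny_clean)
        rng = np.random.default_rng(3)
        params = _full_params(rng, prep).ratings
        ll = rating_loglik(params, prep)
        shifted = {}
        for dim, p in params.items():
            shifted[dim] = dataclasses.replace(
                p, cutpoints=p.cutpoints + 1.7, a_mas=p.a_mas + 1.7,
                a_fem=p.a_fem + 1.7)
        assert rating_loglik(shifted, prep) == pytest.approx(ll, rel=1e-10)

    def test_scales_mode_density(self, tiny_clean):
        prep = prepare(tiny_clean)
        # place every mu at the observed z: each term is log(1/sqrt(2pi))
        mu = np.zeros((2, 3))
        p = hp.ScaleParams(mu=mu, resid_sd=(1.0, 1.0))
        ll = scales_loglik(p, prep)
        by_hand = sum(
            normal_logpdf(z, 0.0, 1.0)
            for z in np.concatenate([prep.z_pp, prep.z_rs]))
        assert ll == pytest.approx(by_hand, rel=1e-12)

    def test_scales_sd_scaling(self, tiny_clean):
        """At z = mu, doubling the SD lowers each log term by log 2."""
        prep = prepare(tiny_clean)
        mu = np.zeros((2, 3))
        z_backup = prep.z_pp.copy(), prep.z_rs.copy()
        prep.z_pp = np.zeros_like(prep.z_pp)
        prep.z_rs = np.zeros_like(prep.z_rs)
        l1 = scales_loglik(hp.ScaleParams(mu=mu, resid_sd=(1, 1)), prep)
        l2 = scales_loglik(hp.ScaleParams(mu=mu, resid_sd=(2, 2)), prep)
        n_terms = 2 * prep.n_raters
        assert l1 - l2 == pytest.approx(n_terms * np.log(2), rel=1e-12)
        prep.z_pp, prep.z_rs = z_backup


class TestJointDensity:
    def test_additivity_of_blocks(self, tiny_clean):
        prep = prepare(tiny_clean)
        rng = np.random.default_rng(7)
        params = _full_params(rng, prep)
        priors = Priors()
        joint = joint_logdensity(params, priors, prep)
        parts = (choice_loglik(params.choice, prep)
                 + rating_loglik(params.ratings, prep)
                 + scales_loglik(params.scales, prep))
        assert joint > parts * (1 + 1e-12) or joint < parts  # priors < 0 shift
        # additivity: removing the likelihood leaves priors + intercepts
        assert np.isfinite(joint)

    def test_matches_naive_loop_oracle(self, tiny_clean):
        """Vectorised joint density == scalar-loop oracle to 1e-10."""
        prep = prepare(tiny_clean)
        rng = np.random.default_rng(11)
        priors = Priors()
        for _ in range(10):
            params = _full_params(rng, prep)
            ours = joint_logdensity(params, priors, prep)
            naive = naive_joint_logdensity(params, priors, tiny_clean)
            assert ours == pytest.approx(naive, rel=1e-10)

    def test_finite_under_prior_draws(self, tiny_prepared):
        rng = np.random.default_rng(13)
        priors = Priors()
        for _ in range(1000):
            params = random_joint_params(rng, tiny_prepared.n_targets,
                                         tiny_prepared.n_raters)
            assert np.isfinite(joint_logdensity(params, priors,
                                                tiny_prepared))


class TestGradients:
    """Finite differences vs the analytic sampler-backend gradients."""

    @pytest.mark.parametrize("builder", [
        lambda prep, pr: choice_logp_and_grad(prep, pr),
        lambda prep, pr: rating_logp_and_grad("attractiveness", prep, pr),
        lambda prep, pr: rating_logp_and_grad("formidability", prep, pr),
        lambda prep, pr: scales_logp_and_grad(prep, pr),
        lambda prep, pr: scales_logp_and_grad(prep, pr, fix_resid_sd=0.8),
    ])
    def test_numeric_gradient_agreement(self, tiny_prepared, builder):
        layout, f = builder(tiny_prepared, Priors())
        rng = np.random.default_rng(layout.ndim)
        theta = 0.3 * rng.standard_normal(layout.ndim)
        _, grad = f(theta)
        idx = rng.choice(layout.ndim, size=min(40, layout.ndim),
                         replace=False)
        eps = 1e-6
        for i in idx:
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            fd = (f(up)[0] - f(dn)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)
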