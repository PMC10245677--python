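"""Model families, (x, y) parametrization, closed forms and coupling."""

import numpy as np
import pytest
from scipy import stats

from cmegf import gf_core as gc
from cmegf import models as M

import oracles
from conftest import tv


class TestQualitativeCoords:
    def test_mixture_like_forward_map(self):
        """kappa=0.1, a=0.4, theta=1, beta=0.8 one-species -> x=1/9, y=5/7."""
        p = M.SDEDriverParams("gou", kappa=0.1, a=0.4, theta=1.0, beta=0.8)
        q = M.process_to_qualitative(p, species_mode="one")
        assert q.x == pytest.approx(1.0 / 9.0, rel=1e-12)
        assert q.y == pytest.approx(5.0 / 7.0, rel=1e-12)

    def test_two_species_mixture_like(self):
        p = M.SDEDriverParams("gou", kappa=0.1, a=0.4, theta=1.0, beta=0.8, gamma=0.9)
        q = M.process_to_qualitative(p, species_mode="two")
        assert q.x == pytest.approx(1.0 / 18.0, rel=1e-12)

    def test_burst_like_kappa(self):
        """x=9/10, beta=0.8 one-species inverts to kappa=7.2."""
        coords = M.QualitativeCoords(x=0.9, y=0.5, muK=5.0, beta=0.8,
                                     species_mode="one")
        p = M.qualitative_to_process(coords, "gou")
        assert p.kappa == pytest.approx(7.2, rel=1e-12)

    def test_symmetric_point(self):
        coords = M.QualitativeCoords(x=0.5, y=0.5, muK=1.0, beta=0.4, gamma=0.6,
                                     species_mode="two")
        p = M.qualitative_to_process(coords, "gou")
        assert p.kappa == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("x_one,expected", [(0.4, 0.24), (0.9, 0.81)])
    def test_one_to_two_species_transform(self, x_one, expected):
        """One-species illustrative points map to two-species x ~ 0.24 / 0.81."""
        coords = M.QualitativeCoords(x=x_one, y=0.9, muK=5.0, beta=0.8,
                                     species_mode="one")
        p = M.qualitative_to_process(coords, "gou")
        p2 = M.SDEDriverParams("gou", kappa=p.kappa, a=p.a, theta=p.theta,
                               beta=0.8, gamma=0.9)
        q2 = M.process_to_qualitative(p2, species_mode="two")
        assert q2.x == pytest.approx(expected, abs=0.005)

    def test_telegraph_identification_example(self):
        """kon=koff=1, kinit=2 -> kappa=2, a=2, theta=1; x=0.5 (beta=2), y=1/3."""
        p = M.TelegraphParams(kon=1.0, koff=1.0, kinit=2.0, beta=2.0)
        kappa, a, theta = M.telegraph_driver_identification(p)
        assert (kappa, a, theta) == pytest.approx((2.0, 2.0, 1.0))
        q = M.process_to_qualitative(p, species_mode="one")
        assert q.x == pytest.approx(0.5)
        assert q.y == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("family", ["gou", "cir", "telegraph"])
    @pytest.mark.parametrize("x,y", [(0.3, 0.6), (0.9, 0.2), (1/9, 5/7)])
    def test_round_trip_bijection(self, family, x, y):
        coords = M.QualitativeCoords(x=x, y=y, muK=5.0, beta=0.8, gamma=0.9)
        p = M.qualitative_to_process(coords, family)
        back = M.process_to_qualitative(p, species_mode="two")
        assert back.x == pytest.approx(x, rel=1e-10)
        assert back.y == pytest.approx(y, rel=1e-10)
        assert back.muK == pytest.approx(5.0, rel=1e-10)

    def test_telegraph_moment_matching(self):
        p = M.TelegraphParams(kon=0.6, koff=1.7, kinit=3.0, beta=1.0)
        kappa, a, theta = M.telegraph_driver_identification(p)
        muK = p.kon * p.kinit / kappa
        assert a * theta / kappa == pytest.approx(muK, rel=1e-12)
        varK = p.kon * p.koff * p.kinit**2 / kappa**2
        assert theta * muK == pytest.approx(varK, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            M.QualitativeCoords(x=0.0, y=0.5, muK=1.0, beta=1.0, species_mode="one")
        with pytest.raises(ValueError):
            M.QualitativeCoords(x=0.5, y=1.0, muK=1.0, beta=1.0, species_mode="one")


class TestDropoutClosure:
    def test_identity_at_p_one(self):
        p = M.SDEDriverParams("gou", kappa=0.1, a=0.4, theta=1.0, beta=0.8)
        assert M.apply_dropout_closure(p, 1.0) == p

    def test_telegraph_rule(self):
        p = M.TelegraphParams(kon=1.0, koff=1.0, kinit=5.0, beta=1.0)
        out = M.apply_dropout_closure(p, 0.2)
        assert out.kinit == pytest.approx(1.0)
        assert (out.kon, out.koff, out.beta) == (p.kon, p.koff, p.beta)

    @pytest.mark.parametrize("params", [
        M.SDEDriverParams("gou", kappa=0.1, a=0.4, theta=1.0, beta=0.8),
        M.SDEDriverParams("cir", kappa=0.4, a=0.7, theta=1.2, beta=0.9),
        M.TelegraphParams(kon=0.8, koff=1.1, kinit=4.0, beta=1.0),
    ], ids=["gou", "cir", "telegraph"])
    def test_thinning_equivalence(self, params):
        """Reparametrized stationary PMF equals the binomial-thinned PMF."""
        p_obs = 0.5
        shape = (48,)
        base = M.stationary_pmf(params, shape=shape).values
        closed = M.stationary_pmf(M.apply_dropout_closure(params, p_obs),
                                  shape=shape).values
        thinned = oracles.thin_pmf_1d(base, p_obs)
        assert tv(closed, thinned) < 1e-6

    def test_y_star_decreases(self):
        p = M.SDEDriverParams("gou", kappa=0.1, a=0.4, theta=1.0, beta=0.8)
        y0 = M.process_to_qualitative(p, "one").y
        assert M.dropout_y_star(p, 0.5) < y0

    def test_p_out_of_range(self):
        p = M.TelegraphParams(kon=1, koff=1, kinit=1, beta=1)
        with pytest.raises(ValueError):
            M.apply_dropout_closure(p, 0.0)


class TestClosedForms:
    def test_constitutive_poisson(self):
        law = M.stationary_closed_form(M.ConstitutiveParams(K=2.0, gamma=1.0))
        assert law.pmf(0) == pytest.approx(np.exp(-2.0))

    def test_autocatalytic_nb_shape_scale(self):
        """alpha=1, q=0.5, gamma=1 -> NB shape 2, scale 1 (vs CME oracle)."""
        params = M.AutocatalyticParams(alpha=1.0, q=0.5, gamma=1.0)
        law = M.stationary_closed_form(params)
        ref = stats.nbinom(2.0, 0.5)  # shape alpha/q = 2, scale q/(gamma-q) = 1
        xs = np.arange(60)
        np.testing.assert_allclose(law.pmf(xs), ref.pmf(xs), rtol=1e-12)
        cme = oracles.autocatalytic_cme(1.0, 0.5, 1.0, n=120)
        assert tv(cme, law.pmf(np.arange(120))) < 1e-6

    def test_bursty_nb(self):
        law = M.stationary_closed_form(M.BurstyParams(alpha=1.0, b=4.9, beta=0.7))
        assert law.args[0] == pytest.approx(1.0 / 0.7)
        cme = oracles.bursty_cme(1.0, 4.9, 0.7, nN=150)
        assert tv(cme, law.pmf(np.arange(150))) < 1e-6

    def test_no_closed_form_signal(self):
        with pytest.raises(M.NoClosedFormError):
            M.stationary_closed_form(
                M.AutocatalyticParams(alpha=1.0, q=0.2, gamma=1.0, b=2.0))


class TestBurstyAutocatalyticGF:
    def test_normalization(self):
        G = M.bursty_autocatalytic_gf(
            M.AutocatalyticParams(alpha=1.0, q=0.3, gamma=1.0, b=2.0))
        assert G(np.array([0.0 + 0.0j])) == pytest.approx(1.0)

    def test_q_to_zero_reduces_to_bursty_nb(self):
        G = M.bursty_autocatalytic_gf(
            M.AutocatalyticParams(alpha=1.0, q=1e-9, gamma=1.0, b=2.0))
        u = np.linspace(-0.4, 0.4, 9).astype(complex)
        expected = (1.0 - 2.0 * u) ** (-1.0)  # (1 - b u)^(-alpha/gamma)
        np.testing.assert_allclose(G(u), expected, rtol=1e-6)

    def test_pmf_matches_cme_oracle(self):
        params = M.AutocatalyticParams(alpha=1.0, q=0.3, gamma=1.0, b=2.0)
        G = M.bursty_autocatalytic_gf(params)
        pmf = gc.invert_gf(lambda u: G(u[0]), (100,)).values
        cme = oracles.autocatalytic_cme(1.0, 0.3, 1.0, b=2.0, n=100)
        assert tv(pmf, cme) < 1e-4

    def test_matches_transient_bursty_gf(self):
        """Stationary autocatalytic GF = transient plain-bursty GF when
        q/c = b exp(-kappa tau) and the burst frequency/decay ratio equals v."""
        alpha, q, gamma, b = 1.0, 0.3, 1.0, 2.0
        params = M.AutocatalyticParams(alpha=alpha, q=q, gamma=gamma, b=b)
        c, v = params.c, params.v
        kappa = 1.0
        tau = -np.log(q / (c * b)) / kappa  # q/c = b exp(-kappa tau)
        G_auto = M.bursty_autocatalytic_gf(params)
        u = np.array([0.2 + 0.1j, -0.3 + 0.0j, 0.05 - 0.25j])
        # transient bursty process (freq v*kappa, decay kappa, empty start):
        # log G = v*kappa * int_0^tau [1/(1 - b u e^{-kappa s}) - 1] ds
        s = np.linspace(0.0, tau, 200001)
        integrand = 1.0 / (1.0 - b * u[:, None] * np.exp(-kappa * s[None, :])) - 1.0
        lhs = np.exp(v * kappa * np.trapezoid(integrand, x=s, axis=1))
        np.testing.assert_allclose(G_auto(u), lhs, rtol=1e-9)


class TestCoupledModels:
    def test_mixture_single_component_is_product(self):
        G1 = lambda u: np.exp(2.0 * u[0])
        mix = M.build_coupled_model("mixture", None, weights=[1.0], components=[G1])
        u = np.array([[0.3 + 0.1j]])
        np.testing.assert_allclose(mix(u), G1(u))

    def test_mixture_weights_must_normalize(self):
        with pytest.raises(ValueError):
            M.build_coupled_model("mixture", None, weights=[0.5, 0.2],
                                  components=[lambda u: 1, lambda u: 1])

    def test_eps_one_factorizes(self):
        """At eps=1 the joint law is the product of single-gene telegraph laws."""
        p = M.CoregulationParams(eps=1.0, kon=0.5, koff=0.8, kinit=3.0,
                                 gamma1=1.0, gamma2=1.0)
        spec = M.build_coupled_model("state_coupled", p)
        joint = gc.gf_to_pmf(spec, (16, 16)).values
        single = M.stationary_pmf(
            M.TelegraphParams(kon=0.5, koff=0.8, kinit=3.0, beta=1.0),
            shape=(16,)).values
        assert tv(joint, np.outer(single, single)) < 1e-5

    def test_small_eps_matches_cobursting_limit(self):
        """eps -> 0 four-state chain vs the reduced two-state formulation."""
        p = M.CoregulationParams(eps=1e-3, kon=0.5, koff=0.8, kinit=3.0,
                                 gamma1=1.0, gamma2=1.0)
        full = gc.gf_to_pmf(M.build_coupled_model("state_coupled", p), (16, 16),
                            nodes=2048).values
        reduced = gc.gf_to_pmf(M.build_coupled_model("cobursting_reduced", p),
                               (16, 16)).values
        assert tv(full, reduced) < 0.01

    def test_cobursting_module_normalizes(self):
        p = M.CoregulationParams(eps=1e-3, kon=0.5, koff=5.0, kinit=50.0,
                                 gamma1=1.0, gamma2=1.0)
        pmf = gc.gf_to_pmf(M.build_coupled_model("cobursting", p), (64, 64))
        assert pmf.normalization_defect < 1e-8


class TestMoments:
    def test_bursty_moments_against_cme(self):
        alpha, b, beta, gamma = 0.8, 2.0, 1.2, 3.14
        (muN, muM), (sdN, sdM) = M.bursty_moments(alpha, b, beta, gamma)
        joint = oracles.bursty_cme(alpha, b, beta, gamma, nN=40, nM=25)
        xs = np.arange(40)[:, None]
        ys = np.arange(25)[None, :]
        assert (joint * xs).sum() == pytest.approx(muN, rel=1e-4)
        assert (joint * ys).sum() == pytest.approx(muM, rel=1e-4)
        varN = (joint * xs**2).sum() - muN**2
        varM = (joint * ys**2).sum() - muM**2
        assert varN == pytest.approx(sdN**2, rel=1e-3)
        assert varM == pytest.approx(sdM**2, rel=1e-3)
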