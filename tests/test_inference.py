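"""Likelihoods, Akaike weights, transient MLE, landscapes, ratio posterior."""

import numpy as np
import pytest
from scipy import stats

from cmegf import inference as I
from cmegf import models as M
from cmegf import reactors as R
from cmegf import simulate as S

PROF = R.StepBurstProfile(2.0, 5.0, 1.0, 1.0, 3.0)
PARAMS = R.TransientModelParams(PROF, alpha=0.8, beta=1.2, gamma=3.14)
PFR = R.ReactorSpec("dirac_pfr", 5.0)


class TestLogLikelihood:
    def test_single_cell_at_mode(self):
        pmf = M.stationary_pmf(M.BurstyParams(alpha=1.0, b=2.0, beta=1.0),
                               shape=(32,))
        mode = int(np.argmax(pmf.values))
        data = S.CountDataset(nascent=np.array([mode]),
                              mature=np.zeros(1, dtype=int))
        assert I.log_likelihood(data, pmf) == pytest.approx(
            np.log(pmf.values[mode]))

    def test_duplicated_dataset_doubles(self, rng):
        pmf = M.stationary_pmf(M.BurstyParams(alpha=1.0, b=2.0, beta=1.0),
                               shape=(64,))
        data = S.sample_from_pmf(pmf, 100, rng)
        double = S.CountDataset(nascent=np.tile(data.nascent, 2),
                                mature=np.tile(data.mature, 2))
        assert I.log_likelihood(double, pmf) == pytest.approx(
            2.0 * I.log_likelihood(data, pmf))

    def test_mean_loglik_approaches_negative_entropy(self, rng):
        lam = 2.0
        pmf = stats.poisson(lam).pmf(np.arange(64))
        n = 200_000
        data = S.CountDataset(nascent=rng.poisson(lam, n),
                              mature=np.zeros(n, dtype=int))
        mean_ll = I.log_likelihood(data, pmf) / n
        entropy = -(pmf[pmf > 0] * np.log(pmf[pmf > 0])).sum()
        assert mean_ll == pytest.approx(-entropy, abs=0.01)

    def test_count_outside_grid_raises(self):
        data = S.CountDataset(nascent=np.array([99]), mature=np.array([0]))
        with pytest.raises(ValueError):
            I.log_likelihood(data, np.ones(10) / 10.0)


class TestAkaikeWeights:
    def test_equal_models_share_weight(self):
        ak = I.akaike_weights([-50.0, -50.0, -50.0], 3)
        np.testing.assert_allclose(ak.weights, 1.0 / 3.0)

    def test_printed_logL_example(self):
        """logL = (-100, -101, -103), equal counts -> (0.7054, 0.2595, 0.0351)."""
        ak = I.akaike_weights([-100.0, -101.0, -103.0], 6)
        np.testing.assert_allclose(ak.weights, [0.7054, 0.2595, 0.0351], atol=2e-4)

    def test_dominant_model(self):
        ak = I.akaike_weights([-100.0, -150.0], 6)
        assert ak.weights[0] == pytest.approx(1.0, abs=1e-10)
        assert ak.best == 0

    def test_invariant_to_constant_shift(self):
        a = I.akaike_weights([-100.0, -101.0, -103.0], 6).weights
        b = I.akaike_weights([-400.0, -401.0, -403.0], 6).weights
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            I.akaike_weights([-1.0], 6)


@pytest.fixture(scope="module")
def dataset():
    times = S.sample_reactor_times(PFR, 150, S.child_rng(21, 1))
    return S.ssa_transient(PARAMS, times, S.child_rng(21, 2))


class TestTransientMLE:
    def test_fit_improves_on_truth_and_respects_bounds(self, dataset):
        fit = I.fit_transient_mle(dataset, PFR, PFR, PARAMS.theta(), (1.0, 3.0))
        shape = (int(dataset.nascent.max()) + 5, int(dataset.mature.max()) + 5)
        ll_truth = I.transient_log_likelihood(dataset, PARAMS, shape)
        assert fit.logL >= ll_truth - 1e-9
        assert np.all(fit.log10_theta >= -1.5) and np.all(fit.log10_theta <= 1.5)
        assert fit.n_iter <= 20

    def test_parameter_recovery_near_truth(self, dataset):
        """Most fitted log-parameters stay within 0.3 of the generating values."""
        fit = I.fit_transient_mle(dataset, PFR, PFR, PARAMS.theta(), (1.0, 3.0))
        err = np.abs(fit.log10_theta - np.log10(PARAMS.theta()))
        assert (err < 0.3).sum() >= 4

    def test_nonfinite_initial_point_raises(self, dataset):
        bad = np.array([1e-12, 1e-12, 1e-12, 1e-12, 1e-12, 1e-12])
        # theta0 far below the bounds is clipped, so construct an actually
        # broken start by shrinking the grid until counts fall outside
        with pytest.raises(Exception):
            I.fit_transient_mle(dataset, PFR, PFR, bad, (1.0, 3.0), shape=(2, 2))


class TestLandscapes:
    def test_empty_dataset_flat_landscape(self):
        data = S.CountDataset(nascent=np.array([], dtype=int),
                              mature=np.array([], dtype=int))
        grid = I.likelihood_landscape(data, "gou", 5.0, 0.8, 0.9,
                                      x_grid=np.array([0.2, 0.6]),
                                      y_grid=np.array([0.3, 0.7]),
                                      shape=(30, 30), nodes=128)
        np.testing.assert_allclose(grid.values, 0.0)

    def test_truth_node_in_top_decile(self):
        """The node nearest the generating parameters scores in the top decile
        of the bivariate likelihood (majority of seeds)."""
        truth = M.SDEDriverParams("gou", kappa=0.1, a=0.4, theta=1.0,
                                  beta=0.8, gamma=0.9)
        pmf = M.stationary_pmf(truth, shape=(50, 51))
        # coarse grid augmented with the exact truth coordinates (x=1/18, y=5/7)
        xg = np.unique(np.append(np.linspace(0.01, 0.99, 8), 1.0 / 18.0))
        yg = np.unique(np.append(np.linspace(0.01, 0.99, 8), 5.0 / 7.0))
        ix = int(np.argmin(np.abs(xg - 1.0 / 18.0)))
        iy = int(np.argmin(np.abs(yg - 5.0 / 7.0)))
        hits = 0
        for seed in range(5):
            data = S.sample_from_pmf(pmf, 200, seed)
            grid = I.likelihood_landscape(data, "gou", 5.0, 0.8, 0.9,
                                          x_grid=xg, y_grid=yg,
                                          shape=(50, 51), nodes=192)
            thr = np.quantile(grid.values, 0.9)
            hits += grid.values[ix, iy] >= thr
        assert hits >= 3

    def test_bivariate_breaks_marginal_degeneracy(self):
        """The burst-like impostor matches the nascent marginal of mixture-like
        data but loses the top decile under the joint likelihood."""
        truth = M.SDEDriverParams("gou", kappa=0.1, a=0.4, theta=1.0,
                                  beta=0.8, gamma=0.9)
        pmf = M.stationary_pmf(truth, shape=(50, 51))
        # impostor: one-species x=9/10 -> kappa=7.2 at the same y and averages
        coords = M.QualitativeCoords(x=0.9, y=5.0 / 7.0, muK=5.0, beta=0.8,
                                     species_mode="one")
        imp = M.qualitative_to_process(coords, "gou")
        imp2 = M.SDEDriverParams("gou", kappa=imp.kappa, a=imp.a, theta=imp.theta,
                                 beta=0.8, gamma=0.9)
        q2 = M.process_to_qualitative(imp2, "two")
        q_true = M.process_to_qualitative(truth, "two")
        xg = np.array(sorted({q_true.x, q2.x, 0.3, 0.5, 0.97}))
        yg = np.array([0.3, 5.0 / 7.0, 0.9])
        ix_true = int(np.argmin(np.abs(xg - q_true.x)))
        ix_imp = int(np.argmin(np.abs(xg - q2.x)))
        iy = 1
        wins = 0
        for seed in range(3):
            data = S.sample_from_pmf(pmf, 200, seed)
            grid = I.likelihood_landscape(data, "gou", 5.0, 0.8, 0.9,
                                          x_grid=xg, y_grid=yg,
                                          shape=(50, 51), nodes=192,
                                          mode="bivariate")
            wins += grid.values[ix_true, iy] > grid.values[ix_imp, iy]
        assert wins >= 2

    def test_low_noise_weights_uninformative(self):
        """y -> 0: all three candidate laws collapse to Poisson, weight -> 1/3."""
        grid = I.model_weight_landscape(
            "gou", muK=5.0, beta=0.8, gamma=0.9, n_cells=150, reps=3, seed=0,
            x_grid=np.array([0.5]), y_grid=np.array([0.01]),
            shape=(30, 31), nodes=128)
        assert grid.values[0, 0] == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_deterministic_weights_same_seed(self):
        kw = dict(muK=5.0, beta=0.8, gamma=0.9, n_cells=50, reps=1,
                  x_grid=np.array([0.4]), y_grid=np.array([0.9]),
                  shape=(40, 41), nodes=128)
        a = I.model_weight_landscape("gou", seed=3, **kw)
        b = I.model_weight_landscape("gou", seed=3, **kw)
        assert a.values[0, 0] == b.values[0, 0]


class TestRatioPosterior:
    def _simulate(self, ratio, n, seed):
        alpha, b_pN, muN, muM = 1.0, 4.9, 7.0, 10.0
        if ratio >= 1.0:
            pM, pN = 1.0, 1.0 / ratio
        else:
            pN, pM = 1.0, ratio
        beta = alpha * b_pN / muN
        b = b_pN / pN
        gamma = alpha * b * pM / muM
        pmf = M.stationary_pmf(M.BurstyParams(alpha=alpha, b=b, beta=beta,
                                              gamma=gamma),
                               shape=(100, 100), pN=pN, pM=pM)
        return S.sample_from_pmf(pmf, n, seed)

    def test_posterior_sums_to_one(self):
        data = self._simulate(1.0, 50, 0)
        post = I.ratio_posterior(data, 1.0, 4.9, 7.0, 10.0, grid_points=40,
                                 nodes=128)
        assert post.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(post.log10_ratio) == 40

    def test_recovers_unit_ratio(self):
        """Posterior mean of log10(pM/pN) near 0 for data generated at ratio 1."""
        means = []
        for seed in range(4):
            data = self._simulate(1.0, 200, seed)
            post = I.ratio_posterior(data, 1.0, 4.9, 7.0, 10.0, grid_points=41,
                                     nodes=160)
            means.append(post.mean())
        assert abs(np.mean(means)) < 0.3

    def test_posterior_narrows_with_sample_size(self):
        """Posterior sd shrinks from n=20 to n=200 at ratio 4."""
        sds = {}
        for n in (20, 200):
            vals = [I.ratio_posterior(self._simulate(4.0, n, seed), 1.0, 4.9,
                                      7.0, 10.0, grid_points=41, nodes=160).sd()
                    for seed in range(3)]
            sds[n] = np.mean(vals)
        assert sds[200] < sds[20]
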