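import numpy as np
import pytest

from vbtstim import inversion
from vbtstim.dynamics import Reduced2DParams, simulate_reduced_2d
from vbtstim.features import TargetBlock, TargetBundle
from vbtstim.hmc import effective_sample_size, sample_nuts, split_rhat
from vbtstim.inversion import (
    GenerativeModel,
    build_generative_model,
    convergence_diagnostics,
    log_likelihood,
    log_posterior_and_grad,
    map_estimate,
    reparameterize,
    sample_posterior,
)


class TestReparameterization:
    def test_orthonormality(self):
        rng = np.random.default_rng(0)
        G = rng.standard_normal((15, 6))  # channels x sources
        rep = reparameterize(G)
        assert np.max(np.abs(rep.V.T @ rep.V - np.eye(6))) < 1e-10

    def test_orthogonal_columns_give_signed_permutation(self):
        rng = np.random.default_rng(1)
        # G with orthogonal columns of distinct norms: G^T G is diagonal,
        # so the eigenvectors are coordinate axes (a signed permutation)
        Q, _ = np.linalg.qr(rng.standard_normal((8, 4)))
        G = Q * np.array([3.0, 1.0, 4.0, 2.0])
        rep = reparameterize(G)
        assert np.allclose(np.abs(rep.V), np.eye(4)[:, np.argsort(
            np.argmax(np.abs(rep.V), axis=0))], atol=1e-10) or \
            np.allclose(np.sum(np.abs(rep.V) > 1e-10, axis=0), 1)
        # eigenvalues ascend
        assert np.all(np.diff(rep.eigenvalues) >= -1e-12)

    def test_roundtrip(self):
        rng = np.random.default_rng(2)
        rep = reparameterize(rng.standard_normal((10, 5)))
        v = rng.standard_normal(5)
        assert np.allclose(rep.from_star(rep.to_star(v)), v, atol=1e-12)

    def test_star_space_gaussian_maps_back(self):
        # sampling z* ~ N(mu*, I) and mapping back through the orthonormal
        # V reproduces N(V mu*, I): closed-form Gaussian transform
        rng = np.random.default_rng(3)
        rep = reparameterize(rng.standard_normal((12, 4)))
        mu_star = np.array([1.0, -2.0, 0.5, 3.0])
        z_star = mu_star + rng.standard_normal((4000, 4))
        z = z_star @ rep.V.T
        assert np.allclose(z.mean(axis=0), rep.V @ mu_star, atol=0.1)
        assert np.allclose(np.cov(z.T), np.eye(4), atol=0.15)

    def test_rank_deficient_still_orthonormal(self):
        G = np.ones((6, 3))  # rank one
        rep = reparameterize(G)
        assert np.max(np.abs(rep.V.T @ rep.V - np.eye(3))) < 1e-10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reparameterize(np.zeros((0, 0)))


def _toy_model(L=2, C=6, T=60, seed=0, x0_true=None, sigma=0.05,
               with_noise=True, stim=None):
    """2-region generative model with data simulated from known params."""
    rng = np.random.default_rng(seed)
    x0_true = np.array([-1.6, -2.5] if x0_true is None else x0_true)
    W = np.abs(rng.standard_normal((L, L)))
    np.fill_diagonal(W, 0.0)
    W = W / W.max()
    p = Reduced2DParams(x0=x0_true, C=W, tau0=10.0, K=0.3)
    # all regions start near the healthy equilibrium; the elevated-x0
    # region seizes after a delay because its permittivity drifts down
    xin = np.full(L, -2.0)
    zin = np.full(L, 2.5)
    act = simulate_reduced_2d(p, (xin, zin), dt=0.1, T=(T - 1) * 0.1)
    gain = np.abs(rng.standard_normal((L, C))) ** 2
    gain /= gain.max()
    target = 1.5 * (gain.T @ act.values) + 0.2
    if with_noise:
        target = target + sigma * rng.standard_normal(target.shape)
    blk = TargetBlock(modality="seeg", labels=[f"c{i}" for i in range(C)],
                      times_s=act.times, values=target, gain=gain)
    model = build_generative_model(TargetBundle([blk]), W, dt=0.1,
                                   tau0=10.0, stim_input=stim)
    truth = dict(x0=x0_true, xinit=xin, zinit=zin, K=0.3, alpha=[1.5],
                 beta=[0.2], sigma=max(sigma, 1e-3))
    return model, truth, act


class TestLikelihood:
    def test_known_point_beats_surrounding_grid(self):
        model, truth, _ = _toy_model(with_noise=False)
        theta0 = model.pack(**truth)
        ll0 = log_likelihood(model, theta0)
        # coarse grid around the true excitabilities
        for d0 in (-0.4, 0.4):
            for d1 in (-0.4, 0.4):
                t = dict(truth, x0=truth["x0"] + np.array([d0, d1]))
                assert log_likelihood(model, model.pack(**t)) < ll0

    def test_multimodal_is_sum_of_blocks(self):
        rng = np.random.default_rng(7)
        L, T = 3, 40
        W = np.abs(rng.standard_normal((L, L)))
        np.fill_diagonal(W, 0.0)
        W /= W.max()
        blocks = []
        for mod, C in (("seeg", 5), ("eeg", 4)):
            blocks.append(TargetBlock(
                modality=mod, labels=[f"{mod}{i}" for i in range(C)],
                times_s=np.arange(T) * 0.1,
                values=rng.standard_normal((C, T)),
                gain=np.abs(rng.standard_normal((L, C)))))
        both = build_generative_model(TargetBundle(blocks), W,
                                      normalize_gain=False)
        only = [build_generative_model(TargetBundle([b]), W,
                                       normalize_gain=False) for b in blocks]
        params = dict(x0=np.full(L, -2.0), xinit=np.full(L, -1.8),
                      zinit=np.full(L, 3.0), K=0.5, sigma=0.7)
        ll_both = log_likelihood(both, both.pack(
            alpha=[1.0, 2.0], beta=[0.1, -0.2], **params))
        ll_each = [log_likelihood(m, m.pack(alpha=[a], beta=[b], **params))
                   for m, a, b in zip(only, [1.0, 2.0], [0.1, -0.2])]
        assert ll_both == pytest.approx(sum(ll_each), rel=1e-12)

    def test_infinite_sigma_flattens(self):
        model, truth, _ = _toy_model()
        t1 = dict(truth, sigma=1e6)
        t2 = dict(truth, sigma=1e6, x0=truth["x0"] + 0.5)
        diff = abs(log_likelihood(model, model.pack(**t1))
                   - log_likelihood(model, model.pack(**t2)))
        assert diff < 1e-3

    def test_gradient_matches_finite_differences(self):
        stim = np.outer(np.arange(60) % 7 < 3, [0.5, 1.0])
        model, truth, _ = _toy_model(stim=stim)
        rng = np.random.default_rng(11)
        theta = inversion._random_init(model, rng)
        lp, grad = log_posterior_and_grad(model, theta)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (log_posterior_and_grad(model, tp)[0]
                   - log_posterior_and_grad(model, tm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-5)


class TestMapEstimate:
    def test_results_sorted_and_deterministic(self):
        model, _, _ = _toy_model()
        res1 = map_estimate(model, n_restarts=6, n_keep=3, seed=9)
        res2 = map_estimate(model, n_restarts=6, n_keep=3, seed=9)
        assert all(a.logp >= b.logp for a, b in zip(res1, res1[1:]))
        for a, b in zip(res1, res2):
            assert np.array_equal(a.theta, b.theta)

    def test_recovers_excitability_on_noiseless_toy(self):
        model, truth, _ = _toy_model(with_noise=False)
        res = map_estimate(model, n_restarts=10, n_keep=2, seed=1)
        x0_hat = model.unpack(res[0].theta)["x0"]
        assert np.all(np.abs(x0_hat - truth["x0"]) < 0.1)

    def test_n_keep_validation(self):
        model, _, _ = _toy_model()
        with pytest.raises(ValueError):
            map_estimate(model, n_restarts=2, n_keep=5)


class TestNuts:
    @staticmethod
    def _gauss_logp(mu, prec):
        def f(theta):
            d = theta - mu
            return -0.5 * d @ prec @ d, -prec @ d
        return f

    def test_linear_gaussian_matches_closed_form(self):
        # Bayesian linear regression: y = X w + e has a Gaussian posterior
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        w_true = np.array([1.0, -0.5, 2.0])
        y = X @ w_true + 0.3 * rng.standard_normal(40)
        prec = X.T @ X / 0.09 + np.eye(3)
        mu = np.linalg.solve(prec, X.T @ y / 0.09)
        res = sample_nuts(self._gauss_logp(mu, prec), np.zeros(3),
                          n_draws=1500, n_warmup=500, seed=4)
        cov = np.linalg.inv(prec)
        se = np.sqrt(np.diag(cov) / 1500) * 5  # generous MC error margin
        assert np.all(np.abs(res.draws.mean(axis=0) - mu) < se * 3 + 0.05)
        assert np.allclose(np.cov(res.draws.T), cov, atol=0.1)

    def test_deterministic_given_seed(self):
        f = self._gauss_logp(np.zeros(2), np.eye(2))
        a = sample_nuts(f, np.ones(2), n_draws=50, n_warmup=50, seed=3)
        b = sample_nuts(f, np.ones(2), n_draws=50, n_warmup=50, seed=3)
        assert np.array_equal(a.draws, b.draws)

    def test_more_draws_reduce_error(self):
        # MC convergence: mean-estimate error shrinks with draws
        f = self._gauss_logp(np.zeros(1), np.eye(1))
        errs = {n: [] for n in (100, 400)}
        for seed in range(10):
            for n in errs:
                res = sample_nuts(f, np.array([2.0]), n_draws=n,
                                  n_warmup=100, seed=seed)
                errs[n].append(abs(res.draws.mean()))
        assert np.mean(errs[400]) < np.mean(errs[100])

    def test_nonfinite_start_rejected(self):
        def bad(theta):
            return -np.inf, np.zeros_like(theta)
        with pytest.raises(ValueError):
            sample_nuts(bad, np.zeros(2), n_draws=10, n_warmup=10, seed=0)


class TestDiagnostics:
    def test_identical_chains_rhat_exactly_one(self):
        chain = np.sin(np.arange(200.0))
        assert split_rhat(np.vstack([chain, chain, chain])) == 1.0

    def test_white_noise_ess_near_n(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(5):
            chains = rng.standard_normal((4, 500))
            vals.append(effective_sample_size(chains))
        assert np.mean(vals) == pytest.approx(2000, rel=0.2)

    def test_ar1_ess_much_smaller(self):
        rng = np.random.default_rng(6)
        rho, n = 0.9, 2000
        x = np.zeros((2, n))
        for t in range(1, n):
            x[:, t] = rho * x[:, t - 1] + rng.standard_normal(2)
        ess = effective_sample_size(x)
        # AR(1) closed form: ESS / n = (1 - rho) / (1 + rho) ~ 0.053
        assert ess < 0.15 * 2 * n
        assert ess == pytest.approx(2 * n * (1 - rho) / (1 + rho), rel=0.6)

    def test_cross_check_against_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(7)
        rho, n = 0.5, 600
        chains = np.zeros((4, n))
        for t in range(1, n):
            chains[:, t] = rho * chains[:, t - 1] + rng.standard_normal(4)
        ours_ess = effective_sample_size(chains)
        ref_ess = float(arviz.ess(chains))
        assert ours_ess == pytest.approx(ref_ess, rel=0.3)
        ours_rhat = split_rhat(chains)
        ref_rhat = float(arviz.rhat(chains))
        assert ours_rhat == pytest.approx(ref_rhat, abs=0.1)

    def test_report_shape_and_single_chain_warning(self):
        model, truth, _ = _toy_model()
        theta = model.pack(**truth)
        post = sample_posterior(model, [theta], n_chains=1, draws=40,
                                warmup=40, seed=0)
        with pytest.warns(UserWarning, match="single chain"):
            df = convergence_diagnostics(post)
        assert {"parameter", "rhat", "ess"} <= set(df.columns)
        assert df["rhat"].isna().all()


class TestPosterior:
    def test_seeded_run_reproducible(self):
        model, truth, _ = _toy_model()
        theta = model.pack(**truth)
        a = sample_posterior(model, [theta], n_chains=2, draws=30,
                             warmup=30, seed=12)
        b = sample_posterior(model, [theta], n_chains=2, draws=30,
                             warmup=30, seed=12)
        assert np.array_equal(a.theta, b.theta)

    def test_region_permutation_equivariance(self):
        # identical priors per region: permuting regions in data + gains
        # permutes the log posterior's argument without changing its value
        model, truth, _ = _toy_model(L=3, x0_true=[-1.6, -2.5, -2.1])
        perm = np.array([2, 0, 1])
        blk = TargetBlock(modality="seeg",
                          labels=[f"c{i}" for i in range(6)],
                          times_s=np.arange(model.n_times) * 0.1,
                          values=model.targets[0],
                          gain=model.gains[0][perm])
        permuted = build_generative_model(
            TargetBundle([blk]), model.C[np.ix_(perm, perm)],
            dt=model.dt, tau0=model.tau0, normalize_gain=False)
        params = dict(xinit=truth["xinit"], zinit=truth["zinit"],
                      K=truth["K"], alpha=truth["alpha"],
                      beta=truth["beta"], sigma=0.3)
        lp1, _ = log_posterior_and_grad(
            model, model.pack(x0=truth["x0"], **params))
        lp2, _ = log_posterior_and_grad(
            permuted, permuted.pack(x0=truth["x0"][perm],
                                    xinit=params["xinit"][perm],
                                    zinit=params["zinit"][perm],
                                    K=params["K"], alpha=params["alpha"],
                                    beta=params["beta"],
                                    sigma=params["sigma"]))
        assert lp1 == pytest.approx(lp2, rel=1e-10)

    def test_recovery_with_highest_median_x0(self):
        # data from the 2D model with one elevated region: that region
        # attains the highest posterior median excitability
        hits = 0
        for seed in range(3):
            model, truth, _ = _toy_model(L=4, C=10, seed=seed,
                                         x0_true=[-2.5, -1.6, -2.5, -2.5])
            maps = map_estimate(model, n_restarts=8, n_keep=3, seed=seed)
            post = sample_posterior(model, [m.theta for m in maps],
                                    n_chains=2, draws=150, warmup=150,
                                    seed=seed)
            med = np.median(post.x0.reshape(-1, 4), axis=0)
            hits += int(np.argmax(med) == 1)
        assert hits >= 2

    def test_multimodal_not_less_informative(self):
        # posterior sd of the elevated region's x0 under SEEG + EEG is at
        # most its sd under SEEG alone (seed-averaged)
        rng = np.random.default_rng(0)
        L, T = 3, 60
        x0_true = np.array([-1.6, -2.5, -2.5])
        W = np.abs(rng.standard_normal((L, L)))
        np.fill_diagonal(W, 0.0)
        W /= W.max()
        p = Reduced2DParams(x0=x0_true, C=W, tau0=10.0, K=0.3)
        xin = np.full(L, -2.0)
        zin = np.full(L, 2.5)
        act = simulate_reduced_2d(p, (xin, zin), dt=0.1, T=(T - 1) * 0.1)

        def block(mod, C, seed):
            r = np.random.default_rng(seed)
            g = np.abs(r.standard_normal((L, C))) ** 2
            g /= g.max()
            y = 1.5 * (g.T @ act.values) + 0.05 * r.standard_normal((C, T))
            return TargetBlock(modality=mod,
                               labels=[f"{mod}{i}" for i in range(C)],
                               times_s=act.times, values=y, gain=g)

        sds = {"seeg": [], "multi": []}
        for seed in range(2):
            blocks = [block("seeg", 8, 10 + seed), block("eeg", 6, 20 + seed)]
            for name, blks in (("seeg", blocks[:1]), ("multi", blocks)):
                m = build_generative_model(TargetBundle(blks), W, dt=0.1,
                                           tau0=10.0)
                maps = map_estimate(m, n_restarts=6, n_keep=2, seed=seed)
                post = sample_posterior(m, [mm.theta for mm in maps],
                                        n_chains=2, draws=150, warmup=150,
                                        seed=seed)
                sds[name].append(post.x0.reshape(-1, L)[:, 0].std())
        assert np.mean(sds["multi"]) <= np.mean(sds["seeg"]) * 1.1
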