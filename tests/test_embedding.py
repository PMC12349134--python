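"""Splits, ELBO mechanics, CVAE training behavior, PCA baseline, selection."""

import numpy as np
import pytest
from scipy import integrate, stats

import phenostrat as ps
from phenostrat.cvae import CVAEConfig, CVAEModel, _Frontend, _batch_grads, _init_params, elbo_loss
from phenostrat.selection import mse_test, reconstruction_mse, select_architecture
from phenostrat.splits import stratified_split
from conftest import make_table


# ---------------------------------------------------------------- splits
class TestStratifiedSplit:
    def test_divisible_case_exact(self):
        sites = np.repeat(np.arange(10), 10)  # 100 participants, 10 equal sites
        sp = stratified_split(100, sites, seed=0)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (80, 10, 10)
        for s in range(10):
            assert np.sum(sites[sp.train] == s) == 8
            assert np.sum(sites[sp.val] == s) == 1
            assert np.sum(sites[sp.test] == s) == 1

    def test_partition_exhaustive_disjoint_and_deterministic(self):
        rng = np.random.default_rng(1)
        sites = rng.integers(0, 7, size=503)
        a = stratified_split(503, sites, seed=5)
        b = stratified_split(503, sites, seed=5)
        allidx = np.concatenate([a.train, a.val, a.test])
        assert sorted(allidx.tolist()) == list(range(503))
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_per_site_train_fraction_counting_oracle(self):
        rng = np.random.default_rng(2)
        sites = rng.choice([0, 1, 2, 3, 4], size=1000, p=[0.4, 0.25, 0.15, 0.12, 0.08])
        sp = stratified_split(1000, sites, seed=3)
        for s in range(5):
            n_s = np.sum(sites == s)
            frac = np.sum(sites[sp.train] == s) / n_s
            assert 0.8 - 1.5 / n_s <= frac <= 0.8 + 1.5 / n_s

    def test_tiny_site_rejected(self):
        sites = np.array([0] * 50 + [1] * 2)
        with pytest.raises(ValueError, match="fewer than 3"):
            stratified_split(52, sites)


# ---------------------------------------------------------------- ELBO
def _toy_model(input_dim=3, latent_dim=3, hidden_dim=3, activation="linear", seed=0):
    cfg = CVAEConfig(frontend_dim=None, hidden_dim=hidden_dim, latent_dim=latent_dim,
                     condition_on_site=False, activation=activation, seed=seed)
    params = _init_params(cfg, input_dim, 0, np.random.default_rng(seed))
    return CVAEModel(config=cfg, params=params, frontend=_Frontend.identity(),
                     site_categories=None, ambient_dim=input_dim)


class TestElbo:
    def test_posterior_equal_to_prior_gives_zero_kl(self):
        m = _toy_model()
        for k in m.params:
            m.params[k] = np.zeros_like(m.params[k])  # mu = 0, logvar = 0
        x = np.random.default_rng(0).normal(size=(5, 3))
        _, _, kl = elbo_loss(x, None, m)
        assert kl == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_kl_matches_quadrature_oracle(self):
        """KL(N(1,1) || N(0,1)) = 0.5, cross-checked by numerical integration."""
        m = _toy_model(input_dim=1, latent_dim=1, hidden_dim=1)
        for k in m.params:
            m.params[k] = np.zeros_like(m.params[k])
        m.params["eb2"] = np.array([1.0, 0.0])  # mu = 1, logvar = 0
        _, _, kl = elbo_loss(np.zeros((4, 1)), None, m)

        q = stats.norm(1.0, 1.0)
        p = stats.norm(0.0, 1.0)
        oracle, _ = integrate.quad(
            lambda t: q.pdf(t) * (q.logpdf(t) - p.logpdf(t)), -10, 10
        )
        assert kl == pytest.approx(oracle, abs=1e-9)
        assert kl == pytest.approx(0.5, abs=1e-12)

    def test_perfect_reconstruction_zero_error(self):
        # identity network: mu = x, decoder returns z
        d = 3
        m = _toy_model(input_dim=d, latent_dim=d, hidden_dim=d)
        z0 = {k: np.zeros_like(v) for k, v in m.params.items()}
        m.params = z0
        m.params["eW1"] = np.eye(d)
        m.params["eW2"] = np.concatenate([np.eye(d), np.zeros((d, d))], axis=1)
        m.params["dW1"] = np.eye(d)
        m.params["dW2"] = np.eye(d)
        x = np.random.default_rng(1).normal(size=(6, d))
        _, recon, _ = elbo_loss(x, None, m)
        assert recon == pytest.approx(0.0, abs=1e-18)

    def test_kl_always_nonnegative(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            m = _toy_model(seed=seed, activation="relu")
            x = rng.normal(size=(8, 3))
            _, _, kl = elbo_loss(x, None, m)
            assert kl >= 0.0


def test_backprop_matches_finite_differences():
    """Hand-derived gradients vs central differences on every parameter."""
    cfg = CVAEConfig(frontend_dim=None, hidden_dim=4, latent_dim=2,
                     condition_on_site=True, activation="relu", beta=0.7, seed=0)
    rng = np.random.default_rng(0)
    params = _init_params(cfg, 5, 2, rng)
    m = CVAEModel(config=cfg, params=params, frontend=_Frontend.identity(),
                  site_categories=np.array([0, 1]), ambient_dim=5)
    x = np.random.default_rng(1).normal(size=(7, 5))
    c = np.zeros((7, 2))
    c[np.arange(7), np.random.default_rng(2).integers(0, 2, 7)] = 1.0

    def loss_with(eps_rng_seed=9):
        g, loss = _batch_grads(m, x, c, np.random.default_rng(eps_rng_seed))
        return g, loss

    grads, _ = loss_with()
    h = 1e-6
    for key in m.params:
        flat = m.params[key].ravel()
        for idx in [0, flat.size // 2, flat.size - 1]:
            orig = flat[idx]
            flat[idx] = orig + h
            _, lp = loss_with()
            flat[idx] = orig - h
            _, lm = loss_with()
            flat[idx] = orig
            fd = (lp - lm) / (2 * h)
            assert grads[key].ravel()[idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)


# ---------------------------------------------------------------- training
class TestTraining:
    def test_validation_loss_decreases(self, small_curated, small_split, small_model):
        hist = small_model.history["val_loss"]
        assert hist[-1] < hist[0]

    def test_seeded_training_is_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 30))
        sites = rng.integers(0, 2, size=200)
        sp = stratified_split(200, sites, seed=1)
        cfg = ps.CVAEConfig(frontend_dim=None, hidden_dim=16, latent_dim=5,
                            max_epochs=20, seed=11)
        m1 = ps.train_cvae(x, sites, sp, cfg)
        m2 = ps.train_cvae(x, sites, sp, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_reconstruct_posterior_mean_deterministic_and_sample_seeded(self, small_model, small_curated):
        curated, _, truth = small_curated
        x = curated.as_array()[:10]
        s = truth.site_labels[:10]
        a = small_model.reconstruct(x, s)
        b = small_model.reconstruct(x, s)
        np.testing.assert_array_equal(a, b)
        r1 = small_model.reconstruct(x, s, mode="sample", rng=np.random.default_rng(5))
        r2 = small_model.reconstruct(x, s, mode="sample", rng=np.random.default_rng(5))
        np.testing.assert_array_equal(r1, r2)
        assert not np.allclose(a, r1)

    def test_unseen_site_label_rejected(self, small_model, small_curated):
        curated, _, _ = small_curated
        with pytest.raises(ValueError, match="not seen during training"):
            small_model.encode(curated.as_array()[:2], np.array([999, 999]))

    def test_conditioning_absorbs_site_offsets(self):
        """With strong batch effects, the conditioned model reconstructs
        held-out data better than an unconditioned twin for most seeds."""
        wins = 0
        seeds = [0, 1, 2]
        for seed in seeds:
            cfg = ps.GeneratorConfig(n_participants=700, n_variables=60, n_sites=6,
                                     site_effect_sd=2.0, missing_rate=0.0,
                                     outlier_rate=0.0, frac_discrete=0.0, seed=seed)
            table, truth = ps.generate_phenome(cfg)
            cur, _ = ps.curate(table)
            sp = stratified_split(cur, truth.site_labels, seed=seed)
            common = dict(frontend_dim=40, hidden_dim=32, latent_dim=8,
                          learning_rate=2e-3, max_epochs=60, patience=60, seed=seed)
            mc = ps.train_cvae(cur, truth.site_labels, sp, ps.CVAEConfig(**common))
            mu = ps.train_cvae(cur, None, sp,
                               ps.CVAEConfig(condition_on_site=False, **common))
            x = cur.as_array()
            if mse_test(mc, x, truth.site_labels, sp) < mse_test(mu, x, None, sp):
                wins += 1
        assert wins >= 2

    def test_checkpoint_roundtrip_preserves_behavior(self, small_model, small_curated, tmp_path):
        from phenostrat.cvae import load_model, save_model

        curated, _, truth = small_curated
        p = tmp_path / "model.npz"
        save_model(small_model, p)
        twin = load_model(p)
        x = curated.as_array()[:8]
        s = truth.site_labels[:8]
        np.testing.assert_array_equal(small_model.reconstruct(x, s), twin.reconstruct(x, s))
        assert twin.config == small_model.config

    def test_divergence_raises_informative_error(self):
        # squared error of entries this large overflows to inf immediately
        rng = np.random.default_rng(4)
        x = rng.normal(size=(120, 10)) * 1e160
        sites = rng.integers(0, 2, size=120)
        sp = stratified_split(120, sites, seed=0)
        cfg = ps.CVAEConfig(frontend_dim=None, hidden_dim=16, latent_dim=4,
                            max_epochs=50, seed=0)
        from phenostrat.cvae import TrainingDivergedError
        with pytest.raises(TrainingDivergedError, match="learning rate"):
            ps.train_cvae(x, sites, sp, cfg)


# ---------------------------------------------------------------- PCA baseline
class TestPCABaseline:
    def test_train_mse_equals_discarded_eigenvalues(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(150, 12)) @ rng.normal(size=(12, 12))
        sp = stratified_split(150, np.zeros(150, int), seed=0)
        k = 4
        pca = ps.fit_pca_baseline(x, sp, n_components=k)
        got = reconstruction_mse(pca, x[sp.train])
        # eigendecomposition oracle on the train covariance
        xt = x[sp.train]
        cov = np.cov(xt, rowvar=False, ddof=0)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = evals[k:].sum()
        assert got == pytest.approx(expected, rel=1e-6)

    def test_full_rank_reconstruction_is_exact(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(60, 8))
        sp = stratified_split(60, np.zeros(60, int), seed=0)
        pca = ps.fit_pca_baseline(x, sp, n_components=8)
        assert mse_test(pca, x, None, sp) == pytest.approx(0.0, abs=1e-20)

    def test_basis_orthonormal(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(100, 10))
        sp = stratified_split(100, np.zeros(100, int), seed=0)
        pca = ps.fit_pca_baseline(x, sp, n_components=5)
        np.testing.assert_allclose(pca.components_ @ pca.components_.T, np.eye(5), atol=1e-8)

    def test_too_many_components_rejected(self):
        x = np.random.default_rng(8).normal(size=(20, 5))
        sp = stratified_split(20, np.zeros(20, int), seed=0)
        with pytest.raises(ValueError, match="n_components"):
            ps.fit_pca_baseline(x, sp, n_components=10)


# ---------------------------------------------------------------- selection
class TestSelection:
    def test_zero_predictor_mse_is_total_power(self):
        class Zero:
            def reconstruct(self, x, site_labels=None):
                return np.zeros_like(x)

        rng = np.random.default_rng(9)
        x = rng.normal(size=(50, 20))
        x = (x - x.mean(0)) / x.std(0)
        sp = stratified_split(50, np.zeros(50, int), seed=0)
        got = mse_test(Zero(), x, None, sp)
        assert got == pytest.approx(float(np.mean(np.sum(x[sp.test] ** 2, axis=1))))

    def test_single_candidate_trivially_selected(self, small_curated, small_split):
        curated, _, truth = small_curated
        cfg = ps.CVAEConfig(frontend_dim=30, hidden_dim=16, latent_dim=8,
                            max_epochs=15)
        tbl = select_architecture([cfg], curated, truth.site_labels, small_split,
                                  n_replicates=2)
        assert tbl.winner == 0
        assert tbl.rows.loc[0, "n_ok"] == 2

    def test_higher_capacity_wins_on_nonlinear_data(self):
        cfg = ps.GeneratorConfig(n_participants=700, n_variables=60, frac_nonlinear=0.5,
                                 n_sites=4, missing_rate=0.0, outlier_rate=0.0, seed=13)
        table, truth = ps.generate_phenome(cfg)
        cur, _ = ps.curate(table)
        sp = stratified_split(cur, truth.site_labels, seed=13)
        small = ps.CVAEConfig(frontend_dim=None, hidden_dim=2, latent_dim=2,
                              max_epochs=40, patience=40)
        big = ps.CVAEConfig(frontend_dim=None, hidden_dim=64, latent_dim=12,
                            max_epochs=40, patience=40)
        tbl = select_architecture([small, big], cur, truth.site_labels, sp,
                                  n_replicates=5, keep_models=False)
        assert tbl.winner == 1

    def test_empty_candidates_rejected(self, small_curated, small_split):
        curated, _, truth = small_curated
        with pytest.raises(ValueError):
            select_architecture([], curated, truth.site_labels, small_split)
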