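"""Classifier suite conformance and the deep models' loss wiring."""

import numpy as np
import pytest
from scipy.special import expit

from methbench import (JointAE, JointVAE, ModelSpec, SimpleDNN,
                       gaussian_kl, joint_ae_total_loss,
                       reconstruction_quality, train, vae_total_loss)
from methbench.models import MODEL_FAMILIES


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(17)
    n, k = 120, 12
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 0.5, (n, k)) + y[:, None] * 4.0
    return X, y


DEEP_HP = {"epochs": 60, "lr": 1e-3}


class TestConformance:
    @pytest.mark.parametrize("family", MODEL_FAMILIES)
    def test_separable_data_learned_and_scores_bounded(self, family, separable):
        X, y = separable
        hp = dict(DEEP_HP) if family in ("simple_dnn", "joint_ae",
                                         "joint_vae") else {}
        model = train(ModelSpec(family, hyperparameters=hp, seed=2), X, y)
        s = model.score(X)
        assert s.shape == (len(y),)
        assert s.min() >= 0.0 and s.max() <= 1.0
        acc = ((s >= 0.5) == y).mean()
        assert acc == 1.0, f"{family} failed to separate (acc={acc})"

    def test_constant_features_score_near_prevalence(self):
        X = np.ones((100, 5))
        y = np.array([1] * 70 + [0] * 30)
        m = train(ModelSpec("logreg_l2"), X, y)
        assert np.allclose(m.score(X), 0.7, atol=0.05)

    @pytest.mark.parametrize("family", ["random_forest", "joint_ae"])
    def test_same_seed_reproducible(self, family, separable):
        X, y = separable
        hp = dict(DEEP_HP) if family == "joint_ae" else {}
        s1 = train(ModelSpec(family, hyperparameters=hp, seed=7), X, y).score(X)
        s2 = train(ModelSpec(family, hyperparameters=hp, seed=7), X, y).score(X)
        tol = 1e-6 if family == "joint_ae" else 0.0
        np.testing.assert_allclose(s1, s2, atol=tol)

    def test_nan_features_rejected(self, separable):
        X, y = separable
        X = X.copy()
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(ModelSpec("logreg_l2"), X, y)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("gradient_rocket")


class TestLossFunctions:
    def test_joint_loss_weighted_average(self):
        assert joint_ae_total_loss(1.0, 1.0, 0.3) == 1.0
        assert joint_ae_total_loss(0.2, 0.6, 0.5) == pytest.approx(0.4)
        assert joint_ae_total_loss(0.2, 9.9, 1.0) == pytest.approx(0.2)

    def test_joint_loss_weight_domain(self):
        with pytest.raises(ValueError):
            joint_ae_total_loss(1.0, 1.0, 1.5)

    def test_kl_zero_at_prior(self):
        mu = np.zeros((4, 32))
        logvar = np.zeros((4, 32))
        assert gaussian_kl(mu, logvar) == pytest.approx(0.0)

    def test_kl_single_unit_shifted_mean(self):
        assert gaussian_kl(np.array([[1.0]]),
                           np.array([[0.0]])) == pytest.approx(0.5)

    def test_vae_total_additive(self):
        assert vae_total_loss(1.0, 0.5, 2.0, 0.0 + 1e-12) == pytest.approx(1.5, abs=1e-9)
        assert vae_total_loss(1.0, 0.5, 2.0, 2.0) == pytest.approx(5.5)

    def test_vae_negative_kl_rejected(self):
        with pytest.raises(ValueError):
            vae_total_loss(1.0, -0.1, 1.0, 1.0)


class TestGradients:
    def test_joint_ae_backprop_matches_finite_differences(self):
        """Analytic gradient of the joint loss vs central differences."""
        rng = np.random.default_rng(3)
        net = JointAE(6, scale="M", loss_weight=0.5, seed=4)
        X = rng.normal(0, 1, (8, 6))
        y = np.array([0, 1] * 4, dtype=float)

        def total_loss():
            z = net._encode(X)
            xhat = net._decode(z)
            p = np.clip(expit(net._classify(z)), 1e-12, 1 - 1e-12)
            recon = float(np.mean((xhat - X) ** 2))
            clf = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
            return joint_ae_total_loss(recon, clf, net.w)

        # one analytic backward pass
        z = net._encode(X)
        xhat = net._decode(z)
        p = expit(net._classify(z))
        _, d_dec = net._recon_loss_grad(xhat, X)
        g = net.decoder[-1].backward_from_logits(net.w * d_dec)
        for layer in reversed(net.decoder[:-1]):
            g = layer.backward(g)
        dz = g
        dlogits = (1 - net.w) * ((p - y) / len(y))[:, None]
        g = net.head[-1].backward_from_logits(dlogits)
        for layer in reversed(net.head[:-1]):
            g = layer.backward(g)
        g = dz + g
        for layer in reversed(net.encoder):
            g = layer.backward(g)

        eps = 1e-6
        for layer, (i, j) in [(net.encoder[0], (0, 0)),
                              (net.decoder[1], (3, 2)),
                              (net.head[0], (5, 1))]:
            analytic = layer.dW[i, j]
            layer.W[i, j] += eps
            up = total_loss()
            layer.W[i, j] -= 2 * eps
            down = total_loss()
            layer.W[i, j] += eps
            numeric = (up - down) / (2 * eps)
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestReconstruction:
    def _smooth(self, n=300, p=40, rank=4, seed=0):
        rng = np.random.default_rng(seed)
        Z = rng.normal(0, 1, (n, rank))
        W = rng.normal(0, 1, (rank, p))
        X = Z @ W + rng.normal(0, 0.1, (n, p))
        y = (Z[:, 0] > 0).astype(int)
        return X, y

    def test_overfit_tiny_input(self):
        X, y = self._smooth(n=200, p=10, rank=2)
        net = JointAE(10, scale="M", lr=1e-3, seed=1).fit(X, y, epochs=300)
        assert net.reconstruction_quality(X) > 0.99

    def test_untrained_model_poor_reconstruction(self):
        X, y = self._smooth()
        net = JointAE(40, scale="M", seed=2)
        r = net.reconstruction_quality(X)
        assert -1.0 <= r <= 1.0
        assert abs(r) < 0.5

    def test_vae_reconstructs_smooth_data(self):
        X, y = self._smooth()
        net = JointVAE(40, scale="M", lr=1e-3, seed=3).fit(X, y, epochs=150)
        assert net.reconstruction_quality(X) > 0.9

    def test_non_autoencoder_rejected(self, separable):
        X, y = separable
        m = train(ModelSpec("random_forest"), X, y)
        with pytest.raises(ValueError, match="decoder"):
            reconstruction_quality(m, X)


class TestScaleWiring:
    def test_beta_model_uses_sigmoid_decoder(self):
        net = JointAE(10, scale="beta", seed=0)
        assert net.decoder[-1].activation == "sigmoid"
        net_m = JointAE(10, scale="M", seed=0)
        assert net_m.decoder[-1].activation == "linear"

    def test_beta_model_rejects_out_of_range(self):
        net = JointAE(5, scale="beta", seed=0)
        X = np.full((20, 5), 3.0)
        with pytest.raises(ValueError, match="beta"):
            net.fit(X, np.array([0, 1] * 10), epochs=1)

    def test_beta_scale_training_runs(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0.05, 0.95, (64, 12))
        y = np.array([0, 1] * 32)
        net = JointAE(12, scale="beta", lr=1e-3, seed=1).fit(X, y, epochs=20)
        recon = net.reconstruct(X)
        assert recon.min() >= 0 and recon.max() <= 1
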