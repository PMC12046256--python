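"""Training engine: determinism, convergence, likelihood gradients, the
vanilla-VAE reduction, and checkpoint persistence."""

import numpy as np
import pytest
from scipy import stats

from synthcohort import RHVAEConfig, RHVAEState, RiemannianMetric
from synthcohort.nn import (
    MLP,
    gaussian_kl,
    recon_log_likelihood,
    recon_log_likelihood_grad,
)
from synthcohort.rhvae import TrainingError, train


@pytest.fixture
def mixed_batch(rng):
    """A small batch with 3 numeric and 3 discrete encoded columns."""
    x = rng.random((6, 6))
    x[:, 3:] = (x[:, 3:] > 0.5).astype(float)
    lam = np.clip(rng.random((6, 6)), 0.05, 0.95)
    mask = np.array([True, True, True, False, False, False])
    log_sigma = np.log(np.array([0.05, 0.2, 0.5]))
    return x, lam, mask, log_sigma


def test_recon_likelihood_matches_scipy(mixed_batch):
    """Gaussian columns agree with norm.logpdf, discrete with Bernoulli."""
    x, lam, mask, ls = mixed_batch
    ours = recon_log_likelihood(x, lam, mask, ls)
    ref = np.zeros(len(x))
    for i in range(len(x)):
        for j in range(6):
            if mask[j]:
                ref[i] += stats.norm.logpdf(
                    x[i, j], loc=lam[i, j], scale=np.exp(ls[j])
                )
            else:
                ref[i] += x[i, j] * np.log(lam[i, j]) + (1 - x[i, j]) * np.log(
                    1 - lam[i, j]
                )
    assert np.allclose(ours, ref, atol=1e-10)


def test_recon_likelihood_grad_matches_finite_differences(mixed_batch):
    x, lam, mask, ls = mixed_batch
    g_lam, g_ls = recon_log_likelihood_grad(x, lam, mask, ls)
    h = 1e-6
    for i in range(3):
        for j in range(6):
            d = np.zeros_like(lam)
            d[i, j] = h
            fd = (
                recon_log_likelihood(x, lam + d, mask, ls).sum()
                - recon_log_likelihood(x, lam - d, mask, ls).sum()
            ) / (2 * h)
            assert g_lam[i, j] == pytest.approx(fd, abs=1e-4)
    for k in range(3):
        d = np.zeros_like(ls)
        d[k] = h
        fd = (
            recon_log_likelihood(x, lam, mask, ls + d).sum()
            - recon_log_likelihood(x, lam, mask, ls - d).sum()
        ) / (2 * h)
        assert g_ls[k] == pytest.approx(fd, abs=1e-4)


def test_mlp_backward_matches_finite_differences(rng):
    net = MLP(rng, [4, 6, 3], out_activation="sigmoid")
    x = rng.standard_normal((5, 4))
    w_up = rng.standard_normal((5, 3))  # loss = sum(w_up * out)
    out = net.forward(x)
    din = net.backward(w_up)
    h = 1e-6
    W = net.W[0]
    i, j = 1, 2
    W[i, j] += h
    up = (net.forward(x, cache=False) * w_up).sum()
    W[i, j] -= 2 * h
    dn = (net.forward(x, cache=False) * w_up).sum()
    W[i, j] += h
    assert net.grads["W"][0][i, j] == pytest.approx((up - dn) / (2 * h), abs=1e-5)
    # input gradient
    xh = x.copy()
    xh[0, 1] += h
    up = (net.forward(xh, cache=False) * w_up).sum()
    xh[0, 1] -= 2 * h
    dn = (net.forward(xh, cache=False) * w_up).sum()
    assert din[0, 1] == pytest.approx((up - dn) / (2 * h), abs=1e-5)
    assert np.allclose(net.input_grad(x, w_up), din)


class TestTraining:
    def test_same_seed_identical_log(self, small_cohort):
        from synthcohort import TabularProcessor

        enc = TabularProcessor(small_cohort.schema).fit_transform(small_cohort)
        cfg = RHVAEConfig(epochs=3, seed=11)
        a = train(enc, cfg)
        b = train(enc, cfg)
        assert a.training_log == b.training_log
        c = train(enc, RHVAEConfig(epochs=3, seed=12))
        assert a.training_log != c.training_log

    def test_loss_decreases_materially(self, small_trained):
        log = small_trained.training_log
        assert len(log) == 120
        assert log[-1] < log[0]
        assert (log[0] - log[-1]) >= 0.2 * abs(log[0])

    def test_batch_size_exceeding_n_rejected(self, rng):
        X = rng.random((10, 5))
        with pytest.raises(TrainingError):
            train(X, RHVAEConfig(epochs=1, batch_size=32))

    def test_decoder_outputs_bounded(self, small_trained, rng):
        z = rng.standard_normal((100, small_trained.config.latent_dim)) * 3
        lam = small_trained.decode(z)
        assert lam.min() > 0.0 and lam.max() < 1.0

    def test_learned_noise_scales_are_plausible(self, small_trained, small_cohort):
        """Per-column noise sigmas stay below each column's marginal sd."""
        from synthcohort import TabularProcessor

        enc = TabularProcessor(small_cohort.schema).fit_transform(small_cohort)
        marginal_sd = enc.values[:, small_trained.numeric_mask].std(axis=0)
        sig = np.exp(small_trained.log_sigma)
        assert np.all(sig <= marginal_sd * 1.2)
        assert np.all(sig > 0)

    def test_beats_mean_predictor_on_gaussian_blob(self, rng):
        """2-D correlated blob, 200 epochs: reconstruction MSE < data variance.

        The blob is elongated (r ~ 0.9) so a latent code genuinely carries
        information; on an isotropic blob the ELBO optimum is the mean
        predictor itself and the comparison would be vacuous.
        """
        u = rng.standard_normal(200)
        v = rng.standard_normal(200)
        blob = 0.5 + 0.12 * np.stack([u, 0.9 * u + np.sqrt(1 - 0.81) * v], axis=1)
        blob = np.clip(blob, 0.01, 0.99)
        cfg = RHVAEConfig(
            latent_dim=2, hidden_layers=(16,), epochs=200, batch_size=32,
            n_leapfrog_steps=0, seed=5,
        )
        state = train(blob, cfg)
        mu, _ = state.encode(blob)
        recon = state.decode(mu)
        mse = float(np.mean((recon - blob) ** 2))
        var = float(np.mean((blob - blob.mean(axis=0)) ** 2))
        assert mse < var

    def test_checkpoint_round_trip(self, small_trained, tmp_path, rng):
        path = tmp_path / "model.npz"
        small_trained.save(path)
        back = RHVAEState.load(path)
        z = rng.standard_normal((7, small_trained.config.latent_dim))
        assert np.array_equal(back.decode(z), small_trained.decode(z))
        assert back.training_log == small_trained.training_log
        assert np.array_equal(back.log_sigma, small_trained.log_sigma)
        assert np.array_equal(
            back.metric.centroids, small_trained.metric.centroids
        )
        assert back.sidecar == small_trained.sidecar


def test_vanilla_vae_reduction_matches_independent_elbo(rng):
    """With no Hamiltonian steps the objective equals a from-scratch ELBO.

    The oracle recomputes the negative ELBO with direct formula
    transcription (explicit loops, scipy densities), independent of the
    engine's vectorised path.
    """
    X = np.clip(rng.random((16, 6)), 0.02, 0.98)
    X[:, 4:] = (X[:, 4:] > 0.5).astype(float)
    mask = np.array([True] * 4 + [False] * 2)

    from synthcohort.encoding import EncodedColumn, EncodedMatrix
    from synthcohort.schema import ColumnSpec, CohortSchema

    schema = CohortSchema(
        tuple(
            [ColumnSpec(f"n{i}", "numerical", min=0, max=1) for i in range(4)]
            + [ColumnSpec(f"b{i}", "binary", levels=("n", "y")) for i in range(2)]
        )
    )
    cmap = tuple(
        [EncodedColumn(f"n{i}", "scaled-numeric") for i in range(4)]
        + [EncodedColumn(f"b{i}", "binary") for i in range(2)]
    )
    enc = EncodedMatrix(
        values=X, schema=schema, column_map=cmap,
        scaler_state={f"n{i}": (0.0, 1.0) for i in range(4)},
    )
    cfg = RHVAEConfig(
        latent_dim=3, hidden_layers=(8,), epochs=2, batch_size=8,
        n_leapfrog_steps=0, seed=3,
    )
    state = train(enc, cfg)
    eps = rng.standard_normal((16, 3))
    engine_value = state.negative_elbo(X, eps)

    # independent oracle ---------------------------------------------------
    mu, logvar = state.encode(X)
    z = mu + np.exp(0.5 * logvar) * eps
    lam = state.decode(z)
    sig = np.exp(state.log_sigma)
    total = 0.0
    for i in range(16):
        ll = 0.0
        for j in range(6):
            if mask[j]:
                ll += stats.norm.logpdf(X[i, j], loc=lam[i, j],
                                        scale=sig[list(mask[:j]).count(True)])
            else:
                l_ = min(max(lam[i, j], 1e-6), 1 - 1e-6)
                ll += X[i, j] * np.log(l_) + (1 - X[i, j]) * np.log(1 - l_)
        kl = 0.0
        for k in range(3):
            kl += 0.5 * (mu[i, k] ** 2 + np.exp(logvar[i, k]) - 1 - logvar[i, k])
        total += -ll + kl
    oracle = total / 16
    assert engine_value == pytest.approx(oracle, abs=1e-5)


def test_observation_sampling_is_seeded_and_schema_shaped(small_trained, rng):
    lam = small_trained.decode(
        rng.standard_normal((20, small_trained.config.latent_dim))
    )
    a = small_trained.sample_observation(lam, np.random.default_rng(5))
    b = small_trained.sample_observation(lam, np.random.default_rng(5))
    assert np.array_equal(a, b)
    assert a.min() >= 0.0 and a.max() <= 1.0
    # discrete columns come out hard 0/1, one-hot blocks sum to 1
    disc = ~small_trained.numeric_mask
    assert set(np.unique(a[:, disc])) <= {0.0, 1.0}


def test_identity_metric_is_flat():
    m = RiemannianMetric.identity(3, regularization=1.0)
    z = np.random.default_rng(0).standard_normal((4, 3))
    assert np.allclose(m.inverse(z), np.eye(3))
    assert np.allclose(m.grad_log_det_inverse(z), 0.0)
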