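"""Geometry-based variational autoencoder for HDLSS tabular cohorts.

The model is a VAE whose latent space carries a learned Riemannian metric:
tanh-MLP encoder (design vector -> posterior mean and log-variance) and
sigmoid-MLP decoder (latent point -> [0,1]-bounded reconstruction means),
trained on the ELBO with a mixed reconstruction likelihood — Gaussian with
learned per-column noise scale on scaled numeric columns, Bernoulli
cross-entropy on binary/one-hot columns.  During training the posterior
sample can be refined by a few generalized-leapfrog steps of Hamiltonian
dynamics under the current metric — exploring the posterior along the
manifold rather than isotropically — and the metric itself (centroids at
posterior means of a training subsample, diagonal triangular factors at
inverse posterior scales) tracks the encoder by exponential moving average.

Two stabilisers for the high-dimension/low-sample-size regime: the KL term
is warmed up linearly over the first 30% of epochs (counteracting early
posterior collapse), and the learned noise scales are clamped away from
zero (stopping variance collapse onto individual training records).

Gradients through the Hamiltonian refinement are taken straight-through
(the trajectory endpoint is used in the loss, its displacement treated as
constant in backward), which keeps the exact vanilla-VAE objective when
the refinement is disabled.  With ``n_leapfrog_steps=0`` and an identity
metric the engine IS a plain VAE, a reduction the tests exploit.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encoding import EncodedMatrix
from .metric import RiemannianMetric
from .hamiltonian import leapfrog_integrate
from .nn import (
    MLP,
    Adam,
    gaussian_kl,
    recon_log_likelihood,
    recon_log_likelihood_grad,
)

Array = np.ndarray

_LOGVAR_CLIP = 8.0
_SIGMA_FLOOR = 1e-2
_WARMUP_FRACTION = 0.5


class TrainingError(RuntimeError):
    pass


@dataclass
class RHVAEConfig:
    """Hyperparameters of the geometry-based VAE.

    ``epochs``, ``batch_size`` and ``learning_rate`` default to the
    training recipe the pipeline was designed around (1000 epochs, batches
    of 32, Adam at 1e-3); the remaining values are engine defaults sized
    for a few-hundred-patient, ~100-column cohort.
    """

    latent_dim: int = 10
    hidden_layers: tuple[int, ...] = (64, 32)
    epochs: int = 1000
    batch_size: int = 32
    learning_rate: float = 1e-3
    n_leapfrog_steps: int = 3
    leapfrog_step_size: float = 0.01
    metric_temperature: float = 0.8
    metric_regularization: float = 1e-3
    n_metric_centroids: int | None = None  # default: n_train, capped at 400
    centroid_ema: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.latent_dim, self.epochs, self.batch_size) <= 0:
            raise ValueError("latent_dim, epochs, batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.metric_temperature <= 0 or self.metric_regularization <= 0:
            raise ValueError("metric temperature/regularization must be positive")
        if self.n_leapfrog_steps < 0:
            raise ValueError("n_leapfrog_steps must be >= 0")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["hidden_layers"] = list(self.hidden_layers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RHVAEConfig":
        d = dict(d)
        d["hidden_layers"] = tuple(d.get("hidden_layers", (64, 32)))
        return cls(**d)


@dataclass
class RHVAEState:
    """Trained model: networks, metric, noise scales, log and sidecar."""

    config: RHVAEConfig
    encoder: MLP
    decoder: MLP
    metric: RiemannianMetric
    numeric_mask: Array  # (d,) bool: which encoded columns are numeric
    log_sigma: Array  # learned per-numeric-column noise log-scales
    training_log: list[float] = field(default_factory=list)
    sidecar: dict | None = None  # EncodedMatrix sidecar for decoding
    trained: bool = False

    # -- inference ---------------------------------------------------------
    def encode(self, X: Array) -> tuple[Array, Array]:
        """Posterior mean and log-variance for a batch of design rows."""
        out = self.encoder.forward(np.atleast_2d(X), cache=False)
        dz = self.config.latent_dim
        mu, logvar = out[:, :dz], np.clip(out[:, dz:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return mu, logvar

    def decode(self, z: Array) -> Array:
        """Decoder (reconstruction means) in (0,1) per coordinate."""
        return self.decoder.forward(np.atleast_2d(z), cache=False)

    def sample_observation(self, lam: Array, rng: np.random.Generator) -> Array:
        """Draw x ~ p(x | lam) from the observation model.

        Numeric columns: Gaussian around the decoded mean with the learned
        per-column sigma, clipped to [0, 1].  Binary columns: Bernoulli.
        One-hot blocks: one categorical draw per block from the normalised
        decoder outputs.  Generation samples the full generative model
        p(z) p(x|z) rather than returning conditional means, so artificial
        records carry the same kind of record-level noise real ones do.
        """
        lam = np.atleast_2d(lam)
        out = lam.copy()
        sig = np.exp(self.log_sigma)
        noise = rng.standard_normal((len(lam), int(self.numeric_mask.sum())))
        out[:, self.numeric_mask] = np.clip(
            lam[:, self.numeric_mask] + sig * noise, 0.0, 1.0
        )
        if self.sidecar is not None:
            cmap = self.sidecar["column_map"]
        else:
            cmap = [{"role": "scaled-numeric"}] * lam.shape[1]
        j = 0
        while j < lam.shape[1]:
            role = cmap[j]["role"]
            if role == "binary":
                out[:, j] = (rng.random(len(lam)) < lam[:, j]).astype(float)
                j += 1
            elif role == "one-hot":
                k = j
                while k < lam.shape[1] and cmap[k]["role"] == "one-hot" and (
                    cmap[k]["source"] == cmap[j]["source"]
                ):
                    k += 1
                block = lam[:, j:k]
                p = block / np.maximum(block.sum(axis=1, keepdims=True), 1e-12)
                u = rng.random((len(lam), 1))
                idx = (p.cumsum(axis=1) < u).sum(axis=1)
                hot = np.zeros_like(block)
                hot[np.arange(len(lam)), idx] = 1.0
                out[:, j:k] = hot
                j = k
            else:
                j += 1
        return out

    def negative_elbo(self, X: Array, eps: Array) -> float:
        """Mean negative ELBO on a batch with externally supplied noise.

        Uses the plain reparameterised sample z = mu + sigma * eps (no
        Hamiltonian refinement), so with an identity metric this is exactly
        the vanilla-VAE objective — comparable against an independent
        implementation.
        """
        mu, logvar = self.encode(X)
        z = mu + np.exp(0.5 * logvar) * eps
        lam = self.decode(z)
        ll = recon_log_likelihood(X, lam, self.numeric_mask, self.log_sigma)
        return float(np.mean(-ll + gaussian_kl(mu, logvar)))

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + metric + config + sidecar."""
        arrays: dict[str, Array] = {}
        for tag, net in (("enc", self.encoder), ("dec", self.decoder)):
            for i, W in enumerate(net.W):
                arrays[f"{tag}_W{i}"] = W
            for i, b in enumerate(net.b):
                arrays[f"{tag}_b{i}"] = b
        arrays["metric_centroids"] = self.metric.centroids
        arrays["metric_factors"] = self.metric.factors
        arrays["numeric_mask"] = self.numeric_mask
        arrays["log_sigma"] = self.log_sigma
        arrays["training_log"] = np.asarray(self.training_log, dtype=float)
        manifest = {
            "format": "synthcohort-rhvae",
            "version": 1,
            "trained": self.trained,
            "config": self.config.to_dict(),
            "metric": {
                "temperature": self.metric.temperature,
                "regularization": self.metric.regularization,
            },
            "sidecar": self.sidecar,
            "encoder_sizes": self.encoder.sizes,
            "decoder_sizes": self.decoder.sizes,
        }
        arrays["manifest"] = np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8
        )
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "RHVAEState":
        with np.load(Path(path), allow_pickle=False) as npz:
            manifest = json.loads(bytes(npz["manifest"]).decode())
            config = RHVAEConfig.from_dict(manifest["config"])
            rng = np.random.default_rng(0)
            encoder = MLP(rng, manifest["encoder_sizes"], out_activation="linear")
            decoder = MLP(rng, manifest["decoder_sizes"], out_activation="sigmoid")
            for tag, net in (("enc", encoder), ("dec", decoder)):
                net.W = [npz[f"{tag}_W{i}"].copy() for i in range(len(net.W))]
                net.b = [npz[f"{tag}_b{i}"].copy() for i in range(len(net.b))]
            metric = RiemannianMetric(
                centroids=npz["metric_centroids"].copy(),
                factors=npz["metric_factors"].copy(),
                temperature=manifest["metric"]["temperature"],
                regularization=manifest["metric"]["regularization"],
            )
            numeric_mask = npz["numeric_mask"].copy()
            log_sigma = npz["log_sigma"].copy()
            log = [float(v) for v in npz["training_log"]]
        return cls(
            config=config,
            encoder=encoder,
            decoder=decoder,
            metric=metric,
            numeric_mask=numeric_mask,
            log_sigma=log_sigma,
            training_log=log,
            sidecar=manifest["sidecar"],
            trained=bool(manifest["trained"]),
        )


def _build_networks(config: RHVAEConfig, d: int, rng: np.random.Generator):
    dz = config.latent_dim
    hidden = list(config.hidden_layers)
    encoder = MLP(rng, [d] + hidden + [2 * dz], out_activation="linear")
    decoder = MLP(rng, [dz] + hidden[::-1] + [d], out_activation="sigmoid")
    return encoder, decoder


def _posterior_at(encoder: MLP, X: Array, dz: int) -> tuple[Array, Array]:
    out = encoder.forward(X, cache=False)
    mu = out[:, :dz]
    sigma = np.exp(0.5 * np.clip(out[:, dz:], -_LOGVAR_CLIP, _LOGVAR_CLIP))
    return mu, np.maximum(sigma, _SIGMA_FLOOR)


def _metric_from_moments(
    mu: Array, sigma: Array, config: RHVAEConfig
) -> RiemannianMetric:
    dz = mu.shape[1]
    factors = np.zeros((len(mu), dz, dz))
    idx = np.arange(dz)
    factors[:, idx, idx] = 1.0 / sigma
    return RiemannianMetric(
        centroids=mu,
        factors=factors,
        temperature=config.metric_temperature,
        regularization=config.metric_regularization,
    )


def train(encoded: EncodedMatrix | Array, config: RHVAEConfig) -> RHVAEState:
    """Fit the geometry-based VAE on an encoded cohort.

    One seed (``config.seed``) controls weight initialisation, batch
    shuffling, reparameterisation noise and momentum draws, so the
    training log is reproducible bit-for-bit on a given platform.
    Raw arrays (no :class:`EncodedMatrix`) are treated as all-numeric.
    """
    if isinstance(encoded, EncodedMatrix):
        X_all = np.asarray(encoded.values, dtype=float)
        sidecar = encoded.sidecar()
        numeric_mask = np.array(
            [c.role == "scaled-numeric" for c in encoded.column_map]
        )
    else:
        X_all = np.asarray(encoded, dtype=float)
        sidecar = None
        numeric_mask = np.ones(X_all.shape[1], dtype=bool)
    n, d = X_all.shape
    if config.batch_size > n:
        raise TrainingError(f"batch_size {config.batch_size} exceeds n={n}")

    rng = np.random.default_rng(config.seed)
    dz = config.latent_dim
    encoder, decoder = _build_networks(config, d, rng)
    # start the numeric noise scales at the marginal sd of each column
    init_sd = np.maximum(X_all[:, numeric_mask].std(axis=0), 2e-3)
    log_sigma = np.log(init_sd)
    opt = Adam(
        encoder.params() + decoder.params() + [log_sigma],
        lr=config.learning_rate,
    )

    # metric centroids track a fixed subsample of training rows
    cap = config.n_metric_centroids or min(n, 400)
    centroid_rows = rng.permutation(n)[: min(cap, n)]
    c_mu, c_sigma = _posterior_at(encoder, X_all[centroid_rows], dz)
    metric = _metric_from_moments(c_mu, c_sigma, config)

    def potential_factory(xb: Array):
        """U(z) = -log p(x|z) - log N(z; 0, I), with gradient."""

        def potential(z: Array) -> tuple[Array, Array]:
            lam = decoder.forward(z, cache=False)
            ll = recon_log_likelihood(xb, lam, numeric_mask, log_sigma)
            U = -ll + 0.5 * np.sum(z**2, axis=-1)
            dlam, _ = recon_log_likelihood_grad(xb, lam, numeric_mask, log_sigma)
            gz = decoder.input_grad(z, -dlam) + z
            return U, gz

        return potential

    log: list[float] = []
    n_batches = n // config.batch_size
    warmup = max(int(_WARMUP_FRACTION * config.epochs), 1)
    for epoch in range(config.epochs):
        beta = min(1.0, (epoch + 1) / warmup)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(n_batches):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            xb = X_all[idx]
            B = len(xb)

            enc_out = encoder.forward(xb)
            mu = enc_out[:, :dz]
            logvar_raw = enc_out[:, dz:]
            logvar = np.clip(logvar_raw, -_LOGVAR_CLIP, _LOGVAR_CLIP)
            in_range = (np.abs(logvar_raw) < _LOGVAR_CLIP).astype(float)
            sigma = np.exp(0.5 * logvar)
            eps = rng.standard_normal((B, dz))
            z0 = mu + sigma * eps

            if config.n_leapfrog_steps > 0:
                p0 = metric.sample_momentum(z0, rng)
                z_used, _ = leapfrog_integrate(
                    metric,
                    z0,
                    p0,
                    potential_factory(xb),
                    steps=config.n_leapfrog_steps,
                    step_size=config.leapfrog_step_size,
                    fixed_point_iters=5,
                    fixed_point_tol=1e-10,
                )
            else:
                z_used = z0

            lam = decoder.forward(z_used)
            recon_ll = recon_log_likelihood(xb, lam, numeric_mask, log_sigma)
            kl = gaussian_kl(mu, logvar)
            loss = float(np.mean(-recon_ll + beta * kl))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss

            # backward -----------------------------------------------------
            dll_lam, dll_ls = recon_log_likelihood_grad(
                xb, lam, numeric_mask, log_sigma
            )
            dz_grad = decoder.backward(-dll_lam / B)  # straight-through to z0
            dmu = dz_grad + beta * mu / B
            dlogvar = (
                0.5 * dz_grad * eps * sigma
                + 0.5 * beta * (np.exp(logvar) - 1.0) / B
            ) * in_range
            encoder.backward(np.concatenate([dmu, dlogvar], axis=1))
            opt.step(
                encoder.param_grads() + decoder.param_grads() + [-dll_ls / B]
            )

        log.append(epoch_loss / n_batches)

        # metric EMA toward current posterior moments of the centroid rows
        mu_c, sigma_c = _posterior_at(encoder, X_all[centroid_rows], dz)
        rho = config.centroid_ema
        c_mu = (1 - rho) * c_mu + rho * mu_c
        c_sigma = (1 - rho) * c_sigma + rho * sigma_c
        metric = _metric_from_moments(c_mu, c_sigma, config)

    # final metric snapped to the converged posterior moments
    mu_c, sigma_c = _posterior_at(encoder, X_all[centroid_rows], dz)
    metric = _metric_from_moments(mu_c, sigma_c, config)

    from .nn import LOGSIG_MAX, LOGSIG_MIN

    return RHVAEState(
        config=config,
        encoder=encoder,
        decoder=decoder,
        metric=metric,
        numeric_mask=numeric_mask,
        log_sigma=np.clip(log_sigma, LOGSIG_MIN, LOGSIG_MAX),
        training_log=log,
        sidecar=sidecar,
        trained=True,
    )
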