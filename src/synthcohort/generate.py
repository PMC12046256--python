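"""Artificial-cohort generation from a trained geometry-based VAE.

The default "metric-walk" sampler draws latent points from the learned
geometry: a random-walk step from a metric centroid under that centroid's
local metric, z ~ N(c_i, (M_i + lambda I)^{-1}) with the centroid chosen
uniformly.  Samples therefore concentrate exactly where the latent
manifold is supported — the region the encoder populated during training —
which is the mechanism that makes generation viable from a few hundred
training patients.  A "prior-gaussian" sampler (z ~ N(0, I)) is kept as an
ablation baseline.

Generation is chunked (1,000 latent points at a time) with counter-based
per-chunk seeding, so memory stays bounded and results are independent of
chunking for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import TabularProcessor
from .metric import RiemannianMetric
from .rhvae import RHVAEState
from .schema import CohortTable

Array = np.ndarray

CHUNK = 1000
METRIC_WALK = "metric-walk"
PRIOR_GAUSSIAN = "prior-gaussian"


@dataclass(frozen=True)
class GenerationRequest:
    n_samples: int
    seed: int = 0
    sampler: str = METRIC_WALK

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")
        if self.sampler not in (METRIC_WALK, PRIOR_GAUSSIAN):
            raise ValueError(f"unknown sampler {self.sampler!r}")


def _metric_walk_chunk(
    metric: RiemannianMetric, n: int, rng: np.random.Generator
) -> Array:
    """One vectorised batch of metric-walk samples (n independent draws).

    Each draw is one random-walk step from a uniformly chosen metric
    centroid under that centroid's local geometry: z = c_i + R_i^{-T} eps
    with R_i the Cholesky factor of M_i + lambda I, i.e. z ~ N(c_i,
    (M_i + lambda I)^{-1}).  The local covariance is the metric's own unit
    ball at the centroid, so samples spread exactly as far as the learned
    geometry says the manifold extends there — wide lobes where the
    encoder is uncertain, tight ones where it is confident — and the
    mixture over centroids reproduces the latent region the training data
    actually occupies.
    """
    dz = metric.dz
    idx = rng.integers(0, len(metric.centroids), size=n)
    M = metric._M[idx] + metric.regularization * np.eye(dz)
    R = np.linalg.cholesky(M)
    eps = rng.standard_normal((n, dz))
    step = np.linalg.solve(np.swapaxes(R, -1, -2), eps[..., None])[..., 0]
    return metric.centroids[idx] + step


def _latent_chunk(state: RHVAEState, request: GenerationRequest, idx: int) -> Array:
    """One full latent chunk (always CHUNK points, counter-seeded by idx)."""
    rng = np.random.default_rng(np.random.SeedSequence([request.seed, idx]))
    if request.sampler == PRIOR_GAUSSIAN:
        return rng.standard_normal((CHUNK, state.config.latent_dim))
    return _metric_walk_chunk(state.metric, CHUNK, rng)


def sample_latent(state: RHVAEState, request: GenerationRequest) -> Array:
    """Draw ``request.n_samples`` latent points; seed-deterministic and
    independent of chunk boundaries (full chunks are computed and the
    concatenation truncated, so sample i is the same for any n > i)."""
    if not state.trained:
        raise ValueError("model is not trained")
    dz = state.config.latent_dim
    if request.n_samples == 0:
        return np.empty((0, dz))
    n_chunks = -(-request.n_samples // CHUNK)
    out = [_latent_chunk(state, request, i) for i in range(n_chunks)]
    return np.concatenate(out, axis=0)[: request.n_samples]


def generate_cohort(state: RHVAEState, request: GenerationRequest) -> CohortTable:
    """Sample latents, draw records from the observation model, decode.

    Each artificial patient is a draw from the full generative model: a
    latent point from the requested sampler, then x ~ p(x|z) (Gaussian
    noise on numerics, Bernoulli/categorical draws on discrete columns),
    then the inverse transform back to a schema-valid record.  Observation
    noise uses the same counter-based per-chunk seeding as the latent
    sampler, so results are chunking-independent for a given seed.
    """
    if not state.trained:
        raise ValueError("model is not trained")
    if state.sidecar is None:
        raise ValueError("model has no decoding sidecar")
    processor = TabularProcessor.from_sidecar(state.sidecar)
    if request.n_samples == 0:
        import pandas as pd

        empty = pd.DataFrame(
            {n: pd.Series(dtype=object) for n in processor.schema.names}
        )
        return CohortTable(schema=processor.schema, data=empty)
    n_chunks = -(-request.n_samples // CHUNK)
    rows = []
    for idx in range(n_chunks):
        zc = _latent_chunk(state, request, idx)
        rng = np.random.default_rng(
            np.random.SeedSequence([request.seed, idx, 1])
        )
        rows.append(state.sample_observation(state.decode(zc), rng))
    X = np.concatenate(rows, axis=0)[: request.n_samples]
    return processor.inverse_transform(X)
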