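"""Learned Riemannian metric over latent space.

The inverse metric is a centroid-weighted sum of PSD lobes with a ridge:

    G^{-1}(z) = sum_i L_i L_i^T exp(-||z - c_i||^2 / T^2) + lambda I

where the c_i sit at (a subsample of) the training points' posterior means,
the lower-triangular factors L_i carry local scale information, T is a
temperature controlling lobe width and lambda > 0 a regularisation floor.
G^{-1}(z) is symmetric positive definite everywhere (the ridge guarantees
eigenvalues >= lambda) and decays to lambda I far from all centroids, so
sqrt(det G^{-1}(z)) is large exactly where the latent manifold is supported
— the quantity the geometry-aware sampler targets.

Hamiltonian integration evaluates several z-gradients at a fixed position
(inside implicit-step fixed-point loops), so the position-dependent pieces
are bundled in :class:`MetricContext`, computed once per position batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Array = np.ndarray


class MetricContext:
    """All position-dependent metric quantities for one batch of z.

    Precomputes the kernel weights, G^{-1}, G, the gradient of
    log det G^{-1}, and the third-order tensor S needed to evaluate
    ∇_z [1/2 p^T G^{-1} p] cheaply for many momenta at the same position.
    """

    def __init__(self, metric: "RiemannianMetric", z: Array):
        self.metric = metric
        z = np.atleast_2d(np.asarray(z, dtype=float))
        self.z = z
        B, dz = z.shape
        N = len(metric.centroids)
        diff = z[:, None, :] - metric.centroids[None]  # (B, N, dz)
        w = np.exp(-(diff**2).sum(-1) / metric.temperature**2)  # (B, N)
        M2 = metric._M2  # (N, dz*dz)
        self.G_inv = (w @ M2).reshape(B, dz, dz)
        self.G_inv[:, np.arange(dz), np.arange(dz)] += metric.regularization
        self.G = np.linalg.inv(self.G_inv)
        # tr(G_b M_n) for the log-det gradient
        t = self.G.reshape(B, dz * dz) @ M2.T  # (B, N)
        scale = -2.0 / metric.temperature**2
        self.grad_log_det_inverse = scale * np.einsum(
            "bn,bnk->bk", w * t, diff, optimize=True
        )
        self._w = w
        self._diff = diff
        self._S: Array | None = None  # built on first quad_grad call
        self._dz = dz

    def log_det_inverse(self) -> Array:
        _, logdet = np.linalg.slogdet(self.G_inv)
        return logdet

    def kinetic_grad(self, p: Array) -> Array:
        """∇_p H = G^{-1}(z) p."""
        return np.einsum("bij,bj->bi", self.G_inv, p, optimize=True)

    def quad_grad(self, p: Array) -> Array:
        """∇_z [1/2 p^T G^{-1}(z) p]."""
        if self._S is None:
            # S_bk(ij) = sum_n w_bn diff_bnk M_n(ij): one GEMM, then each
            # momentum evaluation is a cheap contraction
            wd = (self._w[:, :, None] * self._diff).transpose(0, 2, 1)
            self._S = wd @ self.metric._M2  # (B, dz, dz*dz)
        pp = (p[:, :, None] * p[:, None, :]).reshape(len(p), -1)  # (B, dz^2)
        return (-1.0 / self.metric.temperature**2) * np.einsum(
            "bkm,bm->bk", self._S, pp, optimize=True
        )


@dataclass
class RiemannianMetric:
    """Centroid-based latent metric: see module docstring for the form."""

    centroids: Array  # (N, dz)
    factors: Array  # (N, dz, dz) lower-triangular L_i
    temperature: float = 0.8
    regularization: float = 1e-3

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.ndim == 2:
            self.factors = self.factors[None]
        if self.temperature <= 0 or self.regularization <= 0:
            raise ValueError("temperature and regularization must be positive")
        # M_i = L_i L_i^T, precomputed once; _M2 is its (N, dz*dz) layout
        self._M = np.einsum("nij,nkj->nik", self.factors, self.factors)
        self._M2 = np.ascontiguousarray(self._M.reshape(len(self._M), -1))

    @property
    def dz(self) -> int:
        return self.centroids.shape[1]

    @classmethod
    def identity(cls, dz: int, regularization: float = 1.0) -> "RiemannianMetric":
        """Degenerate metric with no centroids: G^{-1}(z) = regularization * I."""
        return cls(
            centroids=np.zeros((1, dz)),
            factors=np.zeros((1, dz, dz)),
            temperature=1.0,
            regularization=regularization,
        )

    def context(self, z: Array) -> MetricContext:
        return MetricContext(self, z)

    def inverse(self, z: Array) -> Array:
        """G^{-1}(z) for a batch of latent points; shape (B, dz, dz)."""
        return self.context(z).G_inv

    def inverse_single(self, z: Array) -> Array:
        return self.inverse(z[None])[0]

    def log_det_inverse(self, z: Array) -> Array:
        """log det G^{-1}(z) per batch row (positive-definite by construction)."""
        return self.context(z).log_det_inverse()

    def grad_log_det_inverse(self, z: Array) -> Array:
        """∇_z log det G^{-1}(z), shape (B, dz)."""
        return self.context(z).grad_log_det_inverse

    def grad_quadratic(self, z: Array, p: Array) -> Array:
        """∇_z [ 1/2 p^T G^{-1}(z) p ], shape (B, dz)."""
        return self.context(z).quad_grad(np.atleast_2d(np.asarray(p, dtype=float)))

    def sample_momentum(self, z: Array, rng: np.random.Generator) -> Array:
        """Draw p ~ N(0, G(z)) so the kinetic energy 1/2 p^T G^{-1} p is χ²-scaled.

        With G^{-1} = R R^T (Cholesky), p = R^{-T} xi has covariance G.
        """
        z = np.atleast_2d(z)
        G_inv = self.inverse(z)
        R = np.linalg.cholesky(G_inv)
        xi = rng.standard_normal(z.shape)
        # solve R^T p = xi  per batch row
        return np.linalg.solve(np.swapaxes(R, -1, -2), xi[..., None])[..., 0]


def metric_inverse(metric: RiemannianMetric, z: Array) -> Array:
    """Functional alias: G^{-1}(z) for one latent point z (dz,) -> (dz, dz)."""
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        return metric.inverse_single(z)
    return metric.inverse(z)
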