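"""Minimal dense-network primitives: MLPs with hand-written backprop, Adam,
and the mixed reconstruction likelihood for encoded cohort matrices.

Kept deliberately small: the encoder/decoder are two-hidden-layer tanh MLPs
operating on a few hundred rows, so explicit NumPy forward/backward passes
are both fast and easy to verify against finite differences.

The reconstruction model treats the two kinds of encoded column
differently: scaled numeric columns get a heteroscedastic Gaussian with a
learned per-column standard deviation (clinical numerics carry idiosyncratic
measurement noise whose scale the model must estimate, not assume), while
binary and one-hot columns get Bernoulli cross-entropy on the decoder's
sigmoid outputs.
"""

from __future__ import annotations

import numpy as np

Array = np.ndarray

LOG2PI = float(np.log(2.0 * np.pi))
_EPS = 1e-6
# learned log-sigma is clamped: floor stops variance collapse onto single
# training points, ceiling stops runaway noise early in training
LOGSIG_MIN, LOGSIG_MAX = np.log(1e-3), np.log(1.0)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Array:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class MLP:
    """Fully connected net with tanh hidden layers and a linear output.

    ``forward`` caches activations; ``backward`` consumes the upstream
    gradient of the output and returns the gradient w.r.t. the input while
    accumulating parameter gradients in ``grads``.  ``input_grad`` gives
    d(output)/d(input) contractions without touching parameter gradients,
    which the Hamiltonian integrator uses for ∇_z log p(x|z).
    """

    def __init__(
        self, rng: np.random.Generator, sizes: list[int], out_activation: str = "linear"
    ):
        self.sizes = list(sizes)
        self.out_activation = out_activation
        self.W = [glorot(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        self.b = [np.zeros(b) for b in sizes[1:]]
        self.grads: dict[str, list[Array]] = {}
        self._cache: list[Array] = []

    # parameters as a flat list for the optimizer
    def params(self) -> list[Array]:
        return self.W + self.b

    def param_grads(self) -> list[Array]:
        return self.grads["W"] + self.grads["b"]

    def forward(self, x: Array, cache: bool = True) -> Array:
        acts = [x]
        h = x
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < n_layers - 1:
                h = np.tanh(h)
            elif self.out_activation == "sigmoid":
                h = 1.0 / (1.0 + np.exp(-h))
            elif self.out_activation == "tanh":
                h = np.tanh(h)
            acts.append(h)
        if cache:
            self._cache = acts
        return h

    def _act_grad(self, i: int, acts: list[Array]) -> Array:
        """Derivative of layer i's activation given its post-activation value."""
        out = acts[i + 1]
        if i < len(self.W) - 1 or self.out_activation == "tanh":
            return 1.0 - out**2
        if self.out_activation == "sigmoid":
            return out * (1.0 - out)
        return np.ones_like(out)

    def backward(self, d_out: Array) -> Array:
        """Backprop ``d_out`` (= dL/d output) through the cached forward pass."""
        acts = self._cache
        gW: list[Array] = [np.empty(0)] * len(self.W)
        gb: list[Array] = [np.empty(0)] * len(self.b)
        delta = d_out * self._act_grad(len(self.W) - 1, acts)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * self._act_grad(i - 1, acts)
            else:
                delta = delta @ self.W[0].T
        self.grads = {"W": gW, "b": gb}
        return delta

    def input_grad(self, x: Array, d_out: Array) -> Array:
        """d(d_out · output)/dx without caching or parameter gradients."""
        acts = [x]
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.tanh(h)
            elif self.out_activation == "sigmoid":
                h = 1.0 / (1.0 + np.exp(-h))
            elif self.out_activation == "tanh":
                h = np.tanh(h)
            acts.append(h)
        delta = d_out * self._act_grad(len(self.W) - 1, acts)
        for i in range(len(self.W) - 1, 0, -1):
            delta = (delta @ self.W[i].T) * self._act_grad(i - 1, acts)
        return delta @ self.W[0].T


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[Array], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[Array]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# --- mixed reconstruction likelihood --------------------------------------

def recon_log_likelihood(
    x: Array, lam: Array, numeric_mask: Array, log_sigma: Array
) -> Array:
    """Per-row log p(x | lam): Gaussian on numeric columns, Bernoulli CE
    on discrete columns.

    ``numeric_mask`` is a boolean (d,) vector; ``log_sigma`` holds the
    learned log standard deviations of the numeric columns, in mask order.
    """
    ls = np.clip(log_sigma, LOGSIG_MIN, LOGSIG_MAX)
    xn, ln = x[:, numeric_mask], lam[:, numeric_mask]
    zscore = (xn - ln) / np.exp(ls)
    ll_num = -0.5 * (zscore**2) - ls - 0.5 * LOG2PI
    xd, ld = x[:, ~numeric_mask], np.clip(lam[:, ~numeric_mask], _EPS, 1 - _EPS)
    ll_disc = xd * np.log(ld) + (1.0 - xd) * np.log1p(-ld)
    return ll_num.sum(axis=-1) + ll_disc.sum(axis=-1)


def recon_log_likelihood_grad(
    x: Array, lam: Array, numeric_mask: Array, log_sigma: Array
) -> tuple[Array, Array]:
    """(d ll / d lam elementwise, d ll / d log_sigma per numeric column)."""
    ls = np.clip(log_sigma, LOGSIG_MIN, LOGSIG_MAX)
    g = np.zeros_like(lam)
    xn, ln = x[:, numeric_mask], lam[:, numeric_mask]
    inv_var = np.exp(-2.0 * ls)
    g[:, numeric_mask] = (xn - ln) * inv_var
    xd = x[:, ~numeric_mask]
    ld = np.clip(lam[:, ~numeric_mask], _EPS, 1 - _EPS)
    g[:, ~numeric_mask] = xd / ld - (1.0 - xd) / (1.0 - ld)
    # d/d log_sigma of sum_rows ll_num; zero where the clamp is active
    zscore2 = ((xn - ln) ** 2) * inv_var
    g_ls = (zscore2 - 1.0).sum(axis=0)
    active = (log_sigma > LOGSIG_MIN) & (log_sigma < LOGSIG_MAX)
    return g, np.where(active, g_ls, 0.0)


def gaussian_kl(mu: Array, logvar: Array) -> Array:
    """Per-row KL( N(mu, diag e^logvar) || N(0, I) )."""
    return 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=-1)
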