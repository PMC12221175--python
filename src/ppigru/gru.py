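"""A minimal GRU engine: NumPy matrix products plus fused gate kernels.

The reducers in this package consume a *flat* feature vector as a univariate
sequence (one scalar per timestep), so the GRU cell has input size 1 and the
input-to-hidden term at step t is just ``x_t * W``.  The recurrent cost is
one (batch x h) @ (h x 3h) matrix product per timestep in each direction,
forward and backward through time; the surrounding pointwise gate algebra is
fused into single-pass Numba kernels when Numba is importable, with an
equivalent pure-NumPy path otherwise.

Gate equations (reset gate applied inside the candidate's recurrent term):

    z_t = sigmoid(x_t Wz + bz + h_{t-1} Uz + cz)
    r_t = sigmoid(x_t Wr + br + h_{t-1} Ur + cr)
    n_t = tanh(x_t Wn + bn + r_t * (h_{t-1} Un + cn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

All parameters are float32, initialized uniformly in [-1/sqrt(h), 1/sqrt(h)]
from a seeded generator, so runs are bit-reproducible on one platform.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32

try:
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


def init_cell(hidden: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Parameters of one univariate-input GRU cell of width ``hidden``."""
    k = 1.0 / np.sqrt(hidden)

    def u(*shape):
        return rng.uniform(-k, k, size=shape).astype(F32)

    return {
        "W": u(3 * hidden),      # input weights for z, r, n (input size 1)
        "b": u(3 * hidden),      # input-side bias
        "U": u(hidden, 3 * hidden),
        "c": u(3 * hidden),      # hidden-side bias
    }


def sigmoid(x: np.ndarray) -> np.ndarray:
    # clip keeps exp in range; float32 saturates well before +-80 anyway
    return 1.0 / (1.0 + np.exp(np.clip(-x, -80.0, 80.0)))


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _step_fwd(G, xt, W, b, h_prev, z_t, r_t, n_t, hn_t, h_out):  # pragma: no cover
        B, h = h_prev.shape
        for i in range(B):
            x = xt[i]
            for j in range(h):
                az = G[i, j] + x * W[j] + b[j]
                ar = G[i, h + j] + x * W[h + j] + b[h + j]
                z = 1.0 / (1.0 + np.exp(-az))
                r = 1.0 / (1.0 + np.exp(-ar))
                hn = G[i, 2 * h + j]
                n = np.tanh(x * W[2 * h + j] + b[2 * h + j] + r * hn)
                z_t[i, j] = z
                r_t[i, j] = r
                n_t[i, j] = n
                hn_t[i, j] = hn
                h_out[i, j] = (1.0 - z) * n + z * h_prev[i, j]

    @numba.njit(cache=True)
    def _step_bwd(dh, xt, h_prev, z_t, r_t, n_t, hn_t,
                  dG, dh_part, gW, gb, gc):  # pragma: no cover
        B, h = h_prev.shape
        for i in range(B):
            x = xt[i]
            for j in range(h):
                z = z_t[i, j]
                r = r_t[i, j]
                n = n_t[i, j]
                hn = hn_t[i, j]
                d = dh[i, j]
                dan = d * (1.0 - z) * (1.0 - n * n)
                daz = d * (h_prev[i, j] - n) * z * (1.0 - z)
                dhn = dan * r
                dar = dan * hn * r * (1.0 - r)
                dG[i, j] = daz
                dG[i, h + j] = dar
                dG[i, 2 * h + j] = dhn
                dh_part[i, j] = d * z
                gW[j] += x * daz
                gW[h + j] += x * dar
                gW[2 * h + j] += x * dan
                gb[j] += daz
                gb[h + j] += dar
                gb[2 * h + j] += dan
                gc[j] += daz
                gc[h + j] += dar
                gc[2 * h + j] += dhn


def make_cache(T: int, B: int, h: int) -> dict[str, np.ndarray]:
    """Reusable BPTT scratch buffers for a (T, B, h) problem."""
    return {
        k: np.empty((T, B, h), dtype=F32)
        for k in ("h_prev", "z", "r", "n", "Hn")
    }


def cell_forward(
    params: dict[str, np.ndarray], X: np.ndarray, keep_cache: bool = False,
    cache: dict | None = None,
):
    """Run the cell over ``X`` (batch x T, one scalar per step).

    Returns the final hidden state (batch x h) and, when ``keep_cache``,
    the per-timestep tensors needed by :func:`cell_backward`.  Passing a
    preallocated ``cache`` (see :func:`make_cache`) avoids reallocating the
    large scratch tensors on every mini-batch.
    """
    B, T = X.shape
    h = params["U"].shape[0]
    W, b, U, c = params["W"], params["b"], params["U"], params["c"]
    ht = np.zeros((B, h), dtype=F32)
    if not keep_cache:
        cache = None
    elif cache is None:
        cache = make_cache(T, B, h)
    if cache is not None:
        cache["X"] = X
    use_numba = _HAVE_NUMBA and params["W"].dtype == F32
    if use_numba:
        XT = np.ascontiguousarray(X.T)
        scratch = (
            cache
            if keep_cache
            else {
                k: np.empty((1, B, h), dtype=F32)
                for k in ("h_prev", "z", "r", "n", "Hn")
            }
        )
        for t in range(T):
            s = t if keep_cache else 0
            G = ht @ U + c
            h_out = np.empty((B, h), dtype=F32)
            _step_fwd(G, XT[t], W, b, ht, scratch["z"][s], scratch["r"][s],
                      scratch["n"][s], scratch["Hn"][s], h_out)
            if keep_cache:
                cache["h_prev"][t] = ht
            ht = h_out
        return ht, cache
    for t in range(T):
        G = ht @ U + c                       # recurrent pre-activations (B, 3h)
        it = X[:, t, None] * W               # input side: scalar x outer W
        it = it + b
        zr = sigmoid(G[:, : 2 * h] + it[:, : 2 * h])
        z = zr[:, :h]
        r = zr[:, h:]
        Hn = G[:, 2 * h :]                   # candidate's recurrent term
        n = np.tanh(it[:, 2 * h :] + r * Hn)
        if keep_cache:
            cache["h_prev"][t] = ht
            cache["z"][t] = z
            cache["r"][t] = r
            cache["n"][t] = n
            cache["Hn"][t] = Hn
        ht = ht + (1.0 - z) * (n - ht)
    return ht, cache


def cell_backward(
    params: dict[str, np.ndarray], cache, d_hT: np.ndarray
) -> dict[str, np.ndarray]:
    """Backpropagate through time from a gradient on the final hidden state."""
    U = params["U"]
    h = U.shape[0]
    X = cache["X"]
    B, T = X.shape
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    gW, gb, gU, gc = grads["W"], grads["b"], grads["U"], grads["c"]
    dh = np.ascontiguousarray(d_hT, dtype=U.dtype)
    dG = np.empty((B, 3 * h), dtype=U.dtype)
    use_numba = _HAVE_NUMBA and U.dtype == F32
    if use_numba:
        XT = np.ascontiguousarray(X.T)
        dh_part = np.empty((B, h), dtype=F32)
        for t in range(T - 1, -1, -1):
            h_prev = cache["h_prev"][t]
            _step_bwd(dh, XT[t], h_prev, cache["z"][t], cache["r"][t],
                      cache["n"][t], cache["Hn"][t], dG, dh_part, gW, gb, gc)
            gU += h_prev.T @ dG
            dh = dh_part + dG @ U.T
        return grads
    da_z = dG[:, :h]
    da_r = dG[:, h : 2 * h]
    dHn_v = dG[:, 2 * h :]
    for t in range(T - 1, -1, -1):
        h_prev = cache["h_prev"][t]
        z, r, n, Hn = cache["z"][t], cache["r"][t], cache["n"][t], cache["Hn"][t]
        da_n = dh * (1.0 - z)
        da_n *= 1.0 - n * n
        np.multiply(dh * (h_prev - n), z * (1.0 - z), out=da_z)
        np.multiply(da_n, r, out=dHn_v)
        np.multiply(da_n * Hn, r * (1.0 - r), out=da_r)
        xt = X[:, t]
        gW[:h] += xt @ da_z
        gW[h : 2 * h] += xt @ da_r
        gW[2 * h :] += xt @ da_n
        s_z = da_z.sum(axis=0)
        s_r = da_r.sum(axis=0)
        s_n = da_n.sum(axis=0)
        gb[:h] += s_z
        gb[h : 2 * h] += s_r
        gb[2 * h :] += s_n
        gc[:h] += s_z
        gc[h : 2 * h] += s_r
        gc[2 * h :] += dHn_v.sum(axis=0)
        gU += h_prev.T @ dG
        dh = dh * z + dG @ U.T
    return grads


def clip_global_norm(grads: list[np.ndarray], max_norm: float) -> float:
    """Scale gradients in place so their joint L2 norm is at most max_norm."""
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
    if total > max_norm and total > 0:
        scale = F32(max_norm / total)
        for g in grads:
            g *= scale
    return total


class Adam:
    """Adam optimizer over a flat list of float32 parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= F32(self.lr) * (m / b1t) / (np.sqrt(v / b2t) + F32(self.eps))


def bce_loss_and_grad(p: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy and its gradient with respect to p."""
    eps = 1e-7
    pc = np.clip(p, eps, 1.0 - eps)
    loss = float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
    grad = ((pc - y) / (pc * (1.0 - pc))) / p.shape[0]
    return loss, grad.astype(F32)
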