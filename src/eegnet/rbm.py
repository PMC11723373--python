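"""Contractive spike-and-slab convolutional RBM (CssCRBM).

The model couples a real-valued visible layer ``v`` (L channels) to K feature
maps of binary *spike* units ``h`` and real *slab* units ``s`` through shared
convolution kernels ``w``. Its energy is

    E(v, s, h) = - sum_{l,k,ij} (v^l * w^{l,k})_ij h_ij^k s_ij^k
                 - sum_k b^k sum_ij h_ij^k
                 + sum_{l,mn} (v_mn^l - c^l)^2 / (2 sigma^2)
                 + (1/2) sum_{k,ij} a^k (s_ij^k)^2

(``*`` is valid-mode cross-correlation). Dual-variable probabilistic
max-pooling constrains each pooling block to at most one active spike and
pools both the spike indicator and the (max-mean) slab value; the pooled
output is their elementwise product.

Training is contrastive divergence (CD-k) with a contractive penalty: the
squared Frobenius norm of the Jacobian of the spike activation probabilities
with respect to the visible input, which shrinks the representation's
sensitivity to input perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils import check_random_state

from . import _autodiff as ad

__all__ = [
    "CssCRBMParams",
    "LayerState",
    "TrainConfig",
    "init_params",
    "energy",
    "response",
    "spike_activation",
    "spike_given_v",
    "pooled_spike_given_v",
    "slab_given_vh",
    "pooled_slab_given_v",
    "visible_given_sh",
    "sample_pooled_state",
    "gibbs_step",
    "cd_gradient",
    "contractive_penalty",
    "contractive_grad",
    "cd_update",
    "CssCRBM",
]


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------

@dataclass
class CssCRBMParams:
    """All trainable quantities of one CssCRBM layer.

    w : [K, L, kh, kw] convolution kernels
    b : [K] spike biases
    c : [L] visible biases
    a : [K] slab precision penalties (one learnable value per feature map,
        broadcast over positions), strictly positive
    sigma : visible noise scale
    pool : pooling block side length
    padding : symmetric zero padding applied before correlation
    """

    w: np.ndarray
    b: np.ndarray
    c: np.ndarray
    a: np.ndarray
    sigma: float = 1.0
    pool: int = 1
    padding: int = 0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64).reshape(-1)
        self.c = np.asarray(self.c, dtype=np.float64).reshape(-1)
        self.a = np.asarray(self.a, dtype=np.float64)
        if np.any(self.a <= 0):
            raise ValueError("slab penalty a must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.pool < 1:
            raise ValueError("pool must be >= 1")

    @property
    def n_kernels(self):
        return self.w.shape[0]

    @property
    def n_channels(self):
        return self.w.shape[1]

    @property
    def kernel_size(self):
        return self.w.shape[2]

    def a_col(self):
        """Slab penalty broadcastable against [N, K, Hh, Ww] maps."""
        if self.a.ndim == 1:
            return self.a[None, :, None, None]
        return self.a[None]


@dataclass
class LayerState:
    """One joint configuration (or sample) of a CssCRBM layer."""

    v: np.ndarray
    h: np.ndarray
    s: np.ndarray
    p_h: np.ndarray | None = None
    p_s: np.ndarray | None = None

    @property
    def hybrid(self):
        return self.h * self.s

    @property
    def pooled(self):
        if self.p_h is None or self.p_s is None:
            raise ValueError("state has no pooled maps")
        return self.p_h * self.p_s


@dataclass
class TrainConfig:
    """CD training hyper-parameters (defaults follow the reference setup:
    learning rate and contractive coefficient 0.01/0.1, CD step 5, batch 20)."""

    eta: float = 0.01
    lam: float = 0.1
    cd_steps: int = 5
    batchsize: int = 20
    epochs: int = 1
    seed: int = 0
    clip_norm: float | None = 5.0

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")


def init_params(
    n_kernels,
    n_channels,
    kernel_size,
    pool=1,
    padding=0,
    sigma=1.0,
    rng=None,
    w_scale=0.01,
):
    """Random small-kernel initialisation: w ~ N(0, w_scale^2), sparse spike
    bias b = -1, c = 0, a = 1."""
    rng = np.random.default_rng(rng)
    w = rng.normal(0.0, w_scale, size=(n_kernels, n_channels, kernel_size, kernel_size))
    return CssCRBMParams(
        w=w,
        b=np.full(n_kernels, -1.0),
        c=np.zeros(n_channels),
        a=np.ones(n_kernels),
        sigma=sigma,
        pool=pool,
        padding=padding,
    )


# ---------------------------------------------------------------------------
# shape helpers
# ---------------------------------------------------------------------------

def _batched(x):
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        return x[None], True
    if x.ndim == 4:
        return x, False
    raise ValueError(f"expected [C,H,W] or [N,C,H,W], got shape {x.shape}")


def _unbatch(x, squeeze):
    return x[0] if squeeze else x


def _check_v(v, params):
    if v.shape[1] != params.n_channels:
        raise ValueError(
            f"visible tensor has {v.shape[1]} channels, kernels expect "
            f"{params.n_channels}"
        )
    k = params.kernel_size
    if v.shape[2] + 2 * params.padding < k or v.shape[3] + 2 * params.padding < k:
        raise ValueError("kernel larger than (padded) visible field")


# ---------------------------------------------------------------------------
# responses and conditionals
# ---------------------------------------------------------------------------

def response(v, params):
    """Channel-summed bottom-up filter response z = sum_l v^l * w^{l,k}."""
    v, squeeze = _batched(v)
    _check_v(v, params)
    return _unbatch(ad.conv2d(v, params.w, padding=params.padding), squeeze)


def spike_activation(v, params):
    """Logistic / softmax argument I_ij^k = z_ij^2 / (2 a^k) + b^k."""
    v, squeeze = _batched(v)
    _check_v(v, params)
    z = ad.conv2d(v, params.w, padding=params.padding)
    return _unbatch(z ** 2 / (2.0 * params.a_col()) + params.b[None, :, None, None], squeeze)


def energy(state, params):
    """Evaluate E(v, s, h); returns one scalar per batch element."""
    v, squeeze = _batched(state.v)
    h, _ = _batched(state.h)
    s, _ = _batched(state.s)
    _check_v(v, params)
    z = ad.conv2d(v, params.w, padding=params.padding)
    if z.shape != h.shape or h.shape != s.shape:
        raise ValueError(
            f"shape mismatch: response {z.shape}, h {h.shape}, s {s.shape}"
        )
    cross = -(z * h * s).sum(axis=(1, 2, 3))
    spike = -(params.b[None, :, None, None] * h).sum(axis=(1, 2, 3))
    vis = ((v - params.c[None, :, None, None]) ** 2).sum(axis=(1, 2, 3)) / (
        2.0 * params.sigma**2
    )
    slab = 0.5 * (params.a_col() * s**2).sum(axis=(1, 2, 3))
    e = cross + spike + vis + slab
    return float(e[0]) if squeeze else e


def spike_given_v(v, params):
    """Unpooled spike posterior p(h_ij^k = 1 | v) = logistic(I_ij^k)."""
    act = spike_activation(v, params)
    return expit(act)


def _block_pad(x, pool, fill):
    """Pad trailing rows/cols so both spatial dims are multiples of pool."""
    n, k, h, w = x.shape
    hb = -(-h // pool)
    wb = -(-w // pool)
    out = np.full((n, k, hb * pool, wb * pool), fill, dtype=x.dtype)
    out[:, :, :h, :w] = x
    return out


def _block_flat(x, pool):
    """[N,K,H,W] -> [N,K,Hb,Wb,pool*pool] (ceil blocks, padded)."""
    n, k, h, w = x.shape
    hb, wb = h // pool, w // pool
    return (
        x.reshape(n, k, hb, pool, wb, pool)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, k, hb, wb, pool * pool)
    )


def _block_unflat(x, pool, h, w):
    n, k, hb, wb, _ = x.shape
    full = (
        x.reshape(n, k, hb, wb, pool, pool)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, k, hb * pool, wb * pool)
    )
    return full[:, :, :h, :w]


def pooled_spike_given_v(v, params):
    """Spike posterior under the at-most-one-per-block constraint.

    Every hidden unit belongs to the block floor(i/pool), floor(j/pool);
    trailing units form smaller blocks so the constraint covers the whole
    detection grid. Returns ``(p_unit, p_off)`` where ``p_unit[n,k,i,j]`` is
    the probability that unit (i,j) is the single active spike of its block
    and ``p_off[n,k,a,b]`` the probability that block (a,b) is entirely off.
    Within each block the unit probabilities and the off-state sum to one.
    """
    v, squeeze = _batched(v)
    act = spike_activation(v, params)
    pool = params.pool
    if pool == 1:
        q = expit(act)
        return _unbatch(q, squeeze), _unbatch(1.0 - q, squeeze)
    n, k, hh, ww = act.shape
    padded = _block_pad(act, pool, -np.inf)
    flat = _block_flat(padded, pool)  # N,K,Hb,Wb,pp
    m = np.maximum(flat.max(axis=-1, keepdims=True), 0.0)
    e = np.exp(flat - m)
    e[~np.isfinite(flat)] = 0.0
    e_off = np.exp(-m[..., 0])
    denom = e.sum(axis=-1) + e_off
    p_flat = e / denom[..., None]
    p_off = e_off / denom
    p_unit = _block_unflat(p_flat, pool, hh, ww)
    return _unbatch(p_unit, squeeze), _unbatch(p_off, squeeze)


def slab_given_vh(v, h, params):
    """Gaussian slab conditional: mean z h / a, variance 1/a."""
    v, squeeze = _batched(v)
    h, _ = _batched(h)
    z = ad.conv2d(v, params.w, padding=params.padding)
    a = params.a_col()
    mean = z * h / a
    var = np.broadcast_to(1.0 / a, mean.shape)
    return _unbatch(mean, squeeze), _unbatch(var.copy(), squeeze)


def pooled_slab_given_v(v, h, params):
    """Pooled slab conditional: block mean = max of unit means, variance 1/a."""
    mean, var = slab_given_vh(v, h, params)
    m, squeeze = _batched(mean)
    pool = params.pool
    if pool > 1:
        padded = _block_pad(m, pool, -np.inf)
        m = _block_flat(padded, pool).max(axis=-1)
    a = params.a_col()
    bvar = np.broadcast_to(1.0 / a, m.shape).copy()
    return _unbatch(m, squeeze), _unbatch(bvar, squeeze)


def visible_given_sh(s, h, params):
    """Gaussian visible conditional: mean sigma^2 * conv_T(h s) + c, var sigma^2."""
    h, squeeze = _batched(h)
    s, _ = _batched(s)
    if h.shape != s.shape:
        raise ValueError(f"h shape {h.shape} != s shape {s.shape}")
    top = ad.conv_transpose2d(h * s, params.w, padding=params.padding)
    mean = params.sigma**2 * top + params.c[None, :, None, None]
    var = np.full_like(mean, params.sigma**2)
    return _unbatch(mean, squeeze), _unbatch(var, squeeze)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_h(v, params, rng):
    """Draw spikes from the per-block categoricals (position or off)."""
    vb, _ = _batched(v)
    act = spike_activation(vb, params)
    pool = params.pool
    if pool == 1:
        q = expit(act)
        return (rng.random(q.shape) < q).astype(np.float64)
    n, k, hh, ww = act.shape
    padded = _block_pad(act, pool, -np.inf)
    flat = _block_flat(padded, pool)
    m = np.maximum(flat.max(axis=-1, keepdims=True), 0.0)
    e = np.exp(flat - m)
    e[~np.isfinite(flat)] = 0.0
    e_off = np.exp(-m[..., 0])
    denom = e.sum(axis=-1) + e_off
    p = e / denom[..., None]  # per-position probabilities; off = remainder
    cdf = np.cumsum(p, axis=-1)
    u = rng.random(cdf.shape[:-1])[..., None]
    pick = (u < cdf).astype(np.float64)
    onehot = np.diff(pick, axis=-1, prepend=0.0)
    # if u lands beyond the last cumsum value the block is off -> all zeros
    h = _block_unflat(onehot, pool, hh, ww)
    return h


def sample_pooled_state(v, params, rng):
    """One joint draw (h, s, pooled maps) from the conditionals given v.

    Returns a :class:`LayerState` whose ``p_h`` is the block spike indicator,
    ``p_s`` a draw from the pooled slab conditional, and whose ``pooled``
    property is their elementwise product. Pooled maps keep only the full
    floor(H/pool) blocks (matching the deterministic shape chain).
    """
    rng = np.random.default_rng(rng)
    vb, squeeze = _batched(v)
    h = _sample_h(vb, params, rng)
    mean, var = slab_given_vh(vb, h, params)
    s = rng.normal(mean, np.sqrt(var))
    pool = params.pool
    n, k, hh, ww = h.shape
    hb, wb = hh // pool, ww // pool
    if pool == 1:
        p_h, p_s = h.copy(), s.copy()
    else:
        p_h = _block_flat(_block_pad(h, pool, 0.0), pool).max(axis=-1)[
            :, :, :hb, :wb
        ]
        pmean, pvar = pooled_slab_given_v(vb, h, params)
        p_s = rng.normal(pmean, np.sqrt(pvar))[:, :, :hb, :wb]
    if squeeze:
        return LayerState(v=vb[0], h=h[0], s=s[0], p_h=p_h[0], p_s=p_s[0])
    return LayerState(v=vb, h=h, s=s, p_h=p_h, p_s=p_s)


def gibbs_step(v, params, rng):
    """One alternating sweep v -> (h, s) -> v'."""
    rng = np.random.default_rng(rng)
    vb, squeeze = _batched(v)
    h = _sample_h(vb, params, rng)
    mean, var = slab_given_vh(vb, h, params)
    s = rng.normal(mean, np.sqrt(var))
    vmean, vvar = visible_given_sh(s, h, params)
    vnew = rng.normal(vmean, np.sqrt(vvar))
    return _unbatch(vnew, squeeze)


# ---------------------------------------------------------------------------
# contrastive divergence
# ---------------------------------------------------------------------------

def _expected_stats(v, params):
    """Expected sufficient statistics of (h, s) given v, Rao-Blackwellised.

    Under the pooled posterior: E[h] = q (block categorical), the slab mean
    given h=1 is z/a, so E[h s] = q z / a and E[s^2] = 1/a + q z^2 / a^2.
    Statistics are averaged over the batch.
    """
    n = v.shape[0]
    z = ad.conv2d(v, params.w, padding=params.padding)
    a = params.a_col()
    q, _ = pooled_spike_given_v(v, params)
    ehs = q * z / a
    es2 = 1.0 / a + q * z**2 / a**2
    kh = params.kernel_size
    vp = v if params.padding == 0 else np.pad(
        v, [(0, 0), (0, 0), (params.padding,) * 2, (params.padding,) * 2]
    )
    win = sliding_window_view(vp, (kh, kh), axis=(-2, -1))
    gw = np.einsum("nlhwij,nkhw->klij", win, ehs, optimize=True) / n
    gb = q.sum(axis=(2, 3)).mean(axis=0)
    gc = ((v - params.c[None, :, None, None]) / params.sigma**2).sum(
        axis=(2, 3)
    ).mean(axis=0)
    ga = -0.5 * es2.sum(axis=(2, 3)).mean(axis=0)
    return {"w": gw, "b": gb, "c": gc, "a": ga}


def cd_gradient(batch, params, cd_steps, rng, return_chain=False):
    """CD-k estimate of the *negative* log-likelihood gradient.

    Runs ``cd_steps`` alternating Gibbs sweeps from the data batch; the
    positive phase uses expected sufficient statistics given the data, the
    negative phase expected statistics given the chain-end visible sample.
    Returns a dict over parameter names (gradient of NLL, i.e. positive-phase
    minus negative-phase statistics, negated).
    """
    rng = np.random.default_rng(rng)
    v0, _ = _batched(batch)
    _check_v(v0, params)
    pos = _expected_stats(v0, params)
    v = v0
    for _ in range(cd_steps):
        v = gibbs_step(v, params, rng)
    neg = _expected_stats(v, params)
    grad = {key: neg[key] - pos[key] for key in pos}
    if return_chain:
        return grad, v
    return grad


def contractive_penalty(v, params, with_grad=True):
    """Contractive regulariser and its gradient with respect to w.

    Penalty = mean over cases of ||d q / d v||_F^2, where q are the unpooled
    spike probabilities (logistic of the squared-response activation). The
    Jacobian has closed form: for each hidden unit the derivative along every
    visible weight-path is q(1-q) (z/a) w, so

        ||J||_F^2 = sum_k ||w^k||_F^2  sum_ij [ q (1-q) z / a ]_ij^2 .

    The gradient flows through q and z as well as the explicit ||w||^2 factor
    (computed by the package's gradient engine).
    """
    vb, _ = _batched(v)
    _check_v(vb, params)
    n = vb.shape[0]
    a = params.a_col()
    b = params.b[None, :, None, None]

    if not with_grad:
        z = ad.conv2d(vb, params.w, padding=params.padding)
        q = expit(z**2 / (2.0 * a) + b)
        g = (q * (1.0 - q) * z / a) ** 2
        wsq = (params.w**2).sum(axis=(1, 2, 3))
        return float((wsq[None, :] * g.sum(axis=(2, 3))).sum() / n)

    wt = ad.Tensor(params.w, requires_grad=True)
    z = ad.conv2d(ad.Tensor(vb), wt, padding=params.padding)
    q = ad.sigmoid(z * z * (1.0 / (2.0 * a)) + b)
    gmap = (q * (1.0 - q) * z * (1.0 / a)) ** 2
    wsq = (wt * wt).sum(axis=(1, 2, 3))
    per_map = gmap.sum(axis=(2, 3))  # N, K
    penalty = (wsq.reshape(1, -1) * per_map).sum() * (1.0 / n)
    penalty.backward()
    return float(penalty.data), wt.grad


def contractive_grad(v, params):
    """Gradient structure of the contractive penalty (w only; other
    parameters are not regularised)."""
    value, gw = contractive_penalty(v, params, with_grad=True)
    return {
        "w": gw,
        "b": np.zeros_like(params.b),
        "c": np.zeros_like(params.c),
        "a": np.zeros_like(params.a),
        "value": value,
    }


def cd_update(batch, params, config, rng):
    """One CD parameter update: theta <- theta - eta (grad_CD + lam grad_contract).

    The slab penalty ``a`` is updated in log-space to preserve positivity;
    ``sigma`` is fixed. Raises on non-finite parameters after the step.
    """
    rng = np.random.default_rng(rng)
    if config.eta == 0.0:
        return replace(params)
    vb, _ = _batched(batch)
    if vb.shape[0] == 0:
        raise ValueError("empty batch")
    grad = cd_gradient(vb, params, config.cd_steps, rng)
    if config.lam > 0:
        grad["w"] = grad["w"] + config.lam * contractive_grad(vb, params)["w"]
    clip = getattr(config, "clip_norm", None)
    if clip is not None:
        gnorm = np.sqrt(sum(float((g**2).sum()) for g in grad.values()))
        if gnorm > clip:
            grad = {k: g * (clip / gnorm) for k, g in grad.items()}
    log_a = np.log(params.a) - config.eta * (params.a * grad["a"])
    new = CssCRBMParams(
        w=params.w - config.eta * grad["w"],
        b=params.b - config.eta * grad["b"],
        c=params.c - config.eta * grad["c"],
        a=np.exp(log_a),
        sigma=params.sigma,
        pool=params.pool,
        padding=params.padding,
    )
    for name in ("w", "b", "c", "a"):
        if not np.all(np.isfinite(getattr(new, name))):
            raise FloatingPointError(f"parameter {name} diverged during CD update")
    return new


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class CssCRBM(TransformerMixin, BaseEstimator):
    """Single contractive spike-and-slab convolutional RBM layer.

    ``fit`` pretrains the layer with CD-k on image batches [N, C, H, W];
    ``transform`` returns the pooled hybrid (spike * slab) feature maps of
    the deterministic mean-field forward pass.

    Parameters mirror the reference training setup: learning rate 0.01,
    contractive coefficient per layer, CD step 5, batch size 20.
    """

    def __init__(
        self,
        n_kernels=8,
        kernel_size=3,
        pool=2,
        padding=0,
        sigma=1.0,
        eta=0.01,
        lam=0.1,
        cd_steps=5,
        batch_size=20,
        n_epochs=1,
        clip_norm=5.0,
        random_state=None,
    ):
        self.n_kernels = n_kernels
        self.kernel_size = kernel_size
        self.pool = pool
        self.padding = padding
        self.sigma = sigma
        self.eta = eta
        self.lam = lam
        self.cd_steps = cd_steps
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.clip_norm = clip_norm
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4:
            raise ValueError("X must be [n_samples, n_channels, H, W]")
        rs = check_random_state(self.random_state)
        rng = np.random.default_rng(rs.randint(2**31))
        params = init_params(
            self.n_kernels,
            X.shape[1],
            self.kernel_size,
            pool=self.pool,
            padding=self.padding,
            sigma=self.sigma,
            rng=rng,
        )
        cfg = TrainConfig(
            eta=self.eta,
            lam=self.lam,
            cd_steps=self.cd_steps,
            batchsize=self.batch_size,
            epochs=max(self.n_epochs, 0),
            clip_norm=self.clip_norm,
        )
        n = X.shape[0]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n - cfg.batchsize + 1, cfg.batchsize):
                batch = X[order[start : start + cfg.batchsize]]
                params = cd_update(batch, params, cfg, rng)
        self.params_ = params
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        from .stack import forward_layer  # local import avoids a cycle

        X = np.asarray(X, dtype=np.float64)
        state = forward_layer(X, self.params_, mode="eval")
        return state["pooled"]
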