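"""Stacking CssCRBMs into a convolutional deep belief network (CssCDBN).

Layers are pretrained greedily bottom-up with CD; each layer consumes the
pooled hybrid (spike * slab) feature maps of the layer below. After
pretraining the stack is treated as a feed-forward network: spike maps come
from a rectified squared-response activation

    h = relu( z^2 / (2a) + b ),        z = channel-summed filter response,

slab maps from s = z h / a (plus an optional seeded noise term of scale 1/a
in training mode), hybrid maps are h * s, and pooling is the deterministic
block max of the hybrid map (floor division, matching the printed shape
chain 64 -> 31 -> 15 -> 7 -> 3 of the default configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils import check_random_state

from . import _autodiff as ad
from .rbm import CssCRBMParams, TrainConfig, cd_update, init_params

__all__ = [
    "LayerSpec",
    "default_stack",
    "reduced_stack",
    "shape_chain",
    "forward_layer",
    "forward_deterministic",
    "FeatureStack",
    "pretrain_stack",
    "CssCDBN",
    "save_stack",
    "load_stack",
]

#: Contractive-penalty coefficients per layer of the default 4-layer stack.
DEFAULT_CONTRACTIVE_COEFFS = (0.1, 0.1, 0.2, 0.2)


@dataclass
class LayerSpec:
    n_kernels: int
    kernel_size: int = 3
    padding: int = 0
    pool: int = 2


def default_stack():
    """The reference 4-layer configuration: 3x64x64 input, kernel counts
    36/64/128/128, 3x3 kernels (padding 1 above layer 1), 2x2 pooling."""
    return [
        LayerSpec(36, 3, 0, 2),
        LayerSpec(64, 3, 1, 2),
        LayerSpec(128, 3, 1, 2),
        LayerSpec(128, 3, 1, 2),
    ]


def reduced_stack(n_kernels=8):
    """A single-layer stack for small-scale experiments."""
    return [LayerSpec(n_kernels, 3, 0, 2)]


def shape_chain(layers, input_shape):
    """Spatial/channel sizes after each layer (conv then floor-pooled)."""
    c, h, w = input_shape
    chain = [(c, h, w)]
    for i, spec in enumerate(layers):
        h2 = h + 2 * spec.padding - spec.kernel_size + 1
        w2 = w + 2 * spec.padding - spec.kernel_size + 1
        if h2 < 1 or w2 < 1:
            raise ValueError(f"layer {i}: kernel exceeds input {h}x{w}")
        h, w = h2 // spec.pool, w2 // spec.pool
        if h < 1 or w < 1:
            raise ValueError(f"layer {i}: pooling collapses the {h2}x{w2} map")
        c = spec.n_kernels
        chain.append((c, h, w))
    return chain


def _layer_parts(params):
    """(w, b, a, pool, padding) from CssCRBMParams or a dict of Tensors."""
    if isinstance(params, CssCRBMParams):
        a = params.a if params.a.ndim == 1 else params.a
        return params.w, params.b, a, params.pool, params.padding
    w, b = params["w"], params["b"]
    a = ad.exp(params["log_a"])
    return w, b, a, params["pool"], params["padding"]


def forward_layer(v, params, mode="eval", rng=None, noise_scale="inverse_penalty"):
    """Deterministic forward pass of one layer (ndarray or Tensor inputs).

    In ``train`` mode a seeded standard-normal noise term is added to the
    slab map. Its scale is 1/a with ``noise_scale='inverse_penalty'`` (the
    source formulation's printed noise term) or 1/sqrt(a) with
    ``'conditional_sd'`` (the slab conditional's actual standard
    deviation); the two differ whenever a != 1. ``eval`` mode is
    noise-free and repeatable.
    """
    w, b, a, pool, padding = _layer_parts(params)
    z = ad.conv2d(v, w, padding=padding)
    a_col = ad.reshape(a, (1, -1, 1, 1)) if isinstance(a, ad.Tensor) else \
        np.reshape(np.asarray(a), (1, -1, 1, 1))
    b_col = ad.reshape(b, (1, -1, 1, 1)) if isinstance(b, ad.Tensor) else \
        np.reshape(np.asarray(b), (1, -1, 1, 1))
    h = ad.relu(z * z / (2.0 * a_col) + b_col)
    s = z * h / a_col
    if mode == "train":
        if rng is None:
            raise ValueError("train mode requires a seeded rng")
        noise = rng.standard_normal(np.shape(ad.asdata(z)))
        scale = (1.0 / a_col) if noise_scale == "inverse_penalty" else a_col ** -0.5
        s = s + scale * noise
    elif mode != "eval":
        raise ValueError(f"unknown mode {mode!r}")
    hybrid = h * s
    pooled = ad.maxpool2d(hybrid, pool)
    dat = ad.asdata(pooled)
    if not np.all(np.isfinite(dat)):
        raise FloatingPointError("non-finite activations in layer forward")
    return {"z": z, "h": h, "s": s, "hybrid": hybrid, "pooled": pooled}


@dataclass
class FeatureStack:
    """Per-layer activation snapshots of a deterministic forward pass."""

    layers: list

    @property
    def final(self):
        return self.layers[-1]["pooled"]


def forward_deterministic(v, stack, mode="eval", rng=None, noise_scale="inverse_penalty"):
    """Run the whole stack; returns a :class:`FeatureStack` (the ``final``
    property is the top pooled hybrid map)."""
    x = v
    if isinstance(x, np.ndarray) and x.ndim == 3:
        x = x[None]
    states = []
    for li, params in enumerate(stack):
        try:
            state = forward_layer(x, params, mode=mode, rng=rng,
                                  noise_scale=noise_scale)
        except FloatingPointError as exc:
            raise FloatingPointError(f"layer {li}: {exc}") from exc
        states.append(state)
        x = state["pooled"]
    return FeatureStack(layers=states)


def pretrain_stack(data, layers, train_cfg, lams=None, rng=None,
                   progress=None):
    """Greedy layer-wise CD pretraining.

    data : [N, C, H, W]; layers : sequence of LayerSpec; lams optionally
    overrides the contractive coefficient per layer (defaults to the
    4-layer reference schedule, truncated/padded as needed). The input to
    each layer is the pooled hybrid map of the layer below (deterministic
    eval-mode forward). epochs = 0 returns initialised, untrained kernels.
    """
    data = np.asarray(data, dtype=np.float64)
    chain = shape_chain(layers, data.shape[1:])  # validates before training
    rng = np.random.default_rng(rng)
    if lams is None:
        lams = [
            DEFAULT_CONTRACTIVE_COEFFS[min(i, len(DEFAULT_CONTRACTIVE_COEFFS) - 1)]
            if train_cfg.lam is None else train_cfg.lam
            for i in range(len(layers))
        ]
    params_list = []
    x = data
    for li, spec in enumerate(layers):
        params = init_params(
            spec.n_kernels, x.shape[1], spec.kernel_size,
            pool=spec.pool, padding=spec.padding, rng=rng,
        )
        cfg = TrainConfig(
            eta=train_cfg.eta, lam=lams[li], cd_steps=train_cfg.cd_steps,
            batchsize=train_cfg.batchsize, epochs=train_cfg.epochs,
            clip_norm=getattr(train_cfg, "clip_norm", 5.0),
        )
        n = x.shape[0]
        bs = min(cfg.batchsize, n)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n - bs + 1, bs):
                batch = x[order[start : start + bs]]
                params = cd_update(batch, params, cfg, rng)
            if progress is not None:
                progress(li, epoch, params)
        params_list.append(params)
        if li + 1 < len(layers):
            x = forward_layer(x, params, mode="eval")["pooled"]
    assert shape_chain(layers, data.shape[1:]) == chain
    return params_list


class CssCDBN(TransformerMixin, BaseEstimator):
    """Greedy-pretrained stack of CssCRBMs as a feature extractor.

    ``fit`` pretrains all layers with CD-k; ``transform`` returns the final
    pooled hybrid feature maps, flattened to [n_samples, n_features].
    """

    def __init__(self, layers=None, eta=0.01, lam=None, cd_steps=5,
                 batch_size=20, n_epochs=1, random_state=None):
        self.layers = layers
        self.eta = eta
        self.lam = lam
        self.cd_steps = cd_steps
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.random_state = random_state

    def _layer_specs(self):
        return default_stack() if self.layers is None else list(self.layers)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        rs = check_random_state(self.random_state)
        cfg = TrainConfig(
            eta=self.eta, lam=self.lam if self.lam is not None else 0.0,
            cd_steps=self.cd_steps, batchsize=self.batch_size,
            epochs=max(self.n_epochs, 0),
        )
        cfg.lam = self.lam  # None -> per-layer default schedule
        self.params_ = pretrain_stack(
            X, self._layer_specs(), cfg,
            lams=None if self.lam is None else [self.lam] * len(self._layer_specs()),
            rng=np.random.default_rng(rs.randint(2**31)),
        )
        self.shape_chain_ = shape_chain(self._layer_specs(), X.shape[1:])
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        final = forward_deterministic(X, self.params_, mode="eval").final
        return final.reshape(len(X), -1)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_stack(path, params_list, extra=None):
    """HDF5 checkpoint: one group per layer (w, b, c, log_a, sigma, pool,
    padding); ``extra`` maps group names to dicts of arrays (e.g. the
    attention head)."""
    import h5py

    with h5py.File(path, "w") as f:
        for li, p in enumerate(params_list):
            g = f.create_group(f"layer{li}")
            g.create_dataset("w", data=p.w)
            g.create_dataset("b", data=p.b)
            g.create_dataset("c", data=p.c)
            g.create_dataset("log_a", data=np.log(p.a))
            g.attrs["sigma"] = p.sigma
            g.attrs["pool"] = p.pool
            g.attrs["padding"] = p.padding
        for name, arrays in (extra or {}).items():
            g = f.create_group(name)
            for key, val in arrays.items():
                g.create_dataset(key, data=np.asarray(val))


def load_stack(path):
    import h5py

    params_list, extra = [], {}
    with h5py.File(path, "r") as f:
        layer_names = sorted(
            (n for n in f if n.startswith("layer")),
            key=lambda n: int(n.removeprefix("layer")),
        )
        for name in layer_names:
            g = f[name]
            params_list.append(
                CssCRBMParams(
                    w=g["w"][:], b=g["b"][:], c=g["c"][:],
                    a=np.exp(g["log_a"][:]),
                    sigma=float(g.attrs["sigma"]),
                    pool=int(g.attrs["pool"]),
                    padding=int(g.attrs["padding"]),
                )
            )
        for name in f:
            if not name.startswith("layer"):
                extra[name] = {k: f[name][k][:] for k in f[name]}
    return params_list, extra


def layers_from_yaml(path_or_text):
    """Stack configuration from YAML: a list of {n_kernels, kernel_size,
    padding, pool} mappings, bottom to top."""
    try:
        text = open(path_or_text).read()
    except (OSError, ValueError):
        text = path_or_text
    raw = yaml.safe_load(text)
    return [LayerSpec(**entry) for entry in raw]
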