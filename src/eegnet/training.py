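"""Dual-task fine-tuning: classification plus Siamese verification.

After greedy pretraining the stack-plus-attention network is trained end to
end on two intertwined objectives. The main task is (categorical) cross-
entropy on the class probabilities. The auxiliary verification task pairs
images within each batch; for a pair with features f1, f2 and Euclidean
distance D = ||f1 - f2||, same-class pairs pay D^2 / 2 and different-class
pairs pay max(0, delta - D)^2 / 2 — a contrastive margin loss that pulls
intra-class features together and pushes inter-class features at least
``delta`` apart. The combined objective per pair is

    loss = loss_main(a) + loss_main(b) + c_ver * loss_ver(a, b),

averaged over pairs and minimised with Adam under weight sharing (both
Siamese branches reference the same parameters).

Verification features are the L2-normalised mean-pooled token
representation (the classifier's input), making the margin scale-free with
default delta = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils import check_random_state

from . import _autodiff as ad
from . import attention as att
from .rbm import TrainConfig
from .stack import (
    LayerSpec,
    default_stack,
    forward_deterministic,
    pretrain_stack,
    shape_chain,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VerificationPair",
    "LossWeights",
    "main_loss",
    "feature_distance",
    "verification_loss",
    "total_loss",
    "make_pairs",
    "AdamOptimizer",
    "FinetuneModel",
    "finetune",
    "SpatialTemporalEEGNet",
]


@dataclass
class VerificationPair:
    image_a: object
    image_b: object
    y_ver: int
    index_a: int = -1
    index_b: int = -1


@dataclass
class LossWeights:
    c_ver: float = 0.11
    delta: float = 1.0

    def __post_init__(self):
        if self.c_ver < 0:
            raise ValueError("c_ver must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


# ---------------------------------------------------------------------------
# losses (dispatch: ndarray or Tensor)
# ---------------------------------------------------------------------------

def _clamp_probs(y_hat):
    d = np.asarray(y_hat, dtype=np.float64)
    if np.any(d <= 0) or np.any(d >= 1):
        logger.warning("probabilities clamped away from {0, 1}")
        d = np.clip(d, 1e-12, 1 - 1e-12)
    return d


def main_loss(y_true, y_hat):
    """Mean cross-entropy. Binary when ``y_hat`` is 1-D (probability of the
    positive class); categorical when 2-D, reducing to the binary form at
    two classes."""
    y_true = np.asarray(y_true)
    if isinstance(y_hat, ad.Tensor):
        if y_hat.ndim == 1:
            return ad.mean_(
                -(y_true * ad.log(y_hat) + (1 - y_true) * ad.log(1 - y_hat))
            )
        onehot = np.eye(y_hat.shape[1])[y_true.astype(int)]
        return -ad.mean_(ad.sum_(onehot * ad.log(y_hat), axis=1))
    y_hat = _clamp_probs(y_hat)
    if y_hat.ndim == 1:
        return float(
            np.mean(-y_true * np.log(y_hat) - (1 - y_true) * np.log(1 - y_hat))
        )
    onehot = np.eye(y_hat.shape[1])[y_true.astype(int)]
    return float(-np.mean((onehot * np.log(y_hat)).sum(axis=1)))


def feature_distance(f1, f2):
    """Euclidean distance between feature vectors (or batches thereof)."""
    d1, d2 = ad.asdata(f1), ad.asdata(f2)
    return np.linalg.norm(d1 - d2, axis=-1)


def verification_loss(f1, f2, y_ver, delta=1.0):
    """Contrastive loss: same pairs D^2/2, different pairs max(0, d-D)^2/2.

    Accepts single vectors or [P, d] batches (mean over pairs); Tensors keep
    the computation differentiable.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    y = np.asarray(y_ver, dtype=np.float64)
    diff = f1 - f2
    if isinstance(diff, ad.Tensor):
        axis = diff.ndim - 1
        d2 = ad.sum_(diff * diff, axis=axis)
        dist = ad.sqrt(d2 + 1e-12)
        same = 0.5 * d2
        other = 0.5 * ad.relu(delta - dist) ** 2
        loss = y * same + (1.0 - y) * other
        return ad.mean_(loss) if loss.ndim else loss
    d2 = (np.asarray(diff) ** 2).sum(axis=-1)
    dist = np.sqrt(d2)
    same = 0.5 * d2
    other = 0.5 * np.maximum(0.0, delta - dist) ** 2
    loss = y * same + (1.0 - y) * other
    return float(np.mean(loss))


def total_loss(y_true_a, y_hat_a, y_true_b, y_hat_b, f_a, f_b, y_ver,
               weights=None):
    """Combined dual-task objective, averaged over pairs."""
    weights = weights or LossWeights()
    lm = main_loss(y_true_a, y_hat_a) + main_loss(y_true_b, y_hat_b)
    lv = verification_loss(f_a, f_b, y_ver, weights.delta)
    return lm + weights.c_ver * lv


def make_pairs(images, labels, rng):
    """Split an even batch into two halves (seeded shuffle) and pair them
    index-wise; y_ver = 1 when the pair's labels agree."""
    labels = np.asarray(labels)
    n = len(labels)
    if n % 2 != 0:
        raise ValueError("batch size must be even for pairing")
    rng = np.random.default_rng(rng)
    order = rng.permutation(n)
    half = n // 2
    ia, ib = order[:half], order[half:]
    return [
        VerificationPair(
            image_a=images[a], image_b=images[b],
            y_ver=int(labels[a] == labels[b]), index_a=int(a), index_b=int(b),
        )
        for a, b in zip(ia, ib)
    ]


# ---------------------------------------------------------------------------
# optimiser and fine-tunable model
# ---------------------------------------------------------------------------

def calibrate_spike_biases(stack_params, X, quantile=0.9, margin=0.05):
    """Raise spike biases just enough that the rectified activation is alive.

    The deterministic forward replaces the logistic spike probability with a
    relu of the same argument; unlike the logistic, a relu whose argument is
    negative everywhere passes no signal and no gradient, so a sparsely
    initialised layer can enter fine-tuning dead. Per feature map, if the
    ``quantile`` of the activation argument over a calibration batch falls
    below ``margin``, the bias is shifted up by the difference. Biases are
    only ever raised, and only as far as needed.
    """
    from dataclasses import replace

    from .rbm import spike_activation

    x = np.asarray(X, dtype=np.float64)
    out = []
    for p in stack_params:
        u = spike_activation(x, p)
        qv = np.quantile(u, quantile, axis=(0, 2, 3))
        shift = np.maximum(0.0, margin - qv)
        p2 = replace(p, b=p.b + shift)
        out.append(p2)
        x = forward_deterministic(x, [p2], mode="eval").final
    return out


class AdamOptimizer:
    """Adam with the standard moment estimates (betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8):
        self.params = params  # dict name -> Tensor
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for key, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g**2
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class FinetuneModel:
    """Stack + attention head with shared trainable Tensors.

    Trainable: every layer's kernels, spike biases and log slab penalties,
    plus all attention/head parameters; visible biases and sigma stay
    frozen. The two Siamese branches run through the same Tensor objects,
    so weight sharing holds by construction.
    """

    def __init__(self, stack_params, attention_params, use_attention=True,
                 attention_norm="softmax", noise_scale="inverse_penalty"):
        self.use_attention = use_attention
        self.attention_norm = attention_norm
        self.noise_scale = noise_scale
        self.frozen = []
        self.layers = []
        for p in stack_params:
            self.layers.append({
                "w": ad.Tensor(p.w.copy(), requires_grad=True),
                "b": ad.Tensor(p.b.copy(), requires_grad=True),
                "log_a": ad.Tensor(np.log(p.a), requires_grad=True),
                "pool": p.pool,
                "padding": p.padding,
            })
            self.frozen.append({"c": p.c.copy(), "sigma": p.sigma})
        self.att = att.AttentionParams(**{
            k: ad.Tensor(np.asarray(v, dtype=np.float64).copy(),
                         requires_grad=True)
            for k, v in attention_params.arrays().items()
        })

    def parameters(self):
        out = {}
        for li, layer in enumerate(self.layers):
            for key in ("w", "b", "log_a"):
                out[f"layer{li}.{key}"] = layer[key]
        for key, val in self.att.arrays().items():
            out[f"att.{key}"] = val
        return out

    def forward(self, X, mode="eval", rng=None):
        """Returns (probability Tensor [N, C], feature Tensor [N, d])."""
        x = ad.Tensor(np.asarray(X, dtype=np.float64))
        feats = forward_deterministic(
            x, self.layers, mode=mode, rng=rng, noise_scale=self.noise_scale
        )
        probs, pooled = att.head_forward(
            feats.final, self.att, norm=self.attention_norm,
            use_attention=self.use_attention,
        )
        norm = ad.sqrt(ad.sum_(pooled * pooled, axis=1, keepdims=True) + 1e-12)
        return probs, pooled * norm ** -1.0

    def predict_proba(self, X):
        probs, _ = self.forward(X, mode="eval")
        return ad.asdata(probs)

    def features(self, X):
        _, f = self.forward(X, mode="eval")
        return ad.asdata(f)

    def export_stack(self):
        """Back to CssCRBMParams (e.g. for checkpointing)."""
        from .rbm import CssCRBMParams

        out = []
        for layer, frozen in zip(self.layers, self.frozen):
            out.append(CssCRBMParams(
                w=layer["w"].data.copy(), b=layer["b"].data.copy(),
                c=frozen["c"], a=np.exp(layer["log_a"].data),
                sigma=frozen["sigma"], pool=layer["pool"],
                padding=layer["padding"],
            ))
        return out


@dataclass
class FinetuneHistory:
    epoch: list = field(default_factory=list)
    loss_main: list = field(default_factory=list)
    loss_ver: list = field(default_factory=list)
    total: list = field(default_factory=list)


def finetune(model, X, y, epochs=10, batch_size=20, lr=0.01, c_ver=0.11,
             delta=1.0, rng=None, train_noise=False):
    """Dual-task fine-tuning loop.

    Per batch: forward once (weight-shared), compute the mean-over-pairs
    combined objective and take one Adam step on its gradient. Aborts with
    the last good parameters if the loss turns non-finite. Returns a
    :class:`FinetuneHistory` of per-epoch mean losses.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(rng)
    params = model.parameters()
    opt = AdamOptimizer(params, lr=lr)
    weights = LossWeights(c_ver=c_ver, delta=delta)
    history = FinetuneHistory()
    n = len(y)
    bs = batch_size if batch_size % 2 == 0 else batch_size + 1
    bs = min(bs, n - (n % 2))
    backup = {k: p.data.copy() for k, p in params.items()}
    for epoch in range(epochs):
        order = rng.permutation(n)
        lm_sum = lv_sum = tot_sum = 0.0
        n_batches = 0
        for start in range(0, n - bs + 1, bs):
            idx = order[start : start + bs]
            xb, yb = X[idx], y[idx]
            probs, feats = model.forward(
                xb, mode="train" if train_noise else "eval", rng=rng
            )
            pairs = make_pairs(np.arange(bs), yb, rng)
            ia = np.array([p.index_a for p in pairs])
            ib = np.array([p.index_b for p in pairs])
            yver = np.array([p.y_ver for p in pairs], dtype=np.float64)
            onehot = np.eye(probs.shape[1])[yb.astype(int)]
            ce = -ad.sum_(onehot * ad.log(probs + 1e-12), axis=1)
            # per-pair main losses: gather by index via selection matrices
            sel_a = np.zeros((len(ia), bs)); sel_a[np.arange(len(ia)), ia] = 1
            sel_b = np.zeros((len(ib), bs)); sel_b[np.arange(len(ib)), ib] = 1
            lm = ad.mean_(ad.matmul(sel_a, ce) + ad.matmul(sel_b, ce))
            fa = ad.matmul(sel_a, feats)
            fb = ad.matmul(sel_b, feats)
            lv = verification_loss(fa, fb, yver, delta)
            loss = lm + c_ver * lv
            if not np.isfinite(loss.data):
                for k, p in params.items():
                    p.data = backup[k]
                logger.warning("non-finite loss at epoch %d; restored last "
                               "good parameters and stopped", epoch)
                return history
            opt.zero_grad()
            loss.backward()
            opt.step()
            lm_sum += float(lm.data)
            lv_sum += float(lv.data)
            tot_sum += float(loss.data)
            n_batches += 1
        backup = {k: p.data.copy() for k, p in params.items()}
        history.epoch.append(epoch)
        history.loss_main.append(lm_sum / max(n_batches, 1))
        history.loss_ver.append(lv_sum / max(n_batches, 1))
        history.total.append(tot_sum / max(n_batches, 1))
    return history


# ---------------------------------------------------------------------------
# the full estimator
# ---------------------------------------------------------------------------

class SpatialTemporalEEGNet(ClassifierMixin, BaseEstimator):
    """Attention-augmented CssCDBN classifier with dual-task fine-tuning.

    ``fit`` standardises the images, greedily pretrains the stack with
    contractive CD, then fine-tunes stack + attention head end to end on
    the combined classification/verification objective. ``layers=None``
    uses the reference 4-layer configuration; small experiments pass their
    own :class:`~eegnet.stack.LayerSpec` list.
    """

    def __init__(self, layers=None, pretrain_epochs=1, cd_steps=5, eta=0.01,
                 lam=None, finetune_epochs=10, lr=0.01, batch_size=20,
                 c_ver=0.11, delta=1.0, use_attention=True, dual_task=True,
                 attention_norm="softmax", train_noise=False, calibrate=True,
                 log_power="auto", random_state=None):
        self.layers = layers
        self.pretrain_epochs = pretrain_epochs
        self.cd_steps = cd_steps
        self.eta = eta
        self.lam = lam
        self.finetune_epochs = finetune_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.c_ver = c_ver
        self.delta = delta
        self.use_attention = use_attention
        self.dual_task = dual_task
        self.attention_norm = attention_norm
        self.train_noise = train_noise
        self.calibrate = calibrate
        self.log_power = log_power
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 4:
            raise ValueError("X must be [n_samples, n_bands, H, W]")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rs = check_random_state(self.random_state)
        rng = np.random.default_rng(rs.randint(2**31))

        # band-power pixels are heavy-tailed; compress with log1p when the
        # input is nonnegative (or when explicitly requested)
        self.log_power_ = (
            self.log_power is True
            or (self.log_power == "auto" and float(X.min()) >= 0.0)
        )
        Xl = np.log1p(X) if self.log_power_ else X
        self.pixel_mean_ = Xl.mean(axis=0)
        self.pixel_std_ = Xl.std(axis=0) + 1e-8
        Xs = (Xl - self.pixel_mean_) / self.pixel_std_

        specs = default_stack() if self.layers is None else list(self.layers)
        cfg = TrainConfig(
            eta=self.eta, lam=0.0, cd_steps=self.cd_steps,
            batchsize=self.batch_size, epochs=max(self.pretrain_epochs, 0),
        )
        stack_params = pretrain_stack(
            Xs, specs, cfg,
            lams=None if self.lam is None else [self.lam] * len(specs),
            rng=rng,
        )
        if self.calibrate:
            cal = Xs[: min(len(Xs), 200)]
            stack_params = calibrate_spike_biases(stack_params, cal)
        chain = shape_chain(specs, Xs.shape[1:])
        c, hs, ws = chain[-1]
        att_params = att.init_attention(
            d_model=c, n_tokens=hs * ws, n_classes=len(self.classes_),
            rng=rng,
        )
        self.model_ = FinetuneModel(
            stack_params, att_params, use_attention=self.use_attention,
            attention_norm=self.attention_norm,
        )
        self.history_ = finetune(
            self.model_, Xs, y_idx, epochs=self.finetune_epochs,
            batch_size=self.batch_size, lr=self.lr,
            c_ver=self.c_ver if self.dual_task else 0.0, delta=self.delta,
            rng=rng, train_noise=self.train_noise,
        )
        self.shape_chain_ = chain
        self.n_features_in_ = X.shape[1]
        return self

    def _standardise(self, X):
        X = np.asarray(X, dtype=np.float64)
        if self.log_power_:
            X = np.log1p(np.maximum(X, 0.0))
        return (X - self.pixel_mean_) / self.pixel_std_

    def predict_proba(self, X):
        return self.model_.predict_proba(self._standardise(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def transform(self, X):
        """Verification features (L2-normalised pooled token vectors)."""
        return self.model_.features(self._standardise(X))
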