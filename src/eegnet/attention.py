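"""Transformer-encoder head over hybrid feature-map tokens.

The final pooled hybrid maps of the stack (128 channels on a 3x3 grid by
default) are flattened row-major into 9 tokens of width 128, given learned
positional embeddings, and passed through one encoder block: single-head
scaled dot-product self-attention and a two-layer perceptron, each wrapped
in a pre-norm residual connection. Classification mean-pools the tokens and
applies a linear softmax head.

With every transform weight at zero the whole head is the identity on
tokens and the classifier outputs the uniform distribution; attention rows
are always stochastic (softmax-normalised). ``attention_norm='none'`` keeps
raw scaled dot products as weights, exposing the un-normalised variant for
ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from . import _autodiff as ad

__all__ = [
    "AttentionParams",
    "init_attention",
    "tokenize",
    "self_attention",
    "attention_weights",
    "encoder_block",
    "classify",
    "head_forward",
]


@dataclass
class AttentionParams:
    """Encoder-block, positional and classifier parameters.

    Arrays (or autodiff Tensors during fine-tuning):
    wq, wk, wv, wo : [d, d] projections; mlp_* : two-layer perceptron with
    hidden width ``mlp_hidden``; ln*_g/b : layer-norm scale/shift;
    pos : [n_tokens, d] learned positional embeddings; head_w/b : linear
    classifier on the mean-pooled token representation.
    """

    wq: object
    wk: object
    wv: object
    wo: object
    mlp_w1: object
    mlp_b1: object
    mlp_w2: object
    mlp_b2: object
    ln1_g: object
    ln1_b: object
    ln2_g: object
    ln2_b: object
    lnf_g: object
    lnf_b: object
    pos: object
    head_w: object
    head_b: object

    def arrays(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}


def init_attention(d_model, n_tokens, n_classes, mlp_hidden=None, rng=None,
                   scale=0.02):
    """Small random init for the transform weights; layer-norm at identity,
    positional embeddings small."""
    rng = np.random.default_rng(rng)
    dh = 2 * d_model if mlp_hidden is None else mlp_hidden
    def w(*shape):
        return rng.normal(0.0, scale, size=shape)

    return AttentionParams(
        wq=w(d_model, d_model), wk=w(d_model, d_model),
        wv=w(d_model, d_model), wo=w(d_model, d_model),
        mlp_w1=w(d_model, dh), mlp_b1=np.zeros(dh),
        mlp_w2=w(dh, d_model), mlp_b2=np.zeros(d_model),
        ln1_g=np.ones(d_model), ln1_b=np.zeros(d_model),
        ln2_g=np.ones(d_model), ln2_b=np.zeros(d_model),
        lnf_g=np.ones(d_model), lnf_b=np.zeros(d_model),
        pos=w(n_tokens, d_model),
        head_w=w(d_model, n_classes), head_b=np.zeros(n_classes),
    )


def tokenize(maps, pos=None):
    """Flatten [N, C, Hs, Ws] feature maps into [N, Hs*Ws, C] tokens
    (row-major spatial order) and add positional embeddings."""
    d = ad.asdata(maps)
    n, c, hs, ws = d.shape
    tokens = ad.reshape(maps, (n, c, hs * ws))
    tokens = ad.transpose(tokens, (0, 2, 1))
    if pos is not None:
        tokens = tokens + pos
    return tokens


def attention_weights(tokens, params, norm="softmax"):
    """Scaled dot-product attention matrix [N, T, T]."""
    d_model = ad.asdata(tokens).shape[-1]
    q = ad.matmul(tokens, params.wq)
    k = ad.matmul(tokens, params.wk)
    scores = ad.matmul(q, ad.transpose(k, (0, 2, 1))) * (d_model ** -0.5)
    if norm == "softmax":
        return ad.softmax(scores, axis=-1)
    if norm == "none":
        return scores
    raise ValueError(f"unknown attention norm {norm!r}")


def _attention_out(tokens, params, norm="softmax"):
    attn = attention_weights(tokens, params, norm=norm)
    v = ad.matmul(tokens, params.wv)
    return ad.matmul(ad.matmul(attn, v), params.wo)


def self_attention(tokens, params, norm="softmax"):
    """Residual single-head self-attention: tokens + A V Wo."""
    return tokens + _attention_out(tokens, params, norm=norm)


def _mlp(x, params):
    h = ad.relu(ad.matmul(x, params.mlp_w1) + params.mlp_b1)
    return ad.matmul(h, params.mlp_w2) + params.mlp_b2


def encoder_block(tokens, params, norm="softmax", pre_norm=True):
    """Self-attention then two-layer perceptron, each residual (pre-norm
    layer normalisation by default)."""
    if pre_norm:
        y = tokens + _attention_out(
            ad.layer_norm(tokens, params.ln1_g, params.ln1_b), params,
            norm=norm,
        )
        return y + _mlp(ad.layer_norm(y, params.ln2_g, params.ln2_b), params)
    y = self_attention(tokens, params, norm=norm)
    return y + _mlp(y, params)


def classify(tokens, head_w, head_b):
    """Mean-pool tokens and map to class probabilities (softmax)."""
    pooled = ad.mean_(tokens, axis=1)
    logits = ad.matmul(pooled, head_w) + head_b
    return ad.softmax(logits, axis=-1)


def head_forward(maps, params, norm="softmax", use_attention=True):
    """Feature maps -> (class probabilities, pooled feature vectors).

    The pooled token representation feeding the classifier is also the
    verification feature (L2-normalised by the caller).
    """
    tokens = tokenize(maps, params.pos)
    if use_attention:
        tokens = encoder_block(tokens, params, norm=norm)
    # final layer norm keeps the pooled representation (and hence the
    # logits) bounded regardless of the stack's activation scale
    tokens = ad.layer_norm(tokens, params.lnf_g, params.lnf_b)
    pooled = ad.mean_(tokens, axis=1)
    logits = ad.matmul(pooled, params.head_w) + params.head_b
    return ad.softmax(logits, axis=-1), pooled
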