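"""Synthetic data: EEG-like records with class-dependent band signatures,
and tiny exactly-enumerable spike-and-slab RBM instances.

The EEG generator emulates the structure of clinical scalp recordings (23
bipolar channels at 256 Hz) without claiming physiological realism: each
channel is 1/f-shaped Gaussian noise whose theta/alpha/beta band power is
boosted by per-class gains (narrowband spectral shaping, i.e. band-filtered
noise), and the ictal class superimposes high-amplitude 3-5 Hz rhythmic
bursts. Class signatures are configuration knobs chosen to make classes
separable for testing, not claims about epileptic physiology.

The tiny-RBM factory returns a one-channel 3x3-visible model small enough
that the spike posterior and the exact likelihood can be computed by brute
force (enumerating all spike configurations and integrating the Gaussian
slab and visible units analytically), serving as the independent oracle for
the closed-form conditionals and the CD gradient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .preprocessing import CHB_CHANNELS, EEGRecord
from .rbm import CssCRBMParams, init_params

__all__ = [
    "SynthSpec",
    "gen_eeg",
    "gen_cohort",
    "gen_tiny_rbm",
    "enumerate_h_configs",
    "log_joint_vh",
    "enumerate_spike_posterior",
    "exact_log_likelihood",
    "exact_loglik_gradient",
    "gen_filter_images",
]

DEFAULT_CLASS_GAINS = {
    # multipliers on (theta, alpha, beta) band power over the 1/f background
    "interictal": (1.0, 1.0, 1.0),
    "preictal": (3.0, 2.0, 1.5),
    "ictal": (4.0, 1.0, 2.0),
}

_BAND_EDGES = ((4.0, 7.0), (8.0, 13.0), (13.0, 30.0))


@dataclass
class SynthSpec:
    """Configuration of the synthetic EEG generator.

    class_band_gains multiply the in-band oscillation *power* (so a 3x theta
    gain triples the theta oscillation power relative to the reference
    class); osc_to_background sets how strongly the oscillations dominate
    the 1/f background inside each band at gain 1.
    """

    n_channels: int = 23
    fs: float = 256.0
    class_band_gains: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_GAINS)
    )
    noise_exponent: float = 1.0
    osc_to_background: float = 8.0
    amplitude_uv: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for label, gains in self.class_band_gains.items():
            if any(g <= 0 for g in gains):
                raise ValueError(f"gains for {label} must be positive")
        if self.fs <= 2 * max(hi for _, hi in _BAND_EDGES):
            raise ValueError("fs must exceed twice the highest band bound")


def gen_eeg(spec, label, duration_s, seed=None, patient_id=""):
    """One synthetic EEG record of the given class.

    Channels are independent realisations of spectrally shaped Gaussian
    noise: amplitude ~ f^(-beta/2) with the class's band-power boosts; the
    ictal class adds rhythmic 3-5 Hz bursts. Fully deterministic given the
    seed (defaults to spec.seed).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if label not in spec.class_band_gains:
        raise ValueError(
            f"unknown label {label!r}; known: {sorted(spec.class_band_gains)}"
        )
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = int(round(duration_s * spec.fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.fs)
    power = np.where(freqs > 0, np.maximum(freqs, 1.0) ** (-spec.noise_exponent), 0.0)
    gains = spec.class_band_gains[label]
    boost = np.ones_like(freqs)
    for (lo, hi), g in zip(_BAND_EDGES, gains):
        mask = (freqs >= lo) & (freqs <= hi)
        boost[mask] += spec.osc_to_background * g
    amp = np.sqrt(power * boost)
    shape = (spec.n_channels, len(freqs))
    coef = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * amp
    coef[:, 0] = 0.0
    data = np.fft.irfft(coef, n=n, axis=1)
    # scale by the gain-free baseline RMS so class gains survive intact
    std_ref = 2.0 / n * np.sqrt(power.sum())
    data *= spec.amplitude_uv / max(std_ref, 1e-12)
    if label == "ictal":
        t = np.arange(n) / spec.fs
        burst_f = 3.0 + 2.0 * rng.random()
        envelope = (np.sin(2 * np.pi * t / 4.0) > 0).astype(float)
        phase = 2 * np.pi * rng.random(spec.n_channels)
        data = data + (
            3.0 * spec.amplitude_uv * envelope
            * np.sin(2 * np.pi * burst_f * t + phase[:, None])
        )
    names = tuple(CHB_CHANNELS[: spec.n_channels]) if spec.n_channels <= 23 \
        else tuple(f"CH{i}" for i in range(spec.n_channels))
    return EEGRecord(
        data=data.astype(np.float32),
        fs=spec.fs,
        channel_names=names,
        intervals=[(0.0, duration_s, label)],
        patient_id=patient_id,
    )


def gen_cohort(spec, n_patients=10, preictal_events=3, preictal_min=60.0,
               interictal_min=180.0, ictal_min=30.0):
    """Lazily generate per-patient record sets for both database builds.

    Per patient (defaults follow the study conditions): ``preictal_events``
    preictal records of ``preictal_min`` minutes (180 min total), one
    ``interictal_min``-minute interictal record, one ``ictal_min``-minute
    ictal record. Yields ``(patient_id, [EEGRecord, ...])`` one patient at a
    time so callers can stream; each patient has a distinct sub-seed.
    """
    children = np.random.SeedSequence(spec.seed).spawn(n_patients)
    for pid_seq in range(n_patients):
        patient = f"synth{pid_seq + 1:02d}"
        subseeds = children[pid_seq].generate_state(preictal_events + 2) % (2**31)
        records = [
            gen_eeg(spec, "preictal", preictal_min * 60.0,
                    seed=int(subseeds[k]), patient_id=patient)
            for k in range(preictal_events)
        ]
        records.append(
            gen_eeg(spec, "interictal", interictal_min * 60.0,
                    seed=int(subseeds[-2]), patient_id=patient)
        )
        records.append(
            gen_eeg(spec, "ictal", ictal_min * 60.0,
                    seed=int(subseeds[-1]), patient_id=patient)
        )
        yield patient, records


# ---------------------------------------------------------------------------
# tiny RBM instances and exact enumeration
# ---------------------------------------------------------------------------

def gen_tiny_rbm(seed=0, n_kernels=1, visible_size=3, kernel_size=2, pool=1,
                 n_samples=6):
    """A small CssCRBM instance plus a sample set, for oracle testing.

    Parameters are randomised but kept moderate so the joint (v, s) Gaussian
    stays well conditioned for every spike configuration.
    """
    rng = np.random.default_rng(seed)
    params = init_params(n_kernels, 1, kernel_size, pool=pool, rng=rng)
    params = replace(
        params,
        w=rng.normal(0.0, 0.25, size=params.w.shape),
        b=rng.normal(-0.5, 0.5, size=params.b.shape),
        c=rng.normal(0.0, 0.3, size=params.c.shape),
        a=rng.uniform(0.8, 1.6, size=params.a.shape),
    )
    samples = rng.normal(
        0.0, 1.0, size=(n_samples, 1, visible_size, visible_size)
    )
    return params, samples


def _hidden_shape(params, visible_size):
    k = params.kernel_size
    n = visible_size + 2 * params.padding - k + 1
    return (params.n_kernels, n, n)


def enumerate_h_configs(hidden_shape, pool=1):
    """All spike configurations honouring the at-most-one-per-block rule."""
    K, H, W = hidden_shape
    blocks = {}
    for i in range(H):
        for j in range(W):
            blocks.setdefault((i // pool, j // pool), []).append((i, j))
    block_choices = []
    for members in blocks.values():
        block_choices.append([None] + members)  # None = block off
    configs = []
    per_map = []
    for choice in itertools.product(*block_choices):
        m = np.zeros((H, W))
        for pos in choice:
            if pos is not None:
                m[pos] = 1.0
        per_map.append(m)
    for maps in itertools.product(per_map, repeat=K):
        configs.append(np.stack(maps))
    return configs


def log_joint_vh(v, h, params):
    """log integral_s exp(-E(v, s, h)) via the Gaussian slab integral.

    Each slab unit contributes integral exp(z h s - a s^2 / 2) ds
    = sqrt(2 pi / a) exp((z h)^2 / (2a)); the remaining energy terms are
    evaluated directly from the energy function.
    """
    from . import _autodiff as ad

    v = np.asarray(v, dtype=np.float64)
    if v.ndim == 3:
        v = v[None]
    z = ad.conv2d(v, params.w, padding=params.padding)[0]
    a = params.a_col()[0]
    spike_term = (params.b[:, None, None] * h).sum()
    vis_term = -((v[0] - params.c[:, None, None]) ** 2).sum() / (
        2.0 * params.sigma**2
    )
    slab_int = (
        0.5 * np.log(2.0 * np.pi / a) * np.ones_like(h)
        + (z * h) ** 2 / (2.0 * np.broadcast_to(a, h.shape))
    ).sum()
    return spike_term + vis_term + slab_int


def enumerate_spike_posterior(v, params, visible_size=None):
    """Exact p(h | v) by brute-force normalisation over all configurations.

    Returns ``(configs, probs, unit_marginals)`` where unit_marginals[k,i,j]
    = p(h_ijk = 1 | v).
    """
    v = np.asarray(v, dtype=np.float64)
    if v.ndim == 3:
        vs = v.shape[-1]
    else:
        vs = v.shape[-1]
    hshape = _hidden_shape(params, vs)
    configs = enumerate_h_configs(hshape, params.pool)
    logw = np.array([log_joint_vh(v, h, params) for h in configs])
    logw -= logsumexp(logw)
    probs = np.exp(logw)
    marg = np.zeros(hshape)
    for p, h in zip(probs, configs):
        marg += p * h
    return configs, probs, marg


def _free_energy_quadratic(h, params, visible_size):
    """Log integral over (v, s) of exp(-E) for a fixed spike configuration.

    E is jointly quadratic in x = (v, s): E = x^T A x / 2 - b^T x + const,
    so the integral is exp(-const) (2 pi)^{d/2} det(A)^{-1/2}
    exp(b^T A^{-1} b / 2).
    """
    L = params.n_channels
    K, Hh, Wh = h.shape
    k = params.kernel_size
    nv = L * visible_size * visible_size
    ns = K * Hh * Wh
    d = nv + ns
    A = np.zeros((d, d))
    A[:nv, :nv] = np.eye(nv) / params.sigma**2
    a = np.broadcast_to(params.a_col()[0], h.shape)
    A[nv:, nv:] = np.diag(a.ravel())
    # coupling -v^T C s from the cross term, C[(l,m,n),(k,i,j)] = h w
    C = np.zeros((nv, ns))
    p = params.padding
    for ki in range(K):
        for i in range(Hh):
            for j in range(Wh):
                s_idx = (ki * Hh + i) * Wh + j
                if h[ki, i, j] == 0:
                    continue
                for l in range(L):
                    for r in range(k):
                        for cc in range(k):
                            m, n = i + r - p, j + cc - p
                            if 0 <= m < visible_size and 0 <= n < visible_size:
                                v_idx = (l * visible_size + m) * visible_size + n
                                C[v_idx, s_idx] += params.w[ki, l, r, cc]
    A[:nv, nv:] = -C
    A[nv:, :nv] = -C.T
    bvec = np.zeros(d)
    bvec[:nv] = np.repeat(params.c, visible_size * visible_size) / params.sigma**2
    const = (params.c**2).sum() * visible_size**2 / (2.0 * params.sigma**2) \
        - (params.b[:, None, None] * h).sum()
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("energy not integrable for this h")
    sol = np.linalg.solve(A, bvec)
    return -const + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet \
        + 0.5 * bvec @ sol


def exact_log_likelihood(v, params):
    """Exact log p(v) for tiny models: enumerate h, integrate s (and, for
    the partition function, v) analytically. Accepts [C,H,W] or [N,C,H,W]
    (mean log-likelihood over the batch)."""
    v = np.asarray(v, dtype=np.float64)
    if v.ndim == 3:
        v = v[None]
    vs = v.shape[-1]
    hshape = _hidden_shape(params, vs)
    configs = enumerate_h_configs(hshape, params.pool)
    log_z = logsumexp([
        _free_energy_quadratic(h, params, vs) for h in configs
    ])
    vals = []
    for vi in v:
        log_num = logsumexp([log_joint_vh(vi, h, params) for h in configs])
        vals.append(log_num - log_z)
    return float(np.mean(vals))


def exact_loglik_gradient(v, params, eps=1e-5):
    """Central finite differences of the exact log-likelihood with respect
    to every trainable parameter. Independent oracle for CD gradients."""
    grads = {}
    for name in ("w", "b", "c", "a"):
        base = getattr(params, name)
        g = np.zeros_like(base)
        it = np.nditer(base, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            for sgn in (+1, -1):
                pert = base.copy()
                pert[idx] += sgn * eps
                p2 = replace(params, **{name: pert})
                g[idx] += sgn * exact_log_likelihood(v, p2)
            g[idx] /= 2 * eps
        grads[name] = g
    return grads


# ---------------------------------------------------------------------------
# known-filter image generator (for recovery experiments)
# ---------------------------------------------------------------------------

def gen_filter_images(filters, n_images=200, image_size=10, density=0.08,
                      noise=0.1, seed=0):
    """Images composed as sparse spike maps convolved with known filters.

    filters : [K, kh, kw]; each image is sum_k spikes_k * filter_k plus
    Gaussian noise, standardised to zero mean / unit variance. Ground truth
    for kernel-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    filters = np.asarray(filters, dtype=np.float64)
    K, kh, kw = filters.shape
    hh, ww = image_size - kh + 1, image_size - kw + 1
    spikes = (rng.random((n_images, K, hh, ww)) < density).astype(float)
    spikes *= rng.uniform(0.5, 1.5, size=spikes.shape)
    from . import _autodiff as ad

    imgs = ad.conv_transpose2d(spikes, filters[:, None, :, :])
    imgs += noise * rng.standard_normal(imgs.shape)
    imgs -= imgs.mean()
    imgs /= imgs.std()
    return imgs  # [n, 1, image_size, image_size]
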