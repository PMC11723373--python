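"""EEG to band-power spectral images.

Raw multichannel EEG is cut into non-overlapping 2-second windows; each
window is Fourier-transformed per channel and summarised by the power in
three physiological bands — theta (4-7 Hz), alpha (8-13 Hz), beta
(13-30 Hz). The 23 per-channel band powers are laid out on a 5x5 scalp grid
reflecting the standard bipolar longitudinal montage and bicubically
resampled to 64x64, giving a 3x64x64 image (band order theta, alpha, beta).
Per-pixel standardisation and ZCA whitening (the whitening transform closest
to the identity) decorrelate the training images.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import RectBivariateSpline
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecord",
    "BandDefinition",
    "SpectralImage",
    "WhiteningTransform",
    "Segment",
    "SpectralImageSet",
    "DEFAULT_BANDS",
    "CHB_CHANNELS",
    "CHANNEL_GRID",
    "segment_record",
    "band_power",
    "lowpass_mask",
    "to_spectral_image",
    "fit_zca",
    "apply_zca",
    "inverse_zca",
    "ZCAWhitening",
    "build_database_one",
    "build_database_two",
    "save_images",
    "load_images",
    "read_edf",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError(f"invalid band bounds ({self.lo_hz}, {self.hi_hz})")


DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

#: The 23 bipolar derivations of the CHB-MIT montage, in recording order.
CHB_CHANNELS = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
    "P7-T7", "T7-FT9", "FT9-FT10", "FT10-T8", "T8-P8-1",
)

#: Scalp layout of the 23 derivations on a 5x5 grid (row 0 = frontal,
#: col 0 = left). Each derivation sits near the midpoint of its electrode
#: pair; the two unused cells are filled by nearest assigned neighbour.
#: Override by passing a custom ``layout`` to :func:`to_spectral_image`.
CHANNEL_GRID = {
    "FP1-F7": (0, 0), "FP1-F3": (0, 1), "FP2-F4": (0, 3), "FP2-F8": (0, 4),
    "F7-T7": (1, 0), "F3-C3": (1, 1), "FZ-CZ": (1, 2), "F4-C4": (1, 3),
    "F8-T8": (1, 4),
    "T7-P7": (2, 0), "C3-P3": (2, 1), "CZ-PZ": (2, 2), "C4-P4": (2, 3),
    "T8-P8": (2, 4),
    "P7-T7": (3, 0), "P3-O1": (3, 1), "P4-O2": (3, 3), "T8-P8-1": (3, 4),
    "P7-O1": (4, 0), "T7-FT9": (4, 1), "FT9-FT10": (4, 2), "FT10-T8": (4, 3),
    "P8-O2": (4, 4),
}


@dataclass
class EEGRecord:
    """Multichannel EEG with annotated period labels.

    data : [n_channels, n_samples] in microvolts
    fs : sampling rate (Hz)
    channel_names : per-row labels
    intervals : (start_s, end_s, label) with label in
        {"interictal", "preictal", "ictal"}
    """

    data: np.ndarray
    fs: float
    channel_names: tuple = CHB_CHANNELS
    intervals: list = field(default_factory=list)
    patient_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be [n_channels, n_samples]")
        dur = self.duration_s
        for start, end, label in self.intervals:
            if not (0 <= start <= end <= dur + 1e-9):
                raise ValueError(
                    f"interval ({start}, {end}, {label}) outside [0, {dur}]"
                )

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def duration_s(self):
        return self.data.shape[1] / self.fs


@dataclass
class Segment:
    """One fixed-length window cut from a record."""

    data: np.ndarray  # [n_channels, window_samples]
    t_start_s: float
    label: str = ""
    patient_id: str = ""


@dataclass
class SpectralImage:
    pixels: np.ndarray  # [3, H, W], band order theta/alpha/beta
    label: int
    patient_id: str = ""
    t_start_s: float = 0.0


@dataclass
class SpectralImageSet:
    """A labelled image dataset (band order theta, alpha, beta)."""

    pixels: np.ndarray  # [N, 3, H, W]
    labels: np.ndarray  # [N]
    patient: np.ndarray  # [N] strings
    t_start: np.ndarray  # [N] seconds
    class_names: tuple = ()
    band_order: tuple = ("theta", "alpha", "beta")

    def __len__(self):
        return len(self.labels)

    def class_counts(self):
        names = self.class_names or tuple(
            str(c) for c in np.unique(self.labels)
        )
        return {
            names[int(c)]: int((self.labels == c).sum())
            for c in np.unique(self.labels)
        }


@dataclass
class WhiteningTransform:
    """ZCA whitening: x -> matrix @ (x - mean).

    ``matrix`` is symmetric (U diag((e+eps)^-1/2) U^T); among all whitening
    transforms ZCA is the one closest to the identity, so whitened images
    stay visually comparable to their originals.
    """

    mean: np.ndarray
    matrix: np.ndarray
    epsilon: float
    inverse_matrix: np.ndarray | None = None


# ---------------------------------------------------------------------------
# windowing and band power
# ---------------------------------------------------------------------------

def segment_record(record, window_s, label_filter=None):
    """Cut non-overlapping ``window_s`` windows from intervals matching
    ``label_filter`` (all intervals when None). Trailing remainders shorter
    than a window are discarded; segments carry their start times."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = int(round(window_s * record.fs))
    out = []
    for start, end, label in record.intervals:
        if label_filter is not None and label != label_filter:
            continue
        n_win = int(np.floor((end - start) / window_s))
        i0 = int(round(start * record.fs))
        for k in range(n_win):
            sl = record.data[:, i0 + k * win : i0 + (k + 1) * win]
            if sl.shape[1] < win:
                break
            out.append(
                Segment(
                    data=sl,
                    t_start_s=start + k * window_s,
                    label=label,
                    patient_id=record.patient_id,
                )
            )
    return out


def band_power(segment, bands=DEFAULT_BANDS, fs=256.0, detrend=True):
    """Per-band, per-channel spectral power of one window.

    Entry (b, c) is the sum of squared DFT magnitudes of channel c over
    frequency bins inside [lo_hz, hi_hz]. The per-channel mean is removed
    first so DC leakage cannot bleed into the lowest band.
    """
    seg = np.asarray(segment, dtype=np.float64)
    if seg.ndim == 1:
        seg = seg[None]
    if seg.shape[1] < 2:
        raise ValueError("segment must have at least 2 samples")
    nyq = fs / 2.0
    for band in bands:
        if band.hi_hz >= nyq:
            raise ValueError(
                f"band {band.name} upper bound {band.hi_hz} Hz is not below "
                f"the Nyquist frequency {nyq} Hz"
            )
    if detrend:
        seg = seg - seg.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(seg, axis=1)
    freqs = np.fft.rfftfreq(seg.shape[1], d=1.0 / fs)
    power = np.abs(spec) ** 2
    out = np.empty((len(bands), seg.shape[0]))
    for i, band in enumerate(bands):
        mask = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
        out[i] = power[:, mask].sum(axis=1)
    return out


def _band_power_batch(segments, bands, fs):
    """Vectorised band power for [n_seg, n_channels, T] stacks."""
    seg = segments - segments.mean(axis=2, keepdims=True)
    spec = np.fft.rfft(seg, axis=2)
    freqs = np.fft.rfftfreq(seg.shape[2], d=1.0 / fs)
    power = np.abs(spec) ** 2
    out = np.empty((seg.shape[0], len(bands), seg.shape[1]))
    for i, band in enumerate(bands):
        mask = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
        out[:, i] = power[:, :, mask].sum(axis=2)
    return out


def lowpass_mask(spectrum, cutoff_hz, fs, n_samples=None):
    """Zero every rfft bin strictly above ``cutoff_hz``; bins at or below the
    cutoff pass unchanged."""
    if cutoff_hz >= fs / 2.0 * (1 + 1e-12) and cutoff_hz > fs / 2.0:
        raise ValueError("cutoff must not exceed the Nyquist frequency")
    spec = np.asarray(spectrum)
    nbins = spec.shape[-1]
    if n_samples is None:
        n_samples = 2 * (nbins - 1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)[:nbins]
    out = spec.copy()
    out[..., freqs > cutoff_hz] = 0.0
    return out


# ---------------------------------------------------------------------------
# grid layout and bicubic resampling
# ---------------------------------------------------------------------------

def _grid_embed(values, channel_names, layout, grid_size=5):
    """Place per-channel values on the scalp grid; unassigned cells take the
    value of the nearest assigned cell (Manhattan distance, row-major
    tie-break)."""
    grid = np.full((grid_size, grid_size), np.nan)
    for name, val in zip(channel_names, values):
        r, c = layout[name]
        grid[r, c] = val
    filled = [(r, c) for r in range(grid_size) for c in range(grid_size)
              if np.isfinite(grid[r, c])]
    for r in range(grid_size):
        for c in range(grid_size):
            if not np.isfinite(grid[r, c]):
                best = min(filled, key=lambda rc: (abs(rc[0] - r) + abs(rc[1] - c), rc))
                grid[r, c] = grid[best]
    return grid


@lru_cache(maxsize=8)
def _resample_operator(grid_size, out_size):
    """Linear operator mapping a grid_size^2 field to an out_size^2 image by
    bicubic spline interpolation. Knots sit on pixels round(linspace(0,
    out-1, grid)) so knot pixels reproduce the inputs exactly; every output
    pixel lies inside the knot hull (clamped evaluation, no extrapolation)."""
    knots = np.round(np.linspace(0, out_size - 1, grid_size)).astype(float)
    coords = np.arange(out_size, dtype=float)
    op = np.empty((out_size * out_size, grid_size * grid_size))
    basis = np.zeros((grid_size, grid_size))
    for i in range(grid_size):
        for j in range(grid_size):
            basis[i, j] = 1.0
            spline = RectBivariateSpline(knots, knots, basis, kx=3, ky=3, s=0)
            op[:, i * grid_size + j] = spline(coords, coords).ravel()
            basis[i, j] = 0.0
    return op, knots.astype(int)


def knot_pixels(grid_size=5, out_size=64):
    """Output-pixel coordinates of the source-grid knots."""
    _, knots = _resample_operator(grid_size, out_size)
    return knots


def to_spectral_image(powers, out_size=64, channel_names=CHB_CHANNELS,
                      layout=None, grid_size=5):
    """Turn a [n_bands, n_channels] power matrix into [n_bands, out, out]
    pixels by scalp-grid embedding plus bicubic resampling."""
    powers = np.asarray(powers, dtype=np.float64)
    if powers.ndim != 2:
        raise ValueError("powers must be [n_bands, n_channels]")
    if not np.all(np.isfinite(powers)):
        raise ValueError("non-finite band powers")
    layout = CHANNEL_GRID if layout is None else layout
    op, _ = _resample_operator(grid_size, out_size)
    fields = np.stack(
        [_grid_embed(row, channel_names, layout, grid_size).ravel()
         for row in powers]
    )
    return (fields @ op.T).reshape(powers.shape[0], out_size, out_size)


def _images_from_segments(segments, bands, fs, out_size, channel_names, layout):
    """Vectorised segment stack [n, C, T] -> image stack [n, 3, out, out]."""
    layout = CHANNEL_GRID if layout is None else layout
    bp = _band_power_batch(segments, bands, fs)  # n, 3, C
    grid_size = 5
    op, _ = _resample_operator(grid_size, out_size)
    # grid embedding is a fixed linear selection: build it once
    sel = np.zeros((grid_size * grid_size, len(channel_names)))
    grid_idx = np.full((grid_size, grid_size), -1, dtype=int)
    for ci, name in enumerate(channel_names):
        r, c = layout[name]
        grid_idx[r, c] = ci
    filled = [(r, c) for r in range(grid_size) for c in range(grid_size)
              if grid_idx[r, c] >= 0]
    for r in range(grid_size):
        for c in range(grid_size):
            if grid_idx[r, c] < 0:
                best = min(filled, key=lambda rc: (abs(rc[0] - r) + abs(rc[1] - c), rc))
                grid_idx[r, c] = grid_idx[best]
            sel[r * grid_size + c, grid_idx[r, c]] = 1.0
    full_op = op @ sel  # [out*out, C]
    n, nb, _ = bp.shape
    return (bp @ full_op.T).reshape(n, nb, out_size, out_size)


# ---------------------------------------------------------------------------
# ZCA whitening
# ---------------------------------------------------------------------------

def fit_zca(images, epsilon=1e-5):
    """Fit a ZCA whitening transform on flattened images [N, ...].

    Eigendecomposition-based: W = U diag((e + eps)^-1/2) U^T with the sample
    covariance's eigensystem (U, e). epsilon = 0 with a rank-deficient
    covariance raises.
    """
    X = np.asarray(images, dtype=np.float64).reshape(len(images), -1)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 images to fit whitening")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigvals, U = np.linalg.eigh(cov)
    eigvals = np.maximum(eigvals, 0.0)
    if epsilon == 0.0 and eigvals.min() < 1e-12 * max(eigvals.max(), 1.0):
        raise np.linalg.LinAlgError(
            "rank-deficient covariance with epsilon = 0; increase epsilon"
        )
    inv_sqrt = 1.0 / np.sqrt(eigvals + epsilon)
    matrix = (U * inv_sqrt) @ U.T
    inverse = (U * np.sqrt(eigvals + epsilon)) @ U.T
    return WhiteningTransform(mean=mean, matrix=matrix, epsilon=epsilon,
                              inverse_matrix=inverse)


def apply_zca(transform, images):
    X = np.asarray(images, dtype=np.float64)
    shape = X.shape
    flat = X.reshape(len(X), -1)
    return ((flat - transform.mean) @ transform.matrix.T).reshape(shape)


def inverse_zca(transform, images):
    if transform.inverse_matrix is None:
        raise ValueError("transform carries no inverse")
    X = np.asarray(images, dtype=np.float64)
    shape = X.shape
    flat = X.reshape(len(X), -1)
    return (flat @ transform.inverse_matrix.T + transform.mean).reshape(shape)


class ZCAWhitening(TransformerMixin, BaseEstimator):
    """sklearn-style ZCA whitening over flattened image pixels."""

    def __init__(self, epsilon=1e-5):
        self.epsilon = epsilon

    def fit(self, X, y=None):
        self.transform_ = fit_zca(X, self.epsilon)
        self.n_features_in_ = int(np.prod(np.asarray(X).shape[1:]))
        return self

    def transform(self, X):
        return apply_zca(self.transform_, X)

    def inverse_transform(self, X):
        return inverse_zca(self.transform_, X)


# ---------------------------------------------------------------------------
# database construction
# ---------------------------------------------------------------------------

def _collect_minutes(records, label, minutes, patient):
    """Chronologically take exactly ``minutes`` of ``label`` data as
    (record, start_s, end_s) chunks; raise naming the patient on shortfall."""
    need = minutes * 60.0
    chunks = []
    for rec in records:
        for start, end, lab in rec.intervals:
            if lab != label or need <= 0:
                continue
            take = min(end - start, need)
            chunks.append((rec, start, start + take))
            need -= take
    if need > 1e-6:
        raise ValueError(
            f"patient {patient}: insufficient {label} data, "
            f"short by {need / 60.0:.2f} min"
        )
    return chunks


def _chunk_images(rec, start, end, window_s, bands, out_size, layout):
    win = int(round(window_s * rec.fs))
    n_win = int(np.floor((end - start) / window_s))
    i0 = int(round(start * rec.fs))
    block = rec.data[:, i0 : i0 + n_win * win].astype(np.float64)
    segs = block.reshape(rec.n_channels, n_win, win).transpose(1, 0, 2)
    imgs = _images_from_segments(
        segs, bands, rec.fs, out_size, rec.channel_names, layout
    )
    t0 = start + window_s * np.arange(n_win)
    return imgs.astype(np.float32), t0


class _Sink:
    """Accumulates images in memory or streams them to HDF5.

    ``keep_pixels=False`` computes every image but retains only labels and
    counts — for verifying dataset construction at full scale without
    holding the pixel tensors.
    """

    def __init__(self, out, out_size, class_names, keep_pixels=True):
        self.out = out
        self.class_names = class_names
        self.keep_pixels = keep_pixels
        self._labels = []
        self._mem = [] if (out is None and keep_pixels) else None
        self._h5 = None
        if out is not None:
            import h5py

            self._h5 = h5py.File(out, "w")
            self._h5.attrs["band_order"] = "theta,alpha,beta"
            self._h5.attrs["class_names"] = ",".join(class_names)
            self._h5.create_dataset(
                "pixels", shape=(0, 3, out_size, out_size),
                maxshape=(None, 3, out_size, out_size), dtype="f4",
                chunks=(256, 3, out_size, out_size),
            )
            for name, dtype in (("labels", "i8"), ("t_start", "f8")):
                self._h5.create_dataset(name, shape=(0,), maxshape=(None,),
                                        dtype=dtype)
            self._h5.create_dataset(
                "patient", shape=(0,), maxshape=(None,),
                dtype=h5py.string_dtype(),
            )
        self.n = 0

    def add(self, pixels, labels, patient, t_start):
        k = len(labels)
        self._labels.append(labels)
        if self._h5 is None and self._mem is None:
            pass
        elif self._mem is not None:
            self._mem.append((pixels, labels, patient, t_start))
        else:
            for name, arr in (
                ("pixels", pixels), ("labels", labels),
                ("patient", patient), ("t_start", t_start),
            ):
                ds = self._h5[name]
                ds.resize(self.n + k, axis=0)
                ds[self.n :] = arr
        self.n += k

    def finish(self):
        if self._h5 is not None:
            self._h5.close()
            return None
        if not self.keep_pixels:
            return None
        pixels = np.concatenate([m[0] for m in self._mem]) if self._mem else \
            np.zeros((0, 3, 64, 64), dtype=np.float32)
        labels = np.concatenate([m[1] for m in self._mem]) if self._mem else \
            np.zeros(0, dtype=int)
        patient = np.concatenate([m[2] for m in self._mem]) if self._mem else \
            np.zeros(0, dtype=object)
        t_start = np.concatenate([m[3] for m in self._mem]) if self._mem else \
            np.zeros(0)
        return SpectralImageSet(
            pixels=pixels, labels=labels, patient=patient, t_start=t_start,
            class_names=self.class_names,
        )


def _iter_cohort(cohort):
    if hasattr(cohort, "items"):
        yield from cohort.items()
    else:
        yield from cohort


def build_database_one(cohort, window_s=2.0, minutes_per_class=180.0,
                       out_size=64, bands=DEFAULT_BANDS, layout=None,
                       out=None, keep_pixels=True):
    """Binary prediction dataset: per patient, equal durations of preictal
    (positive, label 1) and interictal (negative, label 0) data, windowed at
    ``window_s`` and imaged.

    ``cohort`` maps patient id -> list of EEGRecord (or yields such pairs).
    With ``out`` set, images stream to that HDF5 path and per-patient counts
    are returned; otherwise an in-memory :class:`SpectralImageSet`.
    """
    class_names = ("interictal", "preictal")
    sink = _Sink(out, out_size, class_names, keep_pixels=keep_pixels)
    counts = {}
    for patient, records in _iter_cohort(cohort):
        n_pat = 0
        for label, ylab in (("interictal", 0), ("preictal", 1)):
            chunks = _collect_minutes(records, label, minutes_per_class, patient)
            for rec, start, end in chunks:
                imgs, t0 = _chunk_images(rec, start, end, window_s, bands,
                                         out_size, layout)
                sink.add(
                    imgs, np.full(len(t0), ylab, dtype=int),
                    np.full(len(t0), patient, dtype=object), t0,
                )
                n_pat += len(t0)
        counts[patient] = n_pat
    result = sink.finish()
    if result is None:
        labels = np.concatenate(sink._labels) if sink._labels else np.zeros(0)
        per_class = {name: int((labels == i).sum())
                     for i, name in enumerate(class_names)}
        return {"per_patient": counts, "total": sink.n, "path": out,
                "class_names": class_names, "per_class": per_class}
    return result


def build_database_two(cohort, window_s=2.0, minutes_per_class=30.0,
                       out_size=64, bands=DEFAULT_BANDS, layout=None,
                       out=None, keep_pixels=True):
    """Four-class detection dataset: interictal / PreI / PreII / ictal,
    ``minutes_per_class`` each per patient. PreI is the earlier half and
    PreII the later half of the contiguous 2*minutes_per_class preictal
    window, so PreI strictly precedes PreII in time."""
    class_names = ("interictal", "PreI", "PreII", "ictal")
    sink = _Sink(out, out_size, class_names, keep_pixels=keep_pixels)
    counts = {}
    for patient, records in _iter_cohort(cohort):
        n_pat = 0
        plan = []
        for label, ylab in (("interictal", 0), ("ictal", 3)):
            plan.extend(
                (rec, s, e, ylab)
                for rec, s, e in _collect_minutes(records, label,
                                                  minutes_per_class, patient)
            )
        pre = _collect_minutes(records, "preictal", 2 * minutes_per_class,
                               patient)
        half = minutes_per_class * 60.0
        acc = 0.0
        for rec, s, e in pre:
            if acc < half:
                cut = min(e, s + (half - acc))
                plan.append((rec, s, cut, 1))
                if cut < e:
                    plan.append((rec, cut, e, 2))
                acc += e - s
            else:
                plan.append((rec, s, e, 2))
                acc += e - s
        for rec, start, end, ylab in plan:
            imgs, t0 = _chunk_images(rec, start, end, window_s, bands,
                                     out_size, layout)
            sink.add(
                imgs, np.full(len(t0), ylab, dtype=int),
                np.full(len(t0), patient, dtype=object), t0,
            )
            n_pat += len(t0)
        counts[patient] = n_pat
    result = sink.finish()
    if result is None:
        labels = np.concatenate(sink._labels) if sink._labels else np.zeros(0)
        per_class = {name: int((labels == i).sum())
                     for i, name in enumerate(class_names)}
        return {"per_patient": counts, "total": sink.n, "path": out,
                "class_names": class_names, "per_class": per_class}
    return result


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_images(path, dataset):
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["band_order"] = ",".join(dataset.band_order)
        f.attrs["class_names"] = ",".join(dataset.class_names)
        f.create_dataset("pixels", data=dataset.pixels.astype(np.float32))
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("patient",
                         data=np.asarray(dataset.patient, dtype="S"))
        f.create_dataset("t_start", data=dataset.t_start)


def load_images(path):
    import h5py

    with h5py.File(path, "r") as f:
        return SpectralImageSet(
            pixels=f["pixels"][:],
            labels=f["labels"][:],
            patient=f["patient"][:].astype(str),
            t_start=f["t_start"][:],
            class_names=tuple(f.attrs.get("class_names", "").split(",")),
        )


def read_edf(path, annotations_csv=None, channels=CHB_CHANNELS,
             patient_id=""):
    """Load an EDF recording (16-bit, CHB-MIT conventions) with optional
    interval annotations from a ``patient_id,start_s,end_s,label`` CSV."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = [ch for ch in channels if ch in raw.ch_names]
    raw.pick(picks)
    data = raw.get_data() * 1e6  # volts -> microvolts
    intervals = []
    if annotations_csv is not None:
        with open(annotations_csv, newline="") as f:
            for row in csv.DictReader(f):
                if patient_id and row["patient_id"] != patient_id:
                    continue
                intervals.append(
                    (float(row["start_s"]), float(row["end_s"]), row["label"])
                )
    return EEGRecord(
        data=data, fs=float(raw.info["sfreq"]),
        channel_names=tuple(picks), intervals=intervals,
        patient_id=patient_id,
    )
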