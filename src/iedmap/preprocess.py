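"""Sensor-space preparation for HMM inference: zero-phase band-pass and notch
filtering, anti-aliased resampling, time-delay embedding, and PCA reduction.

The canonical pipeline order is bandpass -> notch -> resample -> embed ->
pca_reduce; every step appends to the recording history so the order is
recorded.  Filters are applied forward-backward (zero phase) because both
analysis arms compare event timing at +/-73 ms resolution and group delay
would bias that comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal

from .containers import Recording
from .exceptions import ParameterError

__all__ = ["bandpass", "notch", "resample", "embed", "pca_reduce", "EmbeddedData"]


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (``order`` poles per pass)."""
    if not (0 < low < high < rec.fs / 2):
        raise ParameterError(f"band ({low}, {high}) Hz outside (0, Nyquist={rec.fs / 2}) or inverted")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.evolve(out, step={"step": "bandpass", "low": low, "high": high, "order": order})


def notch(rec: Recording, freq: float, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch (quality factor ``q``) at ``freq`` Hz."""
    if not (0 < freq < rec.fs / 2):
        raise ParameterError(f"notch frequency {freq} Hz outside (0, Nyquist)")
    b, a = signal.iirnotch(freq, q, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return rec.evolve(out, step={"step": "notch", "freq": freq, "q": q})


def resample(rec: Recording, fs_new: float) -> Recording:
    """Polyphase anti-aliased resampling to ``fs_new``.

    The caller is responsible for having band-limited the data below the new
    Nyquist; a warning is issued when the recorded filter history does not
    show that.
    """
    if fs_new <= 0:
        raise ParameterError("target sample rate must be positive")
    if fs_new > rec.fs:
        raise ParameterError("upsampling is not supported")
    if fs_new == rec.fs:
        return rec.evolve(rec.data.copy(), step={"step": "resample", "fs_new": fs_new})
    bands = [h for h in rec.history if h.get("step") == "bandpass"]
    if not bands or bands[-1]["high"] > fs_new / 2:
        warnings.warn(
            "resampling without a recorded band-pass below the new Nyquist; aliasing is "
            "suppressed only by the resampler's own anti-aliasing filter",
            stacklevel=2,
        )
    frac = Fraction(fs_new / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    n_target = int(round(rec.n_samples * fs_new / rec.fs))
    if out.shape[1] > n_target:
        out = out[:, :n_target]
    elif out.shape[1] < n_target:
        out = np.pad(out, ((0, 0), (0, n_target - out.shape[1])))
    return rec.evolve(out, fs=fs_new, step={"step": "resample", "fs_new": fs_new})


@dataclass
class EmbeddedData:
    """Time-delay embedded data, optionally PCA-reduced.

    ``matrix`` rows are valid samples (edges trimmed by ``valid_offset`` on
    each side); columns are channel-major: for channel ``c`` and lag index
    ``j`` (lag ``j - (n_lags-1)/2`` samples), the column is
    ``c * n_lags + j``.  After :func:`pca_reduce`, ``scores`` holds the
    component time courses and ``pca_basis`` the loadings.
    """

    matrix: np.ndarray  # (valid_samples, channels * n_lags)
    lags: np.ndarray  # integer sample offsets, symmetric about 0
    fs: float
    valid_offset: int  # samples trimmed at each edge
    n_channels: int
    scores: Optional[np.ndarray] = None  # (valid_samples, n_components)
    pca_basis: Optional[np.ndarray] = None  # (channels*n_lags, n_components)
    pca_mean: Optional[np.ndarray] = None
    pca_scale: Optional[np.ndarray] = None
    explained_variance_fraction: Optional[float] = None

    @property
    def n_lags(self) -> int:
        return len(self.lags)


def _n_lags_for_window(window_ms: float, fs: float) -> int:
    """Odd lag count closest to the requested window duration."""
    x = window_ms * fs / 1000.0
    n = 2 * int(np.floor(x / 2.0)) + 1
    if n < 3:
        raise ParameterError(f"embedding window {window_ms} ms spans fewer than 3 samples at {fs} Hz")
    return n


def embed(rec: Recording, window_ms: float = 73.0) -> EmbeddedData:
    """Time-delay embedding over a symmetric window of ``window_ms``.

    Each valid row concatenates every channel at every lag; rows within
    ``(n_lags-1)/2`` samples of either edge are dropped.  Row ``t`` is
    indexed to the lag-0 (centre) sample ``t + valid_offset`` of the input.
    """
    n_lags = _n_lags_for_window(window_ms, rec.fs)
    half = (n_lags - 1) // 2
    if rec.n_samples < n_lags:
        raise ParameterError("recording shorter than the embedding window")
    windows = np.lib.stride_tricks.sliding_window_view(rec.data, n_lags, axis=1)
    # windows: (C, T - n_lags + 1, n_lags); row t covers input samples t .. t+n_lags-1
    matrix = windows.transpose(1, 0, 2).reshape(windows.shape[1], rec.n_channels * n_lags)
    return EmbeddedData(
        matrix=np.ascontiguousarray(matrix),
        lags=np.arange(-half, half + 1),
        fs=rec.fs,
        valid_offset=half,
        n_channels=rec.n_channels,
    )


def pca_reduce(embedded: EmbeddedData, n_components: int = 50, standardize: bool = True) -> EmbeddedData:
    """Project the embedded matrix onto its leading principal components.

    Columns are centred (and per-column standardized when ``standardize``);
    components are eigenvectors of the column covariance, sign-fixed so the
    largest-magnitude loading of each component is positive.
    """
    X = embedded.matrix
    n_rows, n_cols = X.shape
    if not 1 <= n_components <= min(n_rows, n_cols):
        raise ParameterError(f"n_components must be in [1, {min(n_rows, n_cols)}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    if standardize:
        scale = X.std(axis=0, ddof=0)
        scale[scale < 1e-300] = 1.0
    else:
        scale = np.ones(n_cols)
    Xs = Xc / scale
    cov = (Xs.T @ Xs) / (n_rows - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    basis = eigvec[:, :n_components]
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    basis = basis * flip
    scores = Xs @ basis
    total = float(np.sum(np.maximum(eigval, 0.0)))
    evf = float(np.sum(np.maximum(eigval[:n_components], 0.0)) / total) if total > 0 else 1.0
    return EmbeddedData(
        matrix=embedded.matrix,
        lags=embedded.lags,
        fs=embedded.fs,
        valid_offset=embedded.valid_offset,
        n_channels=embedded.n_channels,
        scores=scores,
        pca_basis=basis,
        pca_mean=mean,
        pca_scale=scale,
        explained_variance_fraction=min(evf, 1.0),
    )
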