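"""Contraction quantification: optical flow and time-frequency analysis.

Placental motion between consecutive DCE frames is estimated per slice with
the Horn-Schunck variational method (dense in-plane velocity field balancing
the brightness-constancy data term against a smoothness penalty, default
regularization weight 100).  Chamber-wise mean-speed traces feed a Welch
periodogram; a short-time Fourier spectrogram (15-sample Bartlett window,
50% overlap, FFT zero-padded to 10x the trace length) resolves when during
the session the contraction frequencies are active.  Finally, the relative
spectral power of each voxel's intensity time course inside the 8-12 mHz
contraction band, mapped over the grid, localizes phasic motion; its
chamber summary drives a simple phasic/quiescent classification.

At the default 18 s frame interval the sampling rate is 55.6 mHz, so all
spectra end at the 27.8 mHz Nyquist frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy.fft import rfft, rfftfreq

from .chambers import ChamberAssignment
from .errors import InvalidInputError, InvalidParameterError
from .io_preprocess import DCESeries, SegmentationLabelMap

__all__ = [
    "VelocityField",
    "MotionTrace",
    "horn_schunck",
    "compute_flow_series",
    "velocity_traces",
    "welch_psd",
    "spectrogram_stft",
    "subband_relative_power_map",
    "summarize_subband",
    "classify_phasic",
]

# Horn-Schunck neighborhood-average kernel
_AVG_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
)
_GRAD_X = 0.25 * np.array([[-1.0, -1.0], [1.0, 1.0]])
_GRAD_Y = 0.25 * np.array([[-1.0, 1.0], [-1.0, 1.0]])


@dataclass
class VelocityField:
    """Dense in-plane flow between two frames (voxels/frame)."""

    u: np.ndarray
    v: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass
class MotionTrace:
    """Mean speed per frame pair over one region of one placenta."""

    placenta_id: int
    region: str  # whole | low | high
    time_s: np.ndarray
    mean_speed: np.ndarray  # voxels/frame


def horn_schunck(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    alpha: float = 100.0,
    n_iter: int = 100,
    tol: float = 1e-4,
) -> VelocityField:
    """Horn-Schunck optical flow between two 2-D frames.

    ``alpha`` is the smoothness (regularization) weight entering the update
    u = u_bar - Ix (Ix u_bar + Iy v_bar + It) / (alpha + Ix^2 + Iy^2) with
    the original 2x2x2 gradient stencils and 8-neighbor flow averaging.
    Stops after ``n_iter`` sweeps or when the mean update falls below
    ``tol``.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise InvalidInputError("frames must be two same-shape 2-D arrays")
    if alpha <= 0:
        raise InvalidParameterError("alpha must be positive")

    conv = lambda img, k: ndimage.correlate(img, k, mode="nearest", origin=(0, 0))
    ix = conv(a, _GRAD_X) + conv(b, _GRAD_X)
    iy = conv(a, _GRAD_Y) + conv(b, _GRAD_Y)
    it = conv(b - a, 0.25 * np.ones((2, 2)))

    u = np.zeros_like(a)
    v = np.zeros_like(a)
    denom = alpha + ix**2 + iy**2
    for _ in range(n_iter):
        ubar = conv(u, _AVG_KERNEL)
        vbar = conv(v, _AVG_KERNEL)
        coef = (ix * ubar + iy * vbar + it) / denom
        un = ubar - ix * coef
        vn = vbar - iy * coef
        delta = float(np.mean(np.abs(un - u) + np.abs(vn - v)))
        u, v = un, vn
        if delta < tol:
            break
    return VelocityField(u=u, v=v)


def hs_energy(field: VelocityField, frame_a, frame_b, alpha: float = 100.0) -> float:
    """Horn-Schunck energy functional (data term + alpha * smoothness)."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    conv = lambda img, k: ndimage.correlate(img, k, mode="nearest", origin=(0, 0))
    ix = conv(a, _GRAD_X) + conv(b, _GRAD_X)
    iy = conv(a, _GRAD_Y) + conv(b, _GRAD_Y)
    it = conv(b - a, 0.25 * np.ones((2, 2)))
    data = (ix * field.u + iy * field.v + it) ** 2
    gu = np.gradient(field.u)
    gv = np.gradient(field.v)
    smooth = sum((g**2).sum() for g in gu + gv)
    return float(data.sum() + alpha * smooth)


def compute_flow_series(
    series: DCESeries,
    alpha: float = 100.0,
    n_iter: int = 100,
    tol: float = 1e-4,
    rescale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice HS flow for every consecutive frame pair.

    ``rescale`` maps the series onto a 0-255 intensity range first; the
    conventional smoothness weight (100) is calibrated against integer-image
    gradient magnitudes, and flow itself is scale-dependent through the
    data/smoothness balance.  Returns (u, v) of shape
    (n_frames - 1, nx, ny, nz) in voxels/frame.
    """
    nx, ny, nz, nt = series.data.shape
    if nt < 2:
        raise InvalidInputError("need at least 2 frames")
    data = series.data
    if rescale:
        lo, hi = float(data.min()), float(data.max())
        data = (data - lo) * (255.0 / (hi - lo)) if hi > lo else data - lo
    u = np.zeros((nt - 1, nx, ny, nz))
    v = np.zeros((nt - 1, nx, ny, nz))
    for z in range(nz):
        for f in range(nt - 1):
            fld = horn_schunck(
                data[:, :, z, f], data[:, :, z, f + 1], alpha, n_iter, tol
            )
            u[f, :, :, z] = fld.u
            v[f, :, :, z] = fld.v
    return u, v


def velocity_traces(
    flow: tuple[np.ndarray, np.ndarray],
    assignments: dict[int, ChamberAssignment],
    label_map: SegmentationLabelMap,
    frame_interval: float,
) -> list[MotionTrace]:
    """Mean velocity magnitude per frame pair for whole/low/high regions."""
    u, v = flow
    speed = np.hypot(u, v)  # (n_pairs, nx, ny, nz)
    n_pairs = speed.shape[0]
    time_s = (np.arange(n_pairs) + 0.5) * frame_interval
    traces: list[MotionTrace] = []
    for pid in label_map.placenta_labels:
        a = assignments[pid]
        regions = {
            "whole": label_map.mask(pid),
            "low": a.low_mask,
            "high": a.high_mask,
        }
        for name, mask in regions.items():
            if not mask.any():
                warnings.warn(f"placenta {pid}: region {name!r} empty, trace omitted")
                continue
            traces.append(
                MotionTrace(
                    placenta_id=pid,
                    region=name,
                    time_s=time_s,
                    mean_speed=speed[:, mask].mean(axis=1),
                )
            )
    return traces


def welch_psd(
    trace: np.ndarray,
    fs: float,
    segment_length: int | None = None,
    overlap_fraction: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch-averaged periodogram (Hamming window), one-sided up to fs/2.

    Default segment length is floor(n/4) rounded down to even, so the
    one-sided axis ends exactly at the Nyquist frequency fs/2; the degenerate
    single full-length segment reproduces the raw periodogram.
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if segment_length is None:
        segment_length = max(4, n // 4)
        if segment_length % 2 == 1:
            segment_length -= 1
    if segment_length > n:
        raise InvalidParameterError(
            f"segment_length {segment_length} exceeds trace length {n}"
        )
    noverlap = int(segment_length * overlap_fraction)
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=segment_length,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    return freqs, psd


def spectrogram_stft(
    trace: np.ndarray,
    fs: float,
    window_length: int = 15,
    overlap_fraction: float = 0.5,
    nfft_factor: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude-squared short-time Fourier transform of one trace.

    Bartlett window of ``window_length`` samples, 50% overlap, transform
    zero-padded to ``nfft_factor`` times the trace length.  Returns
    (freqs_hz, segment_times_s, power) with power of shape
    (n_freqs, n_segments).
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < window_length:
        raise InvalidInputError(
            f"trace length {n} shorter than the {window_length}-sample window"
        )
    win = np.bartlett(window_length)
    noverlap = int(window_length * overlap_fraction)
    step = window_length - noverlap
    starts = np.arange(0, n - window_length + 1, step)
    nfft = nfft_factor * n
    cols = [np.abs(rfft(x[s : s + window_length] * win, n=nfft)) ** 2 for s in starts]
    power = np.stack(cols, axis=1)
    freqs = rfftfreq(nfft, d=1.0 / fs)
    times = (starts + window_length / 2.0) / fs
    return freqs, times, power


def _highpass(data: np.ndarray, window: int) -> np.ndarray:
    """Remove the slow enhancement trend: subtract a temporal moving average."""
    trend = ndimage.uniform_filter1d(data, size=window, axis=-1, mode="nearest")
    return data - trend


def subband_relative_power_map(
    series: DCESeries,
    band_hz: tuple[float, float] = (0.008, 0.012),
    detrend: str = "highpass",
    highpass_window: int = 9,
) -> np.ndarray:
    """Per-voxel relative spectral power inside ``band_hz``.

    Each voxel's intensity time course is detrended (``"highpass"``:
    subtract a ``highpass_window``-frame moving average, suppressing the
    contrast-uptake ramp; ``"mean"``: remove the mean only), its raw
    periodogram computed, and the band power divided by total power.  Voxels
    with zero total power map to 0; values lie in [0, 1] and are invariant
    to per-voxel affine intensity rescaling.
    """
    if detrend not in ("highpass", "mean"):
        raise InvalidParameterError(f"unknown detrend mode {detrend!r}")
    data = series.data
    if detrend == "highpass":
        x = _highpass(data, highpass_window)
    else:
        x = data - data.mean(axis=-1, keepdims=True)
    spec = np.abs(rfft(x, axis=-1)) ** 2
    freqs = rfftfreq(series.meta.n_frames, d=series.meta.frame_interval)
    band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    total = spec.sum(axis=-1)
    band_power = spec[..., band].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(total > 0, band_power / np.where(total > 0, total, 1.0), 0.0)
    return rel


def summarize_subband(
    subband_map: np.ndarray,
    assignments: dict[int, ChamberAssignment],
    label_map: SegmentationLabelMap,
) -> pd.DataFrame:
    """Mean relative band power per placenta and chamber."""
    rows = []
    for pid in label_map.placenta_labels:
        a = assignments[pid]
        for name, mask in (
            ("whole", label_map.mask(pid)),
            ("low", a.low_mask),
            ("high", a.high_mask),
        ):
            if not mask.any():
                continue
            rows.append(
                {
                    "placenta": pid,
                    "chamber": name,
                    "mean_relative_power": float(subband_map[mask].mean()),
                }
            )
    return pd.DataFrame(rows)


def classify_phasic(
    subband_summary: pd.DataFrame, threshold: float = 0.2
) -> dict[int, bool]:
    """Flag a placenta phasic when its best chamber's mean relative power in
    the contraction band exceeds ``threshold``."""
    chambers_only = subband_summary[subband_summary["chamber"].isin(["low", "high"])]
    out: dict[int, bool] = {}
    for pid, grp in chambers_only.groupby("placenta"):
        out[int(pid)] = bool(grp["mean_relative_power"].max() > threshold)
    return out
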