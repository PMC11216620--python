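"""AIF extraction and steepest-slope perfusion mapping.

Under the one-compartment wash-in model with no venous washout,
dC_T/dt = (F/V_T) C_A(t), so the maximal tissue uptake rate divided by the
AIF peak gives the perfusion F/V_T.  Both quantities are measured here on
baseline-subtracted MR signal (linear signal-concentration surrogate): the
slope map is the per-voxel maximum forward difference of the preprocessed
series divided by the frame interval (clamped at zero — washout is outside
the model), and the AIF is the mean enhancement time course over a
renal-hilum ROI.  The ratio, times 6000, is reported in mL/min/100 mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateAIFError, InvalidInputError
from .io_preprocess import DCESeries, SegmentationLabelMap, check_grids

__all__ = [
    "AIFTrace",
    "SteepestSlopeMap",
    "PerfusionMap",
    "extract_aif",
    "steepest_slope_map",
    "perfusion_map",
]

#: mL/min/100 mL per s^-1 (100 mL x 60 s/min)
SECONDS_TO_ML_MIN_100ML = 6000.0


@dataclass
class AIFTrace:
    """Baseline-subtracted enhancement time course of the arterial ROI."""

    time_s: np.ndarray
    enhancement: np.ndarray  # signal units
    peak_value: float
    peak_index: int
    steepest_slope: float  # signal units / s


@dataclass
class SteepestSlopeMap:
    """Per-voxel maximum uptake rate (signal units / s) and its frame."""

    slope: np.ndarray
    argmax_frame: np.ndarray
    frame_interval: float


@dataclass
class PerfusionMap:
    """Voxelwise F/V_T in mL/min/100 mL."""

    f_over_vt: np.ndarray
    aif_peak: float
    provenance: dict = field(default_factory=dict)


def extract_aif(series: DCESeries, label_map: SegmentationLabelMap) -> AIFTrace:
    """Mean ROI enhancement minus the pre-injection baseline.

    Raises ``DegenerateAIFError`` when the ROI shows no positive enhancement
    (e.g. a constant series).
    """
    check_grids(series, label_map)
    aif_label = label_map.aif_label
    if aif_label is None:
        raise InvalidInputError("label map declares no AIF ROI")
    mask = label_map.mask(aif_label)
    if not mask.any():
        raise InvalidInputError("AIF ROI is empty")
    trace = series.data[mask].mean(axis=0)
    inj = series.meta.injection_frame
    enhancement = trace - trace[:inj].mean()
    peak_index = int(np.argmax(enhancement))
    peak_value = float(enhancement[peak_index])
    if peak_value <= 0:
        raise DegenerateAIFError("AIF shows no positive enhancement")
    dt = series.meta.frame_interval
    steepest = float(np.diff(enhancement).max() / dt)
    return AIFTrace(
        time_s=series.meta.time_s,
        enhancement=enhancement,
        peak_value=peak_value,
        peak_index=peak_index,
        steepest_slope=steepest,
    )


def steepest_slope_map(
    series: DCESeries,
    baseline_frames: int | None = None,
    method: str = "forward",
    savgol_window: int = 5,
) -> SteepestSlopeMap:
    """Maximum uptake rate per voxel.

    ``method="forward"`` (default) is the plain forward first difference,
    faithful to reading the steepest slope off the signal; ``"savgol"``
    substitutes a Savitzky-Golay first derivative (quadratic,
    ``savgol_window`` frames) for noise robustness.  ``baseline_frames``
    (default: all pre-injection frames) only shifts the curves and is kept
    for provenance; differences are unaffected.  Negative maxima are clamped
    to zero.
    """
    if series.meta.n_frames < 2:
        raise InvalidInputError("need at least 2 frames")
    nb = series.meta.injection_frame if baseline_frames is None else baseline_frames
    if not (1 <= nb <= series.meta.n_frames):
        raise InvalidInputError(f"baseline_frames {nb} out of range")
    data = series.data
    baseline = data[..., :nb].mean(axis=-1)
    enh = data - baseline[..., None]
    if method == "forward":
        diffs = np.diff(enh, axis=-1) / series.meta.frame_interval
    elif method == "savgol":
        from scipy.signal import savgol_filter

        diffs = savgol_filter(
            enh, savgol_window, polyorder=2, deriv=1,
            delta=series.meta.frame_interval, axis=-1, mode="nearest",
        )[..., 1:]
    else:
        raise InvalidInputError(f"unknown derivative method {method!r}")
    slope = diffs.max(axis=-1)
    argmax = diffs.argmax(axis=-1).astype(np.int32)
    return SteepestSlopeMap(
        slope=np.maximum(slope, 0.0),
        argmax_frame=argmax,
        frame_interval=series.meta.frame_interval,
    )


def perfusion_map(ss: SteepestSlopeMap, aif: AIFTrace) -> PerfusionMap:
    """F/V_T = 6000 x slope / AIF peak, in mL/min/100 mL.

    The signal scale cancels between numerator and denominator, so the map is
    invariant to global multiplicative rescaling of the series.
    """
    if aif.peak_value <= 0:
        raise DegenerateAIFError("AIF peak must be positive")
    f = SECONDS_TO_ML_MIN_100ML * ss.slope / aif.peak_value
    return PerfusionMap(
        f_over_vt=f,
        aif_peak=aif.peak_value,
        provenance={"aif_peak_index": aif.peak_index},
    )
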