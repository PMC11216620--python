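"""Physiological percentile thresholding into perfusion chambers.

Stereological volumetry of the mouse placenta puts the labyrinth zone (the
high-perfusion exchange compartment) at ~45% of placental volume at E14.5
and ~55% at E17.5.  Imposing those volume fractions on each placenta's own
perfusion distribution yields an automatic chamber split: the threshold is
the 55th percentile of that placenta's perfusion values at E14.5 and the
45th percentile at E17.5; voxels strictly below it form the Low Perfusion
Chamber (decidua + junctional zone surrogate), the rest the High Perfusion
Chamber (labyrinth surrogate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .io_preprocess import SegmentationLabelMap
from .perfusion import PerfusionMap

__all__ = [
    "PERCENTILE_BY_AGE",
    "ChamberAssignment",
    "physiological_threshold",
    "assign_chambers",
    "chamber_summaries",
]

PERCENTILE_BY_AGE: dict[str, float] = {"E14.5": 55.0, "E17.5": 45.0}


@dataclass
class ChamberAssignment:
    """Low/high chamber membership for one placenta.

    ``low_mask``/``high_mask`` index the same array the input values came
    from (1-D over the placenta's voxels, or volumetric when produced by
    :func:`assign_chambers`).
    """

    placenta_id: int
    threshold_value: float
    low_mask: np.ndarray
    high_mask: np.ndarray
    low_fraction: float
    high_fraction: float
    gestational_age: str


def physiological_threshold(
    perfusion_values: np.ndarray, age: str, placenta_id: int = 0
) -> ChamberAssignment:
    """Split one placenta's perfusion values at the age-specific percentile.

    The percentile uses linear interpolation of the empirical CDF.  Ties at
    the threshold go to the high chamber ("below" is strict); a constant
    placenta therefore comes out all-high, with a warning.
    """
    if age not in PERCENTILE_BY_AGE:
        raise InvalidParameterError(
            f"unknown gestational age {age!r}; expected one of {sorted(PERCENTILE_BY_AGE)}"
        )
    values = np.asarray(perfusion_values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("empty voxel set")
    thr = float(np.percentile(values, PERCENTILE_BY_AGE[age]))
    low = values < thr
    high = ~low
    if not low.any():
        warnings.warn(
            f"placenta {placenta_id}: no voxels below threshold "
            f"(constant or near-constant perfusion); low chamber empty"
        )
    return ChamberAssignment(
        placenta_id=placenta_id,
        threshold_value=thr,
        low_mask=low,
        high_mask=high,
        low_fraction=float(low.mean()),
        high_fraction=float(high.mean()),
        gestational_age=age,
    )


def assign_chambers(
    perfusion: PerfusionMap,
    label_map: SegmentationLabelMap,
    age: str,
    pooled: bool = False,
) -> dict[int, ChamberAssignment]:
    """Per-placenta thresholding over a whole litter; masks are volumetric.

    ``pooled=True`` computes one threshold from the litter's pooled perfusion
    values and applies it to every placenta (so per-placenta chamber
    fractions then vary around the nominal percentile).
    """
    if age not in PERCENTILE_BY_AGE:
        raise InvalidParameterError(f"unknown gestational age {age!r}")
    pooled_thr: float | None = None
    if pooled:
        placental = np.isin(label_map.labels, label_map.placenta_labels)
        if not placental.any():
            raise InvalidInputError("label map contains no placental voxels")
        pooled_thr = float(
            np.percentile(perfusion.f_over_vt[placental], PERCENTILE_BY_AGE[age])
        )
    out: dict[int, ChamberAssignment] = {}
    for pid in label_map.placenta_labels:
        pmask = label_map.mask(pid)
        if not pmask.any():
            raise InvalidInputError(f"placenta label {pid} has no voxels")
        vals = perfusion.f_over_vt[pmask]
        if pooled_thr is None:
            flat = physiological_threshold(vals, age, placenta_id=pid)
        else:
            low_flat = vals < pooled_thr
            flat = ChamberAssignment(
                placenta_id=pid,
                threshold_value=pooled_thr,
                low_mask=low_flat,
                high_mask=~low_flat,
                low_fraction=float(low_flat.mean()),
                high_fraction=float((~low_flat).mean()),
                gestational_age=age,
            )
        low = np.zeros_like(pmask)
        high = np.zeros_like(pmask)
        low[pmask] = flat.low_mask
        high[pmask] = flat.high_mask
        out[pid] = ChamberAssignment(
            placenta_id=pid,
            threshold_value=flat.threshold_value,
            low_mask=low,
            high_mask=high,
            low_fraction=flat.low_fraction,
            high_fraction=flat.high_fraction,
            gestational_age=age,
        )
    return out


def chamber_summaries(
    perfusion: PerfusionMap,
    assignments: dict[int, ChamberAssignment],
    label_map: SegmentationLabelMap,
    voxel_volume_ml: float,
) -> pd.DataFrame:
    """Per-placenta, per-chamber perfusion summary table.

    One row per (placenta, chamber) with chamber in {low, high, whole}:
    mean perfusion, voxel count, volume in mL, and the HPC/LPC volume ratio.
    """
    missing = [pid for pid in label_map.placenta_labels if pid not in assignments]
    if missing:
        raise InvalidInputError(f"no chamber assignment for placenta labels {missing}")
    rows = []
    fmap = perfusion.f_over_vt
    for pid in label_map.placenta_labels:
        a = assignments[pid]
        pmask = label_map.mask(pid)
        n_low, n_high = int(a.low_mask.sum()), int(a.high_mask.sum())
        ratio = n_high / n_low if n_low > 0 else np.inf
        for chamber, mask in (("low", a.low_mask), ("high", a.high_mask), ("whole", pmask)):
            n = int(mask.sum())
            rows.append(
                {
                    "placenta": pid,
                    "chamber": chamber,
                    "mean_perfusion": float(fmap[mask].mean()) if n else np.nan,
                    "n_voxels": n,
                    "volume_ml": n * voxel_volume_ml,
                    "hpc_lpc_volume_ratio": ratio,
                    "threshold": a.threshold_value,
                    "gestational_age": a.gestational_age,
                }
            )
    return pd.DataFrame(rows)
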