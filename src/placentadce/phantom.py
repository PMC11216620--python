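"""Digital phantom emulating a DCE-MRI study of a pregnant mouse litter.

The phantom builds a litter of ellipsoidal placentas on a voxel grid, splits
each into a low- and a high-perfusion chamber by a plane perpendicular to the
long axis, drives tissue contrast-agent uptake with a gamma-variate arterial
input function through the one-compartment no-washout wash-in model, converts
concentration to spoiled gradient-echo signal through the Ernst relation with
a linear relaxivity, and optionally displaces the high-perfusion chamber with
subvoxel sinusoidal in-plane motion in the contraction band (around 10, 15
and 25 mHz).  Variable-flip-angle stacks are synthesized pre- and
post-contrast for R1 mapping.  Ground truth (labels, chambers, perfusion, R1,
motion, AIF) is returned alongside so every downstream stage can be checked
quantitatively.

Units: perfusion F/V_T in mL/min/100 mL (divide by 6000 for s^-1), R1 in Hz,
TR/TE in ms, time in s, concentration in arbitrary-consistent units fixed by
the AIF peak amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import ndimage
from scipy.integrate import cumulative_trapezoid

from .errors import InvalidInputError, InvalidSpecError
from .io_preprocess import AcquisitionMeta, DCESeries, SegmentationLabelMap
from .relaxometry import VFAStack, ernst_signal

__all__ = [
    "AIFParams",
    "MotionSpec",
    "PhantomSpec",
    "PlacentaMotion",
    "PhantomTruth",
    "simulate_aif",
    "simulate_tissue_uptake",
    "synthesize_dce",
    "TRUE_PERFUSION",
    "CHAMBER_FRACTIONS",
    "MOTION_PREVALENCE",
]

# Study conditions: chamber volume fractions follow the stereology-derived
# 55/45 split that flips between mid and late gestation; perfusion defaults
# place the late-gestation chambers ~15.6 (low) and ~24.97 (high)
# mL/min/100 mL above the mid-gestation ones.
CHAMBER_FRACTIONS: dict[str, dict[str, float]] = {
    "E14.5": {"low": 0.55, "high": 0.45},
    "E17.5": {"low": 0.45, "high": 0.55},
}
TRUE_PERFUSION: dict[str, dict[str, float]] = {
    "E14.5": {"low": 30.0, "high": 55.0},
    "E17.5": {"low": 45.6, "high": 79.97},
}
MOTION_PREVALENCE: dict[str, float] = {"E14.5": 0.111, "E17.5": 0.821}

DCE_TR_MS = 101.493
DCE_TE_MS = 1.872
DCE_FLIP_DEG = 75.0
VFA_TR_MS = 114.88
VFA_FLIP_DEG = (75.0, 55.0, 30.0, 20.0, 10.0)


class AIFParams(BaseModel):
    """Gamma-variate bolus shape C_A(t) = A ((t-t0)/(a b))^a exp(a - (t-t0)/b).

    ``delay_s`` is the injection time t0, ``shape`` the rise exponent a,
    ``tau_s`` the decay constant b; the peak value is ``peak_amplitude`` and
    occurs at t0 + a*b.
    """

    delay_s: float = 63.0
    shape: float = 2.0
    tau_s: float = 60.0
    peak_amplitude: float = 0.15

    @field_validator("shape", "tau_s")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @field_validator("peak_amplitude")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be non-negative")
        return v


class MotionSpec(BaseModel):
    """Programmed phasic in-plane motion of the high-perfusion chamber."""

    frequencies_mhz: tuple[float, ...] = (10.0, 15.0, 25.0)
    amplitudes_vox: tuple[float, ...] = (0.5, 0.25, 0.25)
    prevalence: float | None = None  # None -> age default
    enabled: bool = True

    @model_validator(mode="after")
    def _lengths(self) -> "MotionSpec":
        if len(self.frequencies_mhz) != len(self.amplitudes_vox):
            raise ValueError("frequencies and amplitudes must have equal length")
        if self.prevalence is not None and not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")
        return self


class PhantomSpec(BaseModel):
    """Full specification of one synthetic imaging session."""

    n_placentas: int = Field(default=8, ge=1)
    grid_shape: tuple[int, int, int] = (64, 64, 8)
    voxel_size: tuple[float, float, float] = (0.156, 0.156, 0.85)  # mm
    n_frames: int = Field(default=50, ge=2)
    frame_interval: float = 18.0  # s
    injection_frame: int = 4  # 0-based first post-injection frame
    gestational_age: str = "E17.5"
    chamber_fractions: dict[str, float] | None = None  # None -> age default
    true_perfusion: dict[str, float] | None = None  # mL/min/100 mL
    aif_params: AIFParams = AIFParams()
    r1_baseline: float = 0.6  # Hz
    relaxivity: float = 3.3  # Hz per concentration unit
    noise_sigma: float = 0.02  # fraction of baseline placental signal
    rician_noise: bool = False
    motion: MotionSpec = MotionSpec()
    texture_amplitude: float = 0.12  # relative M0 heterogeneity in placentas
    background_m0: float = 0.35
    seed: int = 0

    @field_validator("gestational_age")
    @classmethod
    def _age(cls, v: str) -> str:
        if v not in CHAMBER_FRACTIONS:
            raise ValueError(f"unknown gestational age {v!r}")
        return v

    @field_validator("frame_interval")
    @classmethod
    def _dt(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("frame_interval must be positive")
        return v

    @model_validator(mode="after")
    def _consistency(self) -> "PhantomSpec":
        if not (1 <= self.injection_frame < self.n_frames):
            raise ValueError("injection_frame outside [1, n_frames)")
        fr = self.chamber_fractions
        if fr is not None:
            if set(fr) != {"low", "high"} or abs(fr["low"] + fr["high"] - 1.0) > 1e-9:
                raise ValueError("chamber_fractions must have low+high = 1")
        tp = self.true_perfusion
        if tp is not None and any(v < 0 for v in tp.values()):
            raise ValueError("perfusion values must be >= 0")
        return self

    @property
    def fractions(self) -> dict[str, float]:
        return self.chamber_fractions or CHAMBER_FRACTIONS[self.gestational_age]

    @property
    def perfusion(self) -> dict[str, float]:
        return self.true_perfusion or TRUE_PERFUSION[self.gestational_age]

    @property
    def prevalence(self) -> float:
        if self.motion.prevalence is not None:
            return self.motion.prevalence
        return MOTION_PREVALENCE[self.gestational_age]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class PlacentaMotion:
    placenta_id: int
    moving: bool
    frequencies_mhz: tuple[float, ...]
    amplitudes_vox: tuple[float, ...]
    direction: tuple[float, float]  # in-plane unit vector


@dataclass
class PhantomTruth:
    """Ground truth accompanying one synthesized session."""

    label_map: SegmentationLabelMap
    chamber_map: np.ndarray  # 0 outside placentas, 1 low, 2 high
    true_f_over_vt: dict[str, float]  # mL/min/100 mL per chamber
    true_r1_pre: np.ndarray  # Hz
    true_r1_post: np.ndarray  # Hz
    true_motion: list[PlacentaMotion]
    aif_curve: np.ndarray  # concentration at frame times
    time_s: np.ndarray
    spec: PhantomSpec

    @property
    def moving_fraction(self) -> float:
        flags = [m.moving for m in self.true_motion]
        return float(np.mean(flags)) if flags else 0.0


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


def simulate_aif(aif_params: AIFParams, time_grid: np.ndarray) -> np.ndarray:
    """Evaluate the gamma-variate arterial input function on ``time_grid``.

    Zero before the injection delay, a single interior maximum of height
    ``peak_amplitude`` at ``delay_s + shape * tau_s``, then washout.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise InvalidInputError("time_grid must be 1-D and strictly increasing")
    if not (t[0] <= aif_params.delay_s < t[-1]):
        raise InvalidInputError("injection time lies outside the time grid")
    dt = t - aif_params.delay_s
    a, b = aif_params.shape, aif_params.tau_s
    out = np.zeros_like(t)
    pos = dt > 0
    x = dt[pos] / (a * b)
    out[pos] = aif_params.peak_amplitude * np.power(x, a) * np.exp(a - dt[pos] / b)
    return out


def simulate_tissue_uptake(
    aif_curve: np.ndarray, f_over_vt: float, time_grid: np.ndarray
) -> np.ndarray:
    """Wash-in tissue concentration C_T(t) = (F/V_T) * integral of C_A.

    ``f_over_vt`` is in mL/min/100 mL and converted to s^-1 by /6000; the
    integral uses the trapezoid rule on the frame grid.  With no venous
    washout the curve is non-decreasing and its steepest slope equals
    (F/V_T) * max(C_A).
    """
    if f_over_vt < 0:
        raise InvalidInputError("f_over_vt must be >= 0")
    t = np.asarray(time_grid, dtype=float)
    ca = np.asarray(aif_curve, dtype=float)
    if ca.shape != t.shape:
        raise InvalidInputError("aif_curve and time_grid must have equal length")
    integral = cumulative_trapezoid(ca, t, initial=0.0)
    return (f_over_vt / 6000.0) * integral


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _litter_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Place K ellipsoidal placentas on a ring plus a central AIF sphere.

    Returns (labels, chamber_map, axes_long list, directions list).
    """
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    chamber = np.zeros(spec.grid_shape, dtype=np.int8)
    xs, ys, zs = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    k = spec.n_placentas
    ring_r = 0.35 * min(nx, ny)
    # semi-axes grow between mid and late gestation (placental growth); the
    # z semi-axis exceeds half the default slab so placentas are cut by the
    # imaging slab, as in an abdominal acquisition with thick slices
    if spec.gestational_age == "E14.5":
        base_axes = np.array([8.0, 5.5, 4.5])
    else:
        base_axes = np.array([9.0, 6.5, 5.0])
    # scale with the grid so small test grids keep the same proportions
    base_axes[:2] *= min(nx, ny) / 64.0
    base_axes[2] *= nz / 8.0
    directions: list[tuple[float, float]] = []
    cz = (nz - 1) / 2.0
    for pid in range(1, k + 1):
        theta = 2 * np.pi * (pid - 1) / k + rng.uniform(-0.05, 0.05)
        cx = nx / 2.0 + ring_r * np.cos(theta)
        cy = ny / 2.0 + ring_r * np.sin(theta)
        axes = base_axes * rng.uniform(0.95, 1.05, size=3)
        e = np.array([np.cos(theta), np.sin(theta)])  # long axis, radial
        p = np.array([-e[1], e[0]])
        dx, dy, dz = xs - cx, ys - cy, zs - cz
        s_long = dx * e[0] + dy * e[1]
        s_perp = dx * p[0] + dy * p[1]
        inside = (
            (s_long / axes[0]) ** 2 + (s_perp / axes[1]) ** 2 + (dz / axes[2]) ** 2
        ) <= 1.0
        inside &= labels == 0
        if not inside.any():
            raise InvalidSpecError(f"placenta {pid} has no voxels on this grid")
        labels[inside] = pid
        # chamber divide: plane perpendicular to the long axis, low chamber
        # on the maternal (outer) side, at the prescribed volume fraction
        s_vals = s_long[inside]
        thr = np.quantile(s_vals, 1.0 - spec.fractions["low"])
        low = inside & (s_long >= thr)
        chamber[inside] = 2
        chamber[low] = 1
        directions.append((float(p[0]), float(p[1])))
    # AIF region: small sphere at the ring center ("renal hilum")
    aif_label = k + 1
    dist2 = (xs - nx / 2.0) ** 2 + (ys - ny / 2.0) ** 2 + (zs - cz) ** 2
    aif = (dist2 <= 2.2**2) & (labels == 0)
    if not aif.any():
        raise InvalidSpecError("AIF region empty on this grid")
    labels[aif] = aif_label
    roles = {pid: "placenta" for pid in range(1, k + 1)}
    roles[aif_label] = "aif"
    return SegmentationLabelMap(labels=labels, roles=roles), chamber, directions


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------


def _signal_from_r1(m0: np.ndarray, r1_hz: np.ndarray, flip_deg: float, tr_ms: float):
    t1_ms = 1000.0 / np.maximum(r1_hz, 1e-12)
    return ernst_signal(m0, flip_deg, tr_ms, t1_ms)


def synthesize_dce(
    spec: PhantomSpec,
) -> tuple[DCESeries, VFAStack, VFAStack, PhantomTruth]:
    """Generate a full synthetic session: DCE series, pre/post VFA stacks, truth.

    Deterministic given ``spec.seed``: geometry, M0 texture, the choice of
    moving placentas and the noise draws all derive from one generator.
    Motion is applied to the noiseless signal; noise is added last.
    """
    rng = np.random.default_rng(spec.seed)
    label_map, chamber, directions = _litter_geometry(spec, rng)
    labels = label_map.labels
    t = spec.time_s

    aif_curve = simulate_aif(spec.aif_params, t)
    c_low = simulate_tissue_uptake(aif_curve, spec.perfusion["low"], t)
    c_high = simulate_tissue_uptake(aif_curve, spec.perfusion["high"], t)

    # M0 with smooth intra-placental texture (biological heterogeneity)
    m0 = np.full(spec.grid_shape, spec.background_m0)
    placental = (chamber > 0)
    texture = ndimage.gaussian_filter(rng.standard_normal(spec.grid_shape), sigma=1.5)
    texture = texture / max(texture.std(), 1e-12) * spec.texture_amplitude
    m0[placental] = 1.0 + texture[placental]
    aif_mask = labels == (label_map.aif_label or -1)
    m0[aif_mask] = 1.0

    low_mask = chamber == 1
    high_mask = chamber == 2

    # concentration volume per frame -> R1 -> Ernst signal
    conc = np.zeros(spec.grid_shape + (spec.n_frames,))
    conc[low_mask, :] = c_low
    conc[high_mask, :] = c_high
    conc[aif_mask, :] = aif_curve
    r1 = spec.r1_baseline + spec.relaxivity * conc
    signal = _signal_from_r1(m0[..., None], r1, DCE_FLIP_DEG, DCE_TR_MS)

    # phasic motion: sinusoidal in-plane translation of the high chamber
    k = spec.n_placentas
    n_moving = int(round(spec.prevalence * k)) if spec.motion.enabled else 0
    moving_ids = rng.permutation(np.arange(1, k + 1))[:n_moving]
    true_motion: list[PlacentaMotion] = []
    if spec.motion.enabled and n_moving > 0:
        amp_total = float(np.sum(spec.motion.amplitudes_vox))
        if amp_total > 3.0:
            raise InvalidSpecError(
                f"total motion amplitude {amp_total} voxels exceeds the chamber scale"
            )
        freqs_hz = np.asarray(spec.motion.frequencies_mhz) / 1000.0
        amps = np.asarray(spec.motion.amplitudes_vox)
        for pid in moving_ids:
            mdir = np.asarray(directions[pid - 1])
            sel = (labels == pid) & high_mask
            ix, iy, iz = np.nonzero(sel)
            disp = (amps[None, :] * np.sin(2 * np.pi * freqs_hz[None, :] * t[:, None])).sum(
                axis=1
            )
            for fi in range(spec.n_frames):
                d = disp[fi]
                if d == 0.0:
                    continue
                sx = ix - mdir[0] * d
                sy = iy - mdir[1] * d
                for z in np.unique(iz):
                    zsel = iz == z
                    signal[ix[zsel], iy[zsel], z, fi] = ndimage.map_coordinates(
                        signal[:, :, z, fi],
                        np.vstack([sx[zsel], sy[zsel]]),
                        order=1,
                        mode="nearest",
                    )
    for pid in range(1, k + 1):
        moving = pid in moving_ids
        true_motion.append(
            PlacentaMotion(
                placenta_id=pid,
                moving=moving,
                frequencies_mhz=spec.motion.frequencies_mhz if moving else (),
                amplitudes_vox=spec.motion.amplitudes_vox if moving else (),
                direction=directions[pid - 1],
            )
        )

    # reference baseline signal for the noise scale
    s0_ref = float(ernst_signal(1.0, DCE_FLIP_DEG, DCE_TR_MS, 1000.0 / spec.r1_baseline))
    sigma = spec.noise_sigma * s0_ref

    def _add_noise(arr: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return arr
        if spec.rician_noise:
            n1 = rng.normal(0.0, sigma, arr.shape)
            n2 = rng.normal(0.0, sigma, arr.shape)
            return np.sqrt((arr + n1) ** 2 + n2**2)
        return arr + rng.normal(0.0, sigma, arr.shape)

    signal = _add_noise(signal)

    meta = AcquisitionMeta(
        frame_interval=spec.frame_interval,
        injection_frame=spec.injection_frame,
        tr_ms=DCE_TR_MS,
        te_ms=DCE_TE_MS,
        flip_angle_deg=DCE_FLIP_DEG,
        voxel_size=spec.voxel_size,
        n_slices=spec.grid_shape[2],
        n_frames=spec.n_frames,
    )
    series = DCESeries(data=signal, meta=meta)

    # variable-flip-angle stacks pre (baseline R1) and post (end-of-study R1)
    r1_pre = np.full(spec.grid_shape, spec.r1_baseline)
    r1_post = spec.r1_baseline + spec.relaxivity * conc[..., -1]
    vfa_pre_imgs = np.stack(
        [_add_noise(_signal_from_r1(m0, r1_pre, fa, VFA_TR_MS)) for fa in VFA_FLIP_DEG]
    )
    vfa_post_imgs = np.stack(
        [_add_noise(_signal_from_r1(m0, r1_post, fa, VFA_TR_MS)) for fa in VFA_FLIP_DEG]
    )
    vfa_pre = VFAStack(images=vfa_pre_imgs, flip_angles_deg=VFA_FLIP_DEG, tr_ms=VFA_TR_MS)
    vfa_post = VFAStack(images=vfa_post_imgs, flip_angles_deg=VFA_FLIP_DEG, tr_ms=VFA_TR_MS)

    truth = PhantomTruth(
        label_map=label_map,
        chamber_map=chamber,
        true_f_over_vt=dict(spec.perfusion),
        true_r1_pre=r1_pre,
        true_r1_post=r1_post,
        true_motion=true_motion,
        aif_curve=aif_curve,
        time_s=t,
        spec=spec,
    )
    if spec.aif_params.peak_amplitude == 0:
        warnings.warn("AIF peak amplitude is zero; the session carries no enhancement")
    return series, vfa_pre, vfa_post, truth


def save_phantom(
    series: DCESeries,
    vfa_pre: VFAStack,
    vfa_post: VFAStack,
    truth: PhantomTruth,
    out_dir,
) -> None:
    """Persist one synthetic session: NIfTI volumes, JSON sidecars, truth CSV."""
    import json
    from pathlib import Path

    import pandas as pd

    from .io_preprocess import save_label_map, save_map, save_series

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vs = truth.spec.voxel_size
    save_series(series, out / "dce.nii.gz", out / "dce.json")
    for name, stack in (("vfa_pre", vfa_pre), ("vfa_post", vfa_post)):
        save_map(np.moveaxis(stack.images, 0, -1), out / f"{name}.nii.gz", vs)
        (out / f"{name}.json").write_text(
            json.dumps({"flip_angles_deg": list(stack.flip_angles_deg), "tr_ms": stack.tr_ms})
        )
    save_label_map(truth.label_map, out / "labels.nii.gz", out / "roles.json", vs)
    save_map(truth.chamber_map.astype(np.int16), out / "chambers.nii.gz", vs)
    save_map(truth.true_r1_pre, out / "true_r1_pre.nii.gz", vs)
    save_map(truth.true_r1_post, out / "true_r1_post.nii.gz", vs)
    pd.DataFrame({"time_s": truth.time_s, "aif_concentration": truth.aif_curve}).to_csv(
        out / "true_aif.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "placenta": m.placenta_id,
                "moving": m.moving,
                "frequencies_mhz": ";".join(map(str, m.frequencies_mhz)),
                "amplitudes_vox": ";".join(map(str, m.amplitudes_vox)),
            }
            for m in truth.true_motion
        ]
    ).to_csv(out / "true_motion.csv", index=False)
    pd.DataFrame([truth.true_f_over_vt]).to_csv(out / "true_perfusion.csv", index=False)
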