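"""Study orchestration: phantom or user data through the full analysis.

A study is a list of imaging sessions (each a litter at one gestational
age).  Per session the pipeline runs: temporal + spatial denoising, AIF
extraction, steepest-slope and perfusion mapping, physiological chamber
thresholding, chamber summaries, VFA R1 fitting pre/post contrast with
apparent Gd uptake, apparent blood volume, Gaussian-mixture perfusion
biomarkers, optical-flow motion traces, sub-band power maps and phasic
classification.  Group statistics use Welch's t-test for two groups and
one-way ANOVA with Tukey-Kramer post-hoc tests otherwise.

All randomness flows from one root seed recorded in the report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy import stats

from . import chambers as ch
from . import io_preprocess as iop
from . import motion_spectral as ms
from . import perfdist as pdist
from . import perfusion as perf
from . import phantom as ph
from . import relaxometry as rx
from .errors import InvalidInputError

__all__ = ["SessionConfig", "StudyConfig", "StudyReport", "run_pipeline", "group_compare"]


class SessionConfig(BaseModel):
    """One imaging session: either a phantom spec or paths to NIfTI inputs."""

    session_id: str
    gestational_age: str = "E17.5"
    # phantom mode: overrides merged into PhantomSpec
    phantom: dict | None = None
    # analyze mode: file inputs (VFA stacks optional; 4-D NIfTI with the
    # flip-angle axis last plus a JSON with flip_angles_deg and tr_ms)
    dce_path: str | None = None
    sidecar_path: str | None = None
    labels_path: str | None = None
    roles_path: str | None = None
    vfa_pre_path: str | None = None
    vfa_post_path: str | None = None
    vfa_meta_path: str | None = None

    def is_phantom(self) -> bool:
        return self.dce_path is None


class StudyConfig(BaseModel):
    """Full study description with all module parameters."""

    sessions: list[SessionConfig]
    seed: int = 0
    out_dir: str | None = None
    resume: bool = False  # reuse cached per-session outputs under out_dir
    time_window: int = 3
    closing_length: int = 3
    flow_alpha: float = 100.0
    flow_iters: int = 100
    subband_hz: tuple[float, float] = (0.008, 0.012)
    phasic_threshold: float = 0.2
    run_motion: bool = True
    run_relaxometry: bool = True
    gmm_seed: int = 0
    gmm_n_init: int = 1
    pooled_threshold: bool = False  # per-litter pooled chamber threshold


@dataclass
class StudyReport:
    """Aggregated study outputs plus provenance."""

    chamber_table: pd.DataFrame
    gmm_table: pd.DataFrame
    aif_table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def report_hash(self) -> str:
        payload = (
            self.chamber_table.to_csv(index=False)
            + self.gmm_table.to_csv(index=False)
            + self.aif_table.to_csv(index=False)
        ).encode()
        return hashlib.sha256(payload).hexdigest()

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.chamber_table.to_csv(out / "chamber_table.csv", index=False)
        self.gmm_table.to_csv(out / "gmm_biomarkers.csv", index=False)
        self.aif_table.to_csv(out / "aif_traces.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def _session_seed(root_seed: int, index: int) -> int:
    return int((root_seed * 1000003 + index * 7919 + 17) % (2**31))


def _load_or_synthesize(cfg: SessionConfig, seed: int):
    if cfg.is_phantom():
        overrides = dict(cfg.phantom or {})
        overrides.setdefault("seed", seed)
        overrides["gestational_age"] = cfg.gestational_age
        spec = ph.PhantomSpec(**overrides)
        series, vfa_pre, vfa_post, truth = ph.synthesize_dce(spec)
        return series, vfa_pre, vfa_post, truth.label_map, truth
    if not all([cfg.dce_path, cfg.sidecar_path, cfg.labels_path, cfg.roles_path]):
        raise InvalidInputError(
            f"session {cfg.session_id}: analyze mode requires dce/sidecar/labels/roles paths"
        )
    series = iop.load_series(cfg.dce_path, cfg.sidecar_path)
    label_map = iop.load_label_map(cfg.labels_path, cfg.roles_path)
    iop.check_grids(series, label_map)
    vfa_pre = vfa_post = None
    if cfg.vfa_pre_path and cfg.vfa_post_path and cfg.vfa_meta_path:
        vmeta = json.loads(Path(cfg.vfa_meta_path).read_text())
        angles = tuple(vmeta["flip_angles_deg"])
        tr = float(vmeta["tr_ms"])
        vfa_pre = rx.VFAStack(
            images=np.moveaxis(iop.load_map(cfg.vfa_pre_path), -1, 0),
            flip_angles_deg=angles, tr_ms=tr,
        )
        vfa_post = rx.VFAStack(
            images=np.moveaxis(iop.load_map(cfg.vfa_post_path), -1, 0),
            flip_angles_deg=angles, tr_ms=tr,
        )
    return series, vfa_pre, vfa_post, label_map, None


def analyze_session(
    series: iop.DCESeries,
    label_map: iop.SegmentationLabelMap,
    age: str,
    config: StudyConfig,
    vfa_pre: rx.VFAStack | None = None,
    vfa_post: rx.VFAStack | None = None,
    session_id: str = "session",
):
    """Run the full single-session analysis; returns a dict of results."""
    denoised = iop.temporal_denoise(
        series, time_window=config.time_window, closing_length=config.closing_length
    )
    # the AIF comes from the temporally-denoised series only: a 3x3x3 spatial
    # median would bleed non-enhancing neighbors into the small hilum ROI
    aif = perf.extract_aif(denoised, label_map)
    clean = denoised.with_data(iop.spatial_median3(denoised.data))
    ss = perf.steepest_slope_map(clean)
    pmap = perf.perfusion_map(ss, aif)
    assignments = ch.assign_chambers(
        pmap, label_map, age, pooled=config.pooled_threshold
    )
    table = ch.chamber_summaries(
        pmap, assignments, label_map, series.meta.voxel_volume_ml
    )
    table.insert(0, "session", session_id)

    # chamber-mean steepest slope and ABV
    slope_means, abvs = [], []
    for _, row in table.iterrows():
        pid, chamber = int(row["placenta"]), row["chamber"]
        a = assignments[pid]
        mask = {"low": a.low_mask, "high": a.high_mask, "whole": label_map.mask(pid)}[chamber]
        vals = pmap.f_over_vt[mask]
        slope_means.append(float(ss.slope[mask].mean()) if mask.any() else np.nan)
        abv, _ = pdist.apparent_blood_volume(vals, series.meta.voxel_volume_ml)
        abvs.append(abv)
    table["mean_steepest_slope"] = slope_means
    table["abv_ml_min"] = abvs

    # relaxometry: dR1 and apparent Gd uptake per chamber
    if config.run_relaxometry and vfa_pre is not None and vfa_post is not None:
        r1_pre = rx.fit_t1_vfa(vfa_pre)
        r1_post = rx.fit_t1_vfa(vfa_post)
        dmap, _ = rx.delta_r1(r1_pre, r1_post)
        agu, mean_dr1 = [], []
        for _, row in table.iterrows():
            pid, chamber = int(row["placenta"]), row["chamber"]
            a = assignments[pid]
            mask = {"low": a.low_mask, "high": a.high_mask, "whole": label_map.mask(pid)}[
                chamber
            ]
            try:
                agu.append(rx.apparent_gd_uptake(dmap, mask))
                vals = dmap[mask]
                mean_dr1.append(float(np.nanmean(vals)))
            except InvalidInputError:
                agu.append(np.nan)
                mean_dr1.append(np.nan)
        table["agu_hz_voxels"] = agu
        table["mean_delta_r1_hz"] = mean_dr1

    # perfusion-distribution biomarkers (pooled over the litter)
    placental = np.isin(label_map.labels, label_map.placenta_labels)
    pooled = pmap.f_over_vt[placental]
    positive = pooled[pooled > 0]
    gmm_row: dict = {"session": session_id, "gestational_age": age}
    if positive.size >= 10:
        params = pdist.fit_gmm_em(
            np.log10(positive), seed=config.gmm_seed, n_init=config.gmm_n_init
        )
        bio = pdist.pdf_biomarkers(params)
        gmm_row.update(
            {
                "pi_high": params.pi,
                "mu_low": bio.mu_low,
                "mu_high": bio.mu_high,
                "sigma_low": bio.sigma_low,
                "sigma_high": bio.sigma_high,
                "peak_low": bio.peak_low,
                "peak_high": bio.peak_high,
                "fwhm_low": bio.fwhm_low,
                "fwhm_high": bio.fwhm_high,
                "auc_low": bio.auc_low,
                "auc_high": bio.auc_high,
                "converged": params.converged,
            }
        )

    # motion
    phasic: dict[int, bool] = {}
    if config.run_motion:
        flow = ms.compute_flow_series(
            clean, alpha=config.flow_alpha, n_iter=config.flow_iters
        )
        traces = ms.velocity_traces(
            flow, assignments, label_map, series.meta.frame_interval
        )
        speed_by_key = {
            (t.placenta_id, t.region): float(t.mean_speed.mean()) for t in traces
        }
        table["mean_speed_vox_per_frame"] = [
            speed_by_key.get((int(r["placenta"]), r["chamber"]), np.nan)
            for _, r in table.iterrows()
        ]
        sub = ms.subband_relative_power_map(clean, band_hz=config.subband_hz)
        summary = ms.summarize_subband(sub, assignments, label_map)
        phasic = ms.classify_phasic(summary, threshold=config.phasic_threshold)
        table["phasic"] = [phasic.get(int(r["placenta"]), False) for _, r in table.iterrows()]

    aif_row = {
        "session": session_id,
        "gestational_age": age,
        "aif_peak": aif.peak_value,
        "aif_peak_index": aif.peak_index,
        "aif_steepest_slope": aif.steepest_slope,
    }
    return {
        "table": table,
        "gmm": gmm_row,
        "aif": aif_row,
        "assignments": assignments,
        "perfusion_map": pmap,
        "phasic": phasic,
    }


def run_pipeline(config: StudyConfig) -> StudyReport:
    """Run every session of the study and aggregate the report.

    Deterministic given ``config.seed``: phantom sessions derive their seeds
    from it, and the analysis itself contains no other randomness beyond the
    seeded mixture-model restarts.
    """
    tables, gmm_rows, aif_rows = [], [], []
    for i, scfg in enumerate(config.sessions):
        cache = (
            Path(config.out_dir) / "sessions" / scfg.session_id
            if config.out_dir
            else None
        )
        if config.resume and cache is not None and (cache / "table.csv").exists():
            tables.append(pd.read_csv(cache / "table.csv", float_precision="round_trip"))
            gmm_rows.append(json.loads((cache / "gmm.json").read_text()))
            aif_rows.append(json.loads((cache / "aif.json").read_text()))
            continue
        seed = _session_seed(config.seed, i)
        try:
            series, vfa_pre, vfa_post, label_map, _truth = _load_or_synthesize(scfg, seed)
            res = analyze_session(
                series,
                label_map,
                scfg.gestational_age,
                config,
                vfa_pre=vfa_pre,
                vfa_post=vfa_post,
                session_id=scfg.session_id,
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline halted in session {scfg.session_id!r}: {exc}"
            ) from exc
        tables.append(res["table"])
        gmm_rows.append(res["gmm"])
        aif_rows.append(res["aif"])
        if cache is not None:
            cache.mkdir(parents=True, exist_ok=True)
            res["table"].to_csv(cache / "table.csv", index=False)
            (cache / "gmm.json").write_text(json.dumps(res["gmm"], default=float))
            (cache / "aif.json").write_text(json.dumps(res["aif"], default=float))
    report = StudyReport(
        chamber_table=pd.concat(tables, ignore_index=True),
        gmm_table=pd.DataFrame(gmm_rows),
        aif_table=pd.DataFrame(aif_rows),
        provenance={
            "seed": config.seed,
            "n_sessions": len(config.sessions),
            "config": json.loads(config.model_dump_json()),
        },
    )
    if config.out_dir:
        report.save(config.out_dir)
    return report


def group_compare(
    table: pd.DataFrame, metric: str, grouping: str = "gestational_age"
) -> pd.DataFrame:
    """Group statistics on one report metric.

    Two groups: Welch's unequal-variance t-test.  More: one-way ANOVA with
    Tukey-Kramer pairwise post-hoc comparisons.  Groups with fewer than two
    observations are skipped with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    for name, grp in table.groupby(grouping):
        vals = np.asarray(grp[metric].dropna(), dtype=float)
        if vals.size < 2:
            warnings.warn(f"group {name!r} has <2 observations; skipped")
            continue
        groups[str(name)] = vals
    names = list(groups)
    if len(names) < 2:
        raise InvalidInputError("need at least two groups with >=2 observations")
    rows = []
    if len(names) == 2:
        t, p = stats.ttest_ind(groups[names[0]], groups[names[1]], equal_var=False)
        rows.append(
            {
                "test": "welch_t",
                "group_a": names[0],
                "group_b": names[1],
                "statistic": float(t),
                "p_value": float(p),
            }
        )
    else:
        f, p = stats.f_oneway(*groups.values())
        rows.append(
            {"test": "anova", "group_a": "all", "group_b": "all", "statistic": float(f), "p_value": float(p)}
        )
        res = stats.tukey_hsd(*groups.values())
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(
                    {
                        "test": "tukey_kramer",
                        "group_a": names[i],
                        "group_b": names[j],
                        "statistic": float(res.statistic[i, j]),
                        "p_value": float(res.pvalue[i, j]),
                    }
                )
    return pd.DataFrame(rows)
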