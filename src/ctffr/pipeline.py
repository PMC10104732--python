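"""End-to-end orchestration: phantom -> segmentation -> reconstruction ->
lumen profile -> reduced-order flow -> FFR.

Each stage is a plain function usable standalone on in-memory objects;
:func:`run_pipeline` chains them, writes every intermediate artifact to
the output directory and records a machine-readable manifest (seed,
config hash, package versions, per-stage log), so a run is a single
reproducible unit.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .config import DEFAULT_CONFIG, config_hash, merge_config, validate_config
from .errors import ValidationError
from .hemodynamics import (
    MMHG_PA,
    FFRResult,
    FlowBC,
    FluidModel,
    compute_ffr,
    mean_pressure,
    solve_steady_flow,
)
from .phantom import (
    CohortSpec,
    PhantomSpec,
    make_cohort,
    make_pressure_waveform,
    make_vessel_geometry,
    lumen_mask,
    rasterize_ct,
)
from .reconstruction import (
    extract_lumen_profile,
    marching_cubes,
    mesh_report,
    smooth_mesh,
    write_mesh,
)
from .segmentation import apply_threshold, largest_component, optimal_threshold
from .volume import CTVolume, write_volume

__all__ = [
    "PipelineResult",
    "phantom_stage",
    "segment_stage",
    "reconstruct_stage",
    "profile_stage",
    "ffr_stage",
    "cohort_stage",
    "run_pipeline",
]


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, in memory."""

    config: dict
    volume: CTVolume
    threshold: object
    mask: CTVolume
    mesh: object
    mesh_stats: object
    profile_s: np.ndarray
    profile_r: np.ndarray
    ffr: FFRResult
    flow_mls: float
    manifest: dict


def _phantom_spec(cfg: dict, seed: int) -> PhantomSpec:
    p = cfg["phantom"]
    geo = make_vessel_geometry(
        length=p["length_mm"],
        radius=p["radius_mm"],
        severity=p["severity"],
        stenosis_center=p["stenosis_center_mm"],
        stenosis_width=p["stenosis_width_mm"],
    )
    return PhantomSpec(
        geometry=geo,
        spacing=tuple(p["spacing_mm"]),
        lumen_intensity=p["lumen_intensity"],
        background_intensity=p["background_intensity"],
        noise_sd=p["noise_sd"],
        seed=seed,
        margin=p["margin_mm"],
        supersample=int(p["supersample"]),
    )


def phantom_stage(cfg: dict, seed: int | None = None):
    """Generate the CT phantom volume and its ground-truth lumen mask."""
    seed = cfg["seed"] if seed is None else seed
    spec = _phantom_spec(cfg, seed)
    return rasterize_ct(spec), lumen_mask(spec)


def segment_stage(cfg: dict, volume: CTVolume):
    """Threshold scan + mask + largest-component cleanup."""
    s = cfg["segmentation"]
    result = optimal_threshold(volume, t_min=s["t_min"], t_max=s["t_max"], step=s["step"])
    mask = apply_threshold(volume, result.threshold)
    mask = largest_component(mask, connectivity=s["connectivity"])
    return result, mask


def reconstruct_stage(cfg: dict, mask: CTVolume):
    """Marching-cubes surface of the binary mask, optionally smoothed."""
    r = cfg["reconstruction"]
    mesh = marching_cubes(mask, isolevel=r["isolevel"])
    if r["smooth_iterations"] > 0:
        mesh = smooth_mesh(mesh, iterations=int(r["smooth_iterations"]),
                           factor=r["smooth_factor"])
    return mesh, mesh_report(mesh)


def profile_stage(cfg: dict, mask: CTVolume):
    """Equivalent-radius lumen profile r(s) from the cleaned mask."""
    s, r, gaps = extract_lumen_profile(mask, axis=2)
    keep = r > 0
    if not keep.any():
        raise ValidationError("empty lumen profile: segmentation produced no vessel")
    if gaps.any():
        raise ValidationError("lumen profile has interior gaps")
    return s[keep], r[keep]


def ffr_stage(cfg: dict, s_mm: np.ndarray, r_mm: np.ndarray):
    """Solve hyperemic flow over the profile and average the waveforms.

    The aortic pressure waveform is pulsatile around the configured
    mean; the distal waveform is the aortic one lowered by the steady
    stenotic pressure drop.  FFR = mean(Ps)/mean(Pr).
    """
    h = cfg["hemodynamics"]
    fluid = FluidModel(density=h["density"], viscosity=h["viscosity"])
    q_hyper = h["resting_flow_mls"] * h["hyperemia_factor"] * 1e-6  # m^3/s
    pr_pa = h["aortic_pressure_mmhg"] * MMHG_PA
    sol = solve_steady_flow(s_mm, r_mm, fluid, FlowBC(flow=q_hyper, outlet_pressure=1.0))

    s0, s1 = s_mm[0], s_mm[-1]
    pr_at = s0 if h["pr_station_mm"] is None else float(h["pr_station_mm"])
    ps_at = s1 if h["ps_station_mm"] is None else float(h["ps_station_mm"])
    p_of = lambda st: float(np.interp(st, s_mm, sol.pressure))
    drop_pr = p_of(s0) - p_of(pr_at)
    drop_ps = p_of(s0) - p_of(ps_at)

    aortic = make_pressure_waveform(
        mean=pr_pa - drop_pr,
        amplitude=h["pulse_amplitude_mmhg"] * MMHG_PA,
        period=h["pulse_period_s"],
        n_cycles=int(h["n_cycles"]),
        dt=h["dt_s"],
    )
    from .hemodynamics import Waveform

    distal = Waveform(t=aortic.t, p=aortic.p - (drop_ps - drop_pr))
    return compute_ffr(distal, aortic), sol


def cohort_stage(cfg: dict, seed: int | None = None):
    """Synthetic cohort table per the cohort config block."""
    c = cfg["cohort"]
    seed = cfg["seed"] if seed is None else seed
    spec = CohortSpec(n=int(c["n"]), r_target=c["r_target"],
                      event_probs=tuple(c["event_probs"]), seed=seed)
    return make_cohort(spec)


def run_pipeline(config: dict | None = None, outdir: str | None = None,
                 seed: int | None = None) -> PipelineResult:
    """Run phantom -> segment -> reconstruct -> profile -> solve -> FFR.

    ``config`` may be a partial override of the defaults.  When
    ``outdir`` is given, every intermediate artifact plus a manifest is
    written there.  A stage failure raises with the stage named; any
    artifacts already written are preserved.
    """
    cfg = merge_config(config) if not _is_full(config) else config
    issues = validate_config(cfg)
    if issues:
        raise ValidationError("invalid config: " + "; ".join(issues))
    if seed is not None:
        cfg = dict(cfg, seed=int(seed))

    log: list[dict] = []
    artifacts: dict[str, str] = {}
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            log.append({"stage": name, "status": "failed", "error": str(exc)})
            if outdir:
                _write_manifest(outdir, cfg, log, artifacts)
            raise type(exc)(f"pipeline stage '{name}' failed: {exc}") from exc
        log.append({"stage": name, "status": "ok",
                    "seconds": round(time.perf_counter() - t0, 4)})
        return out

    volume, truth = stage("phantom", lambda: phantom_stage(cfg))
    if outdir:
        write_volume(volume, _art(artifacts, outdir, "phantom", "phantom.mhd"))
    threshold, mask = stage("segment", lambda: segment_stage(cfg, volume))
    if outdir:
        write_volume(CTVolume(mask.data.astype(np.uint8), mask.spacing, mask.origin),
                     _art(artifacts, outdir, "mask", "mask.mhd"))
        threshold.to_json(_art(artifacts, outdir, "threshold", "threshold.json"))
    mesh, stats = stage("reconstruct", lambda: reconstruct_stage(cfg, mask))
    if outdir:
        write_mesh(mesh, _art(artifacts, outdir, "mesh", "mesh.stl"))
        with open(_art(artifacts, outdir, "mesh_report", "mesh_report.json"), "w") as fh:
            json.dump(stats.to_dict(), fh, indent=2)
    s_mm, r_mm = stage("profile", lambda: profile_stage(cfg, mask))
    if outdir:
        import pandas as pd

        pd.DataFrame({"s_mm": s_mm, "r_mm": r_mm}).to_csv(
            _art(artifacts, outdir, "profile", "profile.csv"), index=False)
    ffr, sol = stage("ffr", lambda: ffr_stage(cfg, s_mm, r_mm))
    q_mls = sol.flow * 1e6
    if outdir:
        with open(_art(artifacts, outdir, "ffr", "ffr.json"), "w") as fh:
            json.dump({"ffr": ffr.ffr, "ps_mmhg": ffr.ps_mmhg, "pr_mmhg": ffr.pr_mmhg,
                       "flow_mls": q_mls, "nonphysical": ffr.nonphysical}, fh, indent=2)
        import pandas as pd

        pd.DataFrame({"s_mm": sol.s * 1e3, "pressure_mmhg": sol.pressure / MMHG_PA,
                      "velocity_m_s": sol.velocity}).to_csv(
            _art(artifacts, outdir, "stations", "stations.csv"), index=False)

    manifest = _write_manifest(outdir, cfg, log, artifacts) if outdir else {
        "config_hash": config_hash(cfg), "seed": cfg["seed"], "log": log}
    return PipelineResult(
        config=cfg, volume=volume, threshold=threshold, mask=mask,
        mesh=mesh, mesh_stats=stats, profile_s=s_mm, profile_r=r_mm,
        ffr=ffr, flow_mls=q_mls, manifest=manifest,
    )


def _is_full(config) -> bool:
    return isinstance(config, dict) and set(config) == set(DEFAULT_CONFIG)


def _art(artifacts: dict, outdir: str, key: str, name: str) -> str:
    path = os.path.join(outdir, name)
    artifacts[key] = name
    return path


def _write_manifest(outdir, cfg, log, artifacts) -> dict:
    import numpy
    import scipy

    manifest = {
        "package": "ctffr",
        "version": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "seed": cfg["seed"],
        "config_hash": config_hash(cfg),
        "config": cfg,
        "artifacts": artifacts,
        "log": log,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
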