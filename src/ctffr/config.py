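"""Pipeline configuration: one YAML/JSON document with per-stage blocks.

The shipped defaults describe a 3 mm-diameter, 30 mm-long coronary
segment with a 50% mid-vessel stenosis imaged at 0.5 mm isotropic
voxels, segmented by an integer-grid threshold scan, and solved at a
hyperemic flow of 1.5 mL/s (3x a 0.5 mL/s resting flow) against a
100 mmHg aortic pressure.
"""

from __future__ import annotations

import copy
import json

import yaml

from .errors import ValidationError

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "validate_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "phantom": {
        "length_mm": 30.0,
        "radius_mm": 1.5,
        "severity": 0.5,
        "stenosis_center_mm": None,   # null -> mid-vessel
        "stenosis_width_mm": 4.0,
        "spacing_mm": [0.5, 0.5, 0.5],
        "lumen_intensity": 350.0,
        "background_intensity": 50.0,
        "noise_sd": 10.0,
        "margin_mm": 3.0,
        "supersample": 1,
    },
    "segmentation": {
        "t_min": None,                # null -> scan the full intensity range
        "t_max": None,
        "step": 1.0,
        "connectivity": 26,
    },
    "reconstruction": {
        "isolevel": 0.5,
        "smooth_iterations": 0,
        "smooth_factor": 0.5,
    },
    "hemodynamics": {
        "density": 1060.0,            # kg/m^3
        "viscosity": 0.0035,          # Pa*s
        "resting_flow_mls": 0.5,
        "hyperemia_factor": 3.0,
        "aortic_pressure_mmhg": 100.0,
        "pulse_amplitude_mmhg": 20.0,
        "pulse_period_s": 0.8,
        "n_cycles": 5,
        "dt_s": 0.004,
        "pr_station_mm": None,        # null -> inlet
        "ps_station_mm": None,        # null -> outlet
    },
    "cohort": {
        "n": 90,
        "r_target": 0.3,
        "event_probs": [0.1, 0.1, 0.4],
    },
}


def merge_config(overrides: dict | None) -> dict:
    """Defaults deep-merged with a (possibly partial) override document."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src, path):
        for k, v in src.items():
            if k not in dst:
                raise ValidationError(f"unknown config key: {path}{k}")
            if isinstance(dst[k], dict) and isinstance(v, dict):
                merge(dst[k], v, f"{path}{k}.")
            else:
                dst[k] = v

    if overrides:
        merge(cfg, overrides, "")
    return cfg


def load_config(path) -> dict:
    """Load a YAML or JSON config file and merge it over the defaults."""
    with open(path) as fh:
        text = fh.read()
    try:
        doc = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ValidationError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ValidationError(f"config root must be a mapping, got {type(doc).__name__}")
    return merge_config(doc)


def validate_config(cfg: dict) -> list[str]:
    """Every violated invariant, as ``field: problem`` strings (empty = valid)."""
    issues: list[str] = []

    def check(cond, msg):
        if not cond:
            issues.append(msg)

    p = cfg["phantom"]
    check(p["length_mm"] > 0, "phantom.length_mm: must be positive")
    check(p["radius_mm"] > 0, "phantom.radius_mm: must be positive")
    check(0 <= p["severity"] < 1, "phantom.severity: must lie in [0, 1)")
    check(p["stenosis_width_mm"] > 0, "phantom.stenosis_width_mm: must be positive")
    check(len(p["spacing_mm"]) == 3 and all(s > 0 for s in p["spacing_mm"]),
          "phantom.spacing_mm: need three positive values")
    check(p["lumen_intensity"] > p["background_intensity"],
          "phantom.lumen_intensity: must exceed background_intensity")
    check(p["noise_sd"] >= 0, "phantom.noise_sd: must be non-negative")
    check(int(p["supersample"]) >= 1, "phantom.supersample: must be >= 1")

    s = cfg["segmentation"]
    check(s["step"] > 0, "segmentation.step: must be positive")
    check(s["connectivity"] in (6, 18, 26), "segmentation.connectivity: must be 6, 18 or 26")
    if s["t_min"] is not None and s["t_max"] is not None:
        check(s["t_min"] <= s["t_max"], "segmentation.t_min: exceeds t_max")

    r = cfg["reconstruction"]
    check(r["smooth_iterations"] >= 0, "reconstruction.smooth_iterations: must be >= 0")

    h = cfg["hemodynamics"]
    check(h["density"] > 0, "hemodynamics.density: must be positive")
    check(h["viscosity"] > 0, "hemodynamics.viscosity: must be positive")
    check(h["resting_flow_mls"] >= 0, "hemodynamics.resting_flow_mls: must be non-negative")
    check(h["hyperemia_factor"] > 0, "hemodynamics.hyperemia_factor: must be positive")
    check(h["aortic_pressure_mmhg"] > 0, "hemodynamics.aortic_pressure_mmhg: must be positive")
    check(h["pulse_period_s"] > 0, "hemodynamics.pulse_period_s: must be positive")
    check(h["dt_s"] > 0, "hemodynamics.dt_s: must be positive")
    check(int(h["n_cycles"]) >= 1, "hemodynamics.n_cycles: must be >= 1")

    c = cfg["cohort"]
    check(int(c["n"]) >= 1, "cohort.n: must be positive")
    rt = c["r_target"]
    rts = rt.values() if isinstance(rt, dict) else [rt]
    check(all(abs(v) < 1 for v in rts), "cohort.r_target: |r| must be < 1")
    check(len(c["event_probs"]) == 3 and all(0 <= q <= 1 for q in c["event_probs"]),
          "cohort.event_probs: need three probabilities in [0, 1]")
    return issues


def config_hash(cfg: dict) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
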