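"""Synthetic CT phantoms of stenosed vessels and synthetic patient cohorts.

The imaging phantom is a single straight contrast-enhanced lumen: a
bright tube of baseline radius R0 narrowed by a Gaussian bump at the
stenosis throat, embedded in a darker soft-tissue background, with
optional additive Gaussian noise.  The cohort generator emulates the
statistical structure of a PCI cohort stratified by SYNTAX score:
right-skewed integer scores, lipid measures correlated with the score
through a Gaussian copula, and MACCE events drawn at group-specific
rates.

Everything is driven by a single integer seed through one
``numpy.random.default_rng`` stream per artifact, so identical specs
reproduce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .hemodynamics import Waveform
from .volume import CTVolume

__all__ = [
    "VesselGeometry",
    "PhantomSpec",
    "CohortSpec",
    "make_vessel_geometry",
    "rasterize_ct",
    "lumen_mask",
    "make_cohort",
    "make_pressure_waveform",
]


@dataclass(frozen=True)
class VesselGeometry:
    """Straight vessel with one Gaussian stenosis.

    The lumen radius along the centerline arclength s (mm) is

        r(s) = R0 * (1 - d * g(s)),   g(s) = exp(-(s - s0)^2 / (2 w^2))

    so the throat radius at s = s0 is R0 (1 - d), with d the fractional
    diameter reduction and w the Gaussian width (mm).  The centerline is
    stored as a polyline; v1 keeps it straight along the z axis.
    """

    length: float          # L, mm
    radius: float          # R0, mm
    severity: float        # d in [0, 1)
    stenosis_center: float  # s0, mm
    stenosis_width: float  # w, mm
    centerline: np.ndarray = field(default=None, repr=False)  # (N, 3) mm

    def __post_init__(self):
        if self.length <= 0 or self.radius <= 0 or self.stenosis_width <= 0:
            raise ValidationError("length, radius and stenosis width must be positive")
        if not 0.0 <= self.severity < 1.0:
            raise ValidationError(f"severity must lie in [0, 1), got {self.severity}")
        if self.centerline is None:
            line = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, self.length]])
            object.__setattr__(self, "centerline", line)

    def bump(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.exp(-((s - self.stenosis_center) ** 2) / (2.0 * self.stenosis_width**2))

    def radius_at(self, s) -> np.ndarray:
        """Lumen radius r(s) in mm; strictly positive for d < 1."""
        return self.radius * (1.0 - self.severity * self.bump(s))

    @property
    def throat_radius(self) -> float:
        return self.radius * (1.0 - self.severity)

    def profile(self, n: int = 201) -> tuple[np.ndarray, np.ndarray]:
        """Sampled (s, r) ground-truth profile over the vessel length."""
        s = np.linspace(0.0, self.length, n)
        return s, self.radius_at(s)


def make_vessel_geometry(
    length: float = 30.0,
    radius: float = 1.5,
    severity: float = 0.5,
    stenosis_center: float | None = None,
    stenosis_width: float = 4.0,
) -> VesselGeometry:
    """Build a single-stenosis vessel geometry (defaults: a 3 mm-diameter
    coronary segment, severity 50%, mid-vessel lesion)."""
    if stenosis_center is None:
        stenosis_center = length / 2.0
    return VesselGeometry(length, radius, severity, stenosis_center, stenosis_width)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a rasterized CT phantom.

    Intensities are HU-like: contrast-filled lumen ~350, soft tissue
    ~50.  ``supersample`` > 1 averages sub-voxel occupancy for
    partial-volume softening; the default 1 keeps voxels hard in/out so
    the analytic-volume oracle is exact.  ``margin`` is dead space (mm)
    added laterally around the vessel.
    """

    geometry: VesselGeometry
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)  # (dz, dy, dx) mm
    lumen_intensity: float = 350.0
    background_intensity: float = 50.0
    noise_sd: float = 10.0
    seed: int = 0
    margin: float = 3.0
    supersample: int = 1
    shape: tuple[int, int, int] | None = None  # override; must contain the vessel

    def __post_init__(self):
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be three positive values")
        if self.lumen_intensity <= self.background_intensity:
            raise ValidationError("lumen intensity must exceed background intensity")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")
        if self.supersample < 1:
            raise ValidationError("supersample must be >= 1")


def _grid(spec: PhantomSpec) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Volume shape and origin so the vessel axis runs along z at x=y=0."""
    geo = spec.geometry
    dz, dy, dx = spec.spacing
    half = geo.radius + spec.margin
    nz = int(np.ceil(geo.length / dz)) + 1
    ny = int(np.ceil(2 * half / dy)) + 1
    nx = int(np.ceil(2 * half / dx)) + 1
    if spec.shape is not None:
        sz, sy, sx = spec.shape
        if sz * dz < geo.length or sy * dy < 2 * geo.radius or sx * dx < 2 * geo.radius:
            raise ValidationError("requested volume extent smaller than the vessel geometry")
        nz, ny, nx = sz, sy, sx
    origin = (0.0, -(ny - 1) * dy / 2.0, -(nx - 1) * dx / 2.0)
    return (nz, ny, nx), origin


def _occupancy(spec: PhantomSpec) -> np.ndarray:
    """Fraction of each voxel inside the lumen (hard 0/1 when supersample=1)."""
    (nz, ny, nx), origin = _grid(spec)
    dz, dy, dx = spec.spacing
    k = spec.supersample
    # sub-voxel sample offsets centred in each voxel
    off = (np.arange(k) + 0.5) / k - 0.5
    occ = np.zeros((nz, ny, nx), dtype=float)
    zc = origin[0] + dz * np.arange(nz)
    yc = origin[1] + dy * np.arange(ny)
    xc = origin[2] + dx * np.arange(nx)
    for oz in off:
        r = spec.geometry.radius_at(zc + oz * dz)  # (nz,)
        r2 = r**2
        for oy in off:
            y2 = (yc + oy * dy) ** 2  # (ny,)
            for ox in off:
                x2 = (xc + ox * dx) ** 2  # (nx,)
                d2 = y2[:, None] + x2[None, :]  # (ny, nx)
                occ += (d2[None, :, :] <= r2[:, None, None])
    return occ / k**3


def lumen_mask(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth lumen mask: voxel centres inside the tube."""
    hard = spec if spec.supersample == 1 else replace(spec, supersample=1)
    return _occupancy(hard) > 0.5


def rasterize_ct(spec: PhantomSpec) -> CTVolume:
    """Rasterize the phantom to a CT volume (deterministic per seed)."""
    occ = _occupancy(spec)
    data = spec.background_intensity + (spec.lumen_intensity - spec.background_intensity) * occ
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    _, origin = _grid(spec)
    return CTVolume(data=data, spacing=spec.spacing, origin=origin)


# ---------------------------------------------------------------------------
# cohort generator

#: lipid marginals as (mean, sd) — total cholesterol, triglyceride and
#: LDL-C in mmol/L, ApoB/ApoA1 dimensionless; lognormal to stay positive
LIPID_MARGINALS: dict[str, tuple[float, float]] = {
    "total_cholesterol": (4.8, 1.0),
    "triglyceride": (1.7, 0.9),
    "ldl_c": (3.0, 0.9),
    "apob_apoa1": (0.85, 0.25),
}

#: binary covariate prevalences typical of a PCI cohort
COVARIATE_PREVALENCE: dict[str, float] = {
    "smoking": 0.52,
    "diabetes": 0.20,
    "hypertension": 0.57,
    "hyperlipidemia": 0.55,
    "unstable_angina": 0.40,
}

#: SYNTAX score marginal: rounded gamma, right-skewed over ~0-50
SYNTAX_GAMMA_SHAPE = 7.5
SYNTAX_GAMMA_SCALE = 3.6


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic SYNTAX-stratified cohort.

    ``r_target`` is the Pearson correlation between the SYNTAX score and
    each lipid variable (scalar, or a per-variable mapping).
    ``event_probs`` are MACCE probabilities for the (low, medium, high)
    score groups.
    """

    n: int = 90
    r_target: float | dict = 0.3
    event_probs: tuple[float, float, float] = (0.1, 0.1, 0.4)
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("cohort size must be positive")
        for r in self._r_map().values():
            if not abs(r) < 1:
                raise ValidationError(f"|r_target| must be < 1, got {r}")
        if any(not 0 <= p <= 1 for p in self.event_probs):
            raise ValidationError("event probabilities must lie in [0, 1]")

    def _r_map(self) -> dict[str, float]:
        if isinstance(self.r_target, dict):
            missing = set(LIPID_MARGINALS) - set(self.r_target)
            if missing:
                raise ValidationError(f"r_target missing variables: {sorted(missing)}")
            return {k: float(self.r_target[k]) for k in LIPID_MARGINALS}
        return {k: float(self.r_target) for k in LIPID_MARGINALS}

    def correlation_matrix(self) -> np.ndarray:
        """Latent Gaussian correlation: score first, then the four lipids.

        One-factor structure: corr(score, lipid_j) = r_j and
        corr(lipid_j, lipid_k) = r_j r_k, which is positive semidefinite
        for any |r_j| < 1.
        """
        r = np.array(list(self._r_map().values()))
        c = np.empty((5, 5))
        c[0, 0] = 1.0
        c[0, 1:] = c[1:, 0] = r
        c[1:, 1:] = np.outer(r, r)
        np.fill_diagonal(c[1:, 1:], 1.0)
        return c


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a per-patient cohort table.

    Columns: ``syntax_score`` (integer points, 0-50), the four lipid
    variables, binary covariates, ``macce`` event flag and
    ``followup_years`` (uniform on 2-4).  The score and the lipids share
    a Gaussian copula at the requested correlations; marginals are a
    rounded gamma for the score and matched-moment lognormals for the
    lipids.
    """
    corr = spec.correlation_matrix()
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValidationError("correlation matrix is not positive semidefinite")
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(5))
    z = rng.standard_normal((spec.n, 5)) @ chol.T
    u = stats.norm.cdf(z)

    score = stats.gamma.ppf(u[:, 0], a=SYNTAX_GAMMA_SHAPE, scale=SYNTAX_GAMMA_SCALE)
    score = np.minimum(np.round(score), 50).astype(int)

    table = {"syntax_score": score}
    for j, (name, (mean, sd)) in enumerate(LIPID_MARGINALS.items(), start=1):
        mu, sigma = _lognormal_params(mean, sd)
        table[name] = np.exp(mu + sigma * stats.norm.ppf(u[:, j]))

    for name, prev in COVARIATE_PREVALENCE.items():
        table[name] = rng.random(spec.n) < prev

    p_low, p_med, p_high = spec.event_probs
    group_p = np.where(score <= 22, p_low, np.where(score <= 32, p_med, p_high))
    table["macce"] = rng.random(spec.n) < group_p
    table["followup_years"] = rng.uniform(2.0, 4.0, spec.n)
    return pd.DataFrame(table)


def make_pressure_waveform(
    mean: float,
    amplitude: float,
    period: float,
    n_cycles: int = 5,
    dt: float = 0.01,
) -> Waveform:
    """Periodic pressure waveform whose time average equals ``mean`` exactly.

    A sinusoidal pulsatile component over ``n_cycles`` whole cardiac
    cycles; after sampling, the component's discrete trapezoidal mean is
    subtracted so the contract holds exactly on the returned grid, not
    just in the continuum limit.
    """
    if period <= 0 or dt <= 0:
        raise ValidationError("period and dt must be positive")
    if n_cycles < 1:
        raise ValidationError("need at least one cycle")
    n = int(round(n_cycles * period / dt))
    t = np.linspace(0.0, n_cycles * period, n + 1)
    pulse = amplitude * np.sin(2.0 * np.pi * t / period)
    if amplitude != 0:
        pulse = pulse - np.trapezoid(pulse, t) / (t[-1] - t[0])
    return Waveform(t=t, p=mean + pulse)
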