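"""Digital coronary vessel phantoms with paired emulated IVUS pullbacks.

A phantom is a tube of circular cross section around a straight or helical
centerline: a contrast-bright lumen of radius r(s) inside a vessel wall of
outer radius R(s), both smooth functions of arclength s built from Gaussian
bumps (stenoses narrow the lumen, wall thickenings push the outer boundary
outward). The diffuse wall is non-calcified tissue; calcified (CP) and
low-attenuation (LAP) deposits occupy angular sectors of the wall over
axial intervals. Each tissue gets per-voxel HU drawn from its own normal
distribution; rendering supersamples the analytic geometry 3x per axis and
averages (partial volume), optionally blurs with a Gaussian PSF and adds
noise. Ground truth is computed from the analytic geometry alone and never
depends on the voxel grid.

The paired "IVUS" pullback samples the true area profile at 1 mm
increments of a warped pullback distance (a monotone map emulating
pullback-speed variation), multiplies areas by mean-one lognormal noise,
and carries start/end/bifurcation anchor landmarks for co-registration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm

from .geometry import Centerline, ImageVolume, LabelVolume
from .ivus_profile import (
    ANCHOR_BIFURCATION,
    ANCHOR_END,
    ANCHOR_START,
    PullbackProfile,
)

SUPERSAMPLE = 3  # per-axis supersampling factor for partial-volume rendering
TRUTH_STATION_STEP = 0.5  # mm, tabulated ground-truth stations
TRUTH_QUAD_STEP = 0.02  # mm, dense quadrature step for true volumes

# Default tissue HU distributions (mean, SD). The lumen is contrast-enhanced;
# CP sits above the adaptive calcium threshold (its draw is truncated there),
# NCP occupies the 30..threshold window, LAP the -30..30 window.
DEFAULT_HU_PARAMS = {
    "lumen": (450.0, 60.0),
    "CP": (700.0, 100.0),
    "NCP": (80.0, 30.0),
    "LAP": (0.0, 15.0),
    "background": (-50.0, 20.0),
}

_REGION_IDS = {"background": 0, "lumen": 1, "NCP": 2, "CP": 3, "LAP": 4}


@dataclass(frozen=True)
class Stenosis:
    """Gaussian lumen narrowing: fractional depth ``severity`` at ``center_mm``,
    full width at half maximum ``width_mm``."""

    center_mm: float
    width_mm: float
    severity: float


@dataclass(frozen=True)
class WallThickening:
    """Gaussian outward bump of the outer wall: ``extra_mm`` at the peak."""

    center_mm: float
    width_mm: float
    extra_mm: float


@dataclass(frozen=True)
class Deposit:
    """A plaque component occupying an angular sector of the wall over an
    axial interval [start_mm, end_mm)."""

    start_mm: float
    end_mm: float
    angle_start_deg: float
    span_deg: float
    component: str  # "CP" | "NCP" | "LAP"


@dataclass
class PhantomSpec:
    """Parametric description of one vessel phantom; fully determines the
    rendered image, labels, centerline and ground truth given its seed."""

    length_mm: float = 20.0
    centerline_kind: str = "straight"  # "straight" | "helical"
    helix_radius_mm: float = 0.0
    helix_turns: float = 0.0
    lumen_radius_mm: float = 1.5
    outer_radius_mm: float = 2.5
    stenoses: list = field(default_factory=list)
    wall_thickenings: list = field(default_factory=list)
    deposits: list = field(default_factory=list)
    bifurcations_mm: list = field(default_factory=list)
    hu_params: dict = field(default_factory=lambda: dict(DEFAULT_HU_PARAMS))
    psf_sigma_mm: float = 0.3
    noise_sd_hu: float = 20.0
    voxel_spacing_mm: float = 0.4
    margin_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- analytic radius profiles ------------------------------------------
    def lumen_radius(self, s):
        s = np.asarray(s, dtype=float)
        r = np.full(s.shape, self.lumen_radius_mm)
        for st in self.stenoses:
            sig = st.width_mm / 2.355  # FWHM -> sigma
            r = r - self.lumen_radius_mm * st.severity * np.exp(
                -0.5 * ((s - st.center_mm) / sig) ** 2
            )
        return r

    def outer_radius(self, s):
        s = np.asarray(s, dtype=float)
        r = np.full(s.shape, self.outer_radius_mm)
        for wt in self.wall_thickenings:
            sig = wt.width_mm / 2.355
            r = r + wt.extra_mm * np.exp(-0.5 * ((s - wt.center_mm) / sig) ** 2)
        return r

    def component_arcs(self, s):
        """(cp_arc_deg, lap_arc_deg) at arclengths s, summed over deposits."""
        s = np.asarray(s, dtype=float)
        cp = np.zeros(s.shape)
        lap = np.zeros(s.shape)
        for d in self.deposits:
            active = (s >= d.start_mm) & (s < d.end_mm)
            if d.component == "CP":
                cp = cp + active * d.span_deg
            elif d.component == "LAP":
                lap = lap + active * d.span_deg
        return cp, lap

    def validate(self) -> None:
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel_spacing_mm must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be non-negative")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        for st in self.stenoses:
            if not (0.0 <= st.severity < 1.0):
                raise ValueError("stenosis fractional narrowing must be in [0, 1)")
        s = np.arange(0.0, self.length_mm + 1e-9, 0.05)
        gap = self.outer_radius(s) - self.lumen_radius(s)
        bad = np.nonzero(gap < -1e-9)[0]
        if bad.size:
            raise ValueError(
                f"outer radius < lumen radius at s = {s[bad[0]]:.2f} mm"
            )
        for d in self.deposits:
            if d.component not in ("CP", "NCP", "LAP"):
                raise ValueError(f"unknown deposit component {d.component!r}")
            if not (0 < d.span_deg <= 360):
                raise ValueError("deposit span must be in (0, 360] degrees")
        self._check_deposit_overlap()
        if self.centerline_kind == "helical":
            if 2 * np.pi * self.helix_turns * self.helix_radius_mm >= self.length_mm:
                raise ValueError("helix too tight for its arclength")
        elif self.centerline_kind != "straight":
            raise ValueError(f"unknown centerline_kind {self.centerline_kind!r}")

    def _check_deposit_overlap(self) -> None:
        # disjointness keeps ground-truth component areas additive
        for i, a in enumerate(self.deposits):
            for b in self.deposits[i + 1 :]:
                ax = a.start_mm < b.end_mm and b.start_mm < a.end_mm
                if ax and _sectors_overlap(
                    a.angle_start_deg, a.span_deg, b.angle_start_deg, b.span_deg
                ):
                    raise ValueError("deposits overlap both axially and angularly")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["stenoses"] = [Stenosis(**x) for x in d.get("stenoses", [])]
        d["wall_thickenings"] = [WallThickening(**x) for x in d.get("wall_thickenings", [])]
        d["deposits"] = [Deposit(**x) for x in d.get("deposits", [])]
        d["hu_params"] = {k: tuple(v) for k, v in d.get("hu_params", DEFAULT_HU_PARAMS).items()}
        return cls(**d)

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def read_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sectors_overlap(a0: float, aspan: float, b0: float, bspan: float) -> bool:
    """Do two angular sectors (degrees, wrap at 360) intersect?"""
    a0, b0 = a0 % 360.0, b0 % 360.0
    for shift in (-360.0, 0.0, 360.0):
        if a0 < b0 + bspan + shift and b0 + shift < a0 + aspan:
            return True
    return False


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Analytic truth for one phantom: area profiles, deposit arcs, volumes.

    Derived purely from the :class:`PhantomSpec` geometry — refining the
    voxel grid changes nothing here. Component areas are disjoint
    (``ncp_area`` excludes LAP); cp + ncp + lap equals vessel - lumen at
    every arclength. True volumes integrate the analytic area profiles by
    dense fixed-step trapezoid quadrature.
    """

    spec: PhantomSpec
    bifurcations_mm: list

    @property
    def length(self) -> float:
        return self.spec.length_mm

    def lumen_area(self, s):
        return np.pi * self.spec.lumen_radius(s) ** 2

    def vessel_area(self, s):
        return np.pi * self.spec.outer_radius(s) ** 2

    def wall_area(self, s):
        return self.vessel_area(s) - self.lumen_area(s)

    def cp_area(self, s):
        cp_arc, _ = self.spec.component_arcs(s)
        return cp_arc / 360.0 * self.wall_area(s)

    def lap_area(self, s):
        _, lap_arc = self.spec.component_arcs(s)
        return lap_arc / 360.0 * self.wall_area(s)

    def ncp_area(self, s):
        return self.wall_area(s) - self.cp_area(s) - self.lap_area(s)

    def arcs(self, s):
        return self.spec.component_arcs(s)

    _AREA_FN = {
        "lumen": "lumen_area",
        "vessel": "vessel_area",
        "plaque": "wall_area",
        "cp": "cp_area",
        "ncp": "ncp_area",
        "lap": "lap_area",
    }

    def volume(self, kind: str, start: float = 0.0, end: float | None = None) -> float:
        """True volume (mm^3) of a component over [start, end] arclength."""
        if end is None:
            end = self.length
        start = max(0.0, start)
        end = min(self.length, end)
        if end <= start:
            return 0.0
        n = max(int(np.ceil((end - start) / TRUTH_QUAD_STEP)), 2)
        s = np.linspace(start, end, n + 1)
        a = getattr(self, self._AREA_FN[kind])(s)
        return float(np.trapezoid(a, s))

    def stations(self, step: float = TRUTH_STATION_STEP) -> np.ndarray:
        s = np.arange(0.0, self.length + 1e-9, step)
        if self.length - s[-1] > 1e-9:
            s = np.append(s, self.length)
        return s

    def to_series(self, step: float = TRUTH_STATION_STEP):
        """Noise-free CCTA-side cross-section series from the analytic truth."""
        from .geometry import CrossSectionSeries

        n = max(int(round(self.length / step)), 2)
        s = np.linspace(0.0, self.length, n + 1)
        return CrossSectionSeries(
            arclength=s,
            lumen_area=self.lumen_area(s),
            vessel_area=self.vessel_area(s),
            cp_area=self.cp_area(s),
            ncp_area=self.ncp_area(s),
            lap_area=self.lap_area(s),
            excluded_area=np.zeros_like(s),
        )

    def to_frame(self, step: float = TRUTH_STATION_STEP) -> pd.DataFrame:
        s = self.stations(step)
        cp_arc, lap_arc = self.arcs(s)
        return pd.DataFrame(
            {
                "arclength_mm": s,
                "lumen_area_mm2": self.lumen_area(s),
                "vessel_area_mm2": self.vessel_area(s),
                "cp_area_mm2": self.cp_area(s),
                "ncp_area_mm2": self.ncp_area(s),
                "lap_area_mm2": self.lap_area(s),
                "cp_arc_deg": cp_arc,
                "lap_arc_deg": lap_arc,
            }
        )


# ---------------------------------------------------------------------------
# centerline geometry


def _centerline_points(spec: PhantomSpec, s):
    """World points of the centerline at arclengths ``s``."""
    s = np.asarray(s, dtype=float)
    if spec.centerline_kind == "straight":
        pts = np.zeros(s.shape + (3,))
        pts[..., 2] = s
        return pts
    a, omega, speed = _helix_params(spec)
    t = s / speed
    return np.stack(
        [a * (np.cos(omega * t) - 1.0), a * np.sin(omega * t), t], axis=-1
    )


def _helix_params(spec: PhantomSpec) -> tuple[float, float, float]:
    """(radius a, angular rate omega, arclength speed) of the helix c(t) =
    (a(cos wt - 1), a sin wt, t); s = t * speed."""
    a = spec.helix_radius_mm
    L = spec.length_mm
    k = 2 * np.pi * spec.helix_turns / L
    omega = k / np.sqrt(max(1.0 - (k * a) ** 2, 1e-12))
    speed = np.sqrt((a * omega) ** 2 + 1.0)
    return a, omega, speed


def _tube_coords(spec: PhantomSpec, pts: np.ndarray):
    """(s, r, theta_deg) tube coordinates of world points relative to the
    centerline: arclength of the nearest centerline point, radial distance in
    its normal plane, and angle in a transported frame."""
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    if spec.centerline_kind == "straight":
        r = np.hypot(x, y)
        theta = np.degrees(np.arctan2(y, x)) % 360.0
        return z, r, theta
    a, omega, speed = _helix_params(spec)
    t = np.array(z, dtype=float)  # Newton refinement of the foot parameter
    c2 = speed * speed
    for _ in range(4):
        cw, sw = np.cos(omega * t), np.sin(omega * t)
        dx = x - a * (cw - 1.0)
        dy = y - a * sw
        dz = z - t
        # f(t) = (p - c) . c'(t); c' = (-a w sin, a w cos, 1)
        f = dx * (-a * omega * sw) + dy * (a * omega * cw) + dz
        # f' = -|c'|^2 + (p - c) . c''; c'' = (-a w^2 cos, -a w^2 sin, 0)
        fp = -c2 + dx * (-a * omega**2 * cw) + dy * (-a * omega**2 * sw)
        t = t - f / fp
    cw, sw = np.cos(omega * t), np.sin(omega * t)
    d = np.stack([x - a * (cw - 1.0), y - a * sw, z - t], axis=-1)
    tang = np.stack([-a * omega * sw, a * omega * cw, np.ones_like(t)], axis=-1) / speed
    d_perp = d - np.sum(d * tang, axis=-1, keepdims=True) * tang
    r = np.linalg.norm(d_perp, axis=-1)
    normal = np.stack([-cw, -sw, np.zeros_like(t)], axis=-1)  # toward helix axis
    binormal = np.cross(tang, normal)
    theta = np.degrees(
        np.arctan2(np.sum(d_perp * binormal, axis=-1), np.sum(d_perp * normal, axis=-1))
    ) % 360.0
    return t * speed, r, theta


# ---------------------------------------------------------------------------
# phantom rendering


def make_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, LabelVolume, Centerline, GroundTruth]:
    """Render a phantom: HU image, noise-free labels, centerline, ground truth.

    The analytic geometry is sampled at 3x the voxel resolution and block-
    averaged into per-voxel tissue fractions (partial volume). Voxel HU is
    the fraction-weighted mix of per-tissue draws; labels are the majority
    tissue class. PSF blur and additive noise apply to the image only.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # grid extents from the dense centerline plus max outer radius + margin
    s_dense = np.arange(0.0, spec.length_mm + 1e-9, 0.1)
    cl_dense = _centerline_points(spec, s_dense)
    r_max = float(np.max(spec.outer_radius(s_dense)))
    pad = r_max + spec.margin_mm
    lo = cl_dense.min(axis=0) - pad
    hi = cl_dense.max(axis=0) + pad
    h = float(spec.voxel_spacing_mm)
    n_vox = np.maximum(np.ceil((hi - lo) / h).astype(int), 1)
    origin = lo + h / 2.0  # voxel centers

    # supersampled coordinates (axis-separable offsets)
    ss = SUPERSAMPLE
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    axes = [
        (origin[k] + (np.arange(n_vox[k])[:, None] + sub[None, :]) * h).ravel()
        for k in range(3)
    ]
    X = axes[0][:, None, None]
    Y = axes[1][None, :, None]
    Z = axes[2][None, None, :]
    pts = np.stack(np.broadcast_arrays(X, Y, Z), axis=-1)
    s, r, theta = _tube_coords(spec, pts)
    del pts

    axial = (s >= 0.0) & (s < spec.length_mm)
    r_lum = spec.lumen_radius(np.clip(s, 0.0, spec.length_mm))
    r_out = spec.outer_radius(np.clip(s, 0.0, spec.length_mm))
    region = np.zeros(s.shape, dtype=np.uint8)
    in_lumen = axial & (r < r_lum)
    in_wall = axial & ~in_lumen & (r < r_out)
    region[in_lumen] = _REGION_IDS["lumen"]
    region[in_wall] = _REGION_IDS["NCP"]
    for d in spec.deposits:
        in_ax = (s >= d.start_mm) & (s < d.end_mm)
        ang = (theta - d.angle_start_deg) % 360.0
        sector = ang < d.span_deg
        region[in_wall & in_ax & sector] = _REGION_IDS[d.component]
    del s, r, theta, axial, r_lum, r_out, in_lumen, in_wall

    # block-average one-hot region indicators -> per-voxel tissue fractions
    fracs = {}
    for name, rid in _REGION_IDS.items():
        onehot = (region == rid).astype(np.float32)
        fracs[name] = onehot.reshape(
            n_vox[0], ss, n_vox[1], ss, n_vox[2], ss
        ).mean(axis=(1, 3, 5))
    del region

    labels_data = np.zeros(tuple(n_vox), dtype=np.uint8)
    wall_frac = fracs["NCP"] + fracs["CP"] + fracs["LAP"]
    stacked = np.stack([fracs["background"], fracs["lumen"], wall_frac])
    labels_data = np.argmax(stacked, axis=0).astype(np.uint8)  # 0 bg, 1 lumen, 2 wall

    hu = np.zeros(tuple(n_vox), dtype=np.float64)
    lum_mean, lum_sd = spec.hu_params["lumen"]
    cp_floor = max(350.0, lum_mean + lum_sd)
    for name in ("background", "lumen", "NCP", "CP", "LAP"):
        mean, sd = spec.hu_params[name]
        if name == "CP" and sd > 0:
            # truncated so calcium stays above the adaptive threshold
            a_std = (cp_floor - mean) / sd
            draw = truncnorm.rvs(
                a_std, np.inf, loc=mean, scale=sd, size=tuple(n_vox), random_state=rng
            )
        elif sd > 0:
            draw = rng.normal(mean, sd, size=tuple(n_vox))
        else:
            draw = np.full(tuple(n_vox), mean)
        hu += fracs[name] * draw

    if spec.psf_sigma_mm > 0:
        hu = gaussian_filter(hu, sigma=spec.psf_sigma_mm / h, mode="nearest")
    if spec.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)

    image = ImageVolume(data=hu.astype(np.float32), spacing=np.full(3, h), origin=origin)
    labels = LabelVolume(data=labels_data, spacing=np.full(3, h), origin=origin)
    cl_s = np.arange(0.0, spec.length_mm + 1e-9, 0.5)
    if spec.length_mm - cl_s[-1] > 1e-9:
        cl_s = np.append(cl_s, spec.length_mm)
    centerline = Centerline(points=_centerline_points(spec, cl_s), arclength=cl_s)
    truth = GroundTruth(spec=spec, bifurcations_mm=list(spec.bifurcations_mm))
    return image, labels, centerline, truth


# ---------------------------------------------------------------------------
# IVUS emulation


class MonotoneWarp:
    """Strictly increasing pullback-distance warp, true arclength -> pullback mm.

    A monotone piecewise cubic (PCHIP) through knots whose segment slopes are
    drawn from a bounded range, emulating pullback-speed variation while
    staying invertible.
    """

    def __init__(self, knots_s: np.ndarray, knots_p: np.ndarray):
        self.knots_s = np.asarray(knots_s, dtype=float)
        self.knots_p = np.asarray(knots_p, dtype=float)
        if np.any(np.diff(self.knots_s) <= 0) or np.any(np.diff(self.knots_p) <= 0):
            raise ValueError("warp knots must be strictly increasing")
        if len(self.knots_s) >= 3:
            self._f = PchipInterpolator(self.knots_s, self.knots_p)
        else:
            self._f = lambda s: np.interp(s, self.knots_s, self.knots_p)
        grid = np.linspace(self.knots_s[0], self.knots_s[-1], 4096)
        vals = np.asarray(self._f(grid), dtype=float)
        if np.any(np.diff(vals) <= 0):
            raise ValueError("warp is not strictly increasing")
        self._grid, self._vals = grid, vals

    def __call__(self, s):
        return self._f(s)

    def inverse(self, p):
        """Pullback position -> true arclength (dense-grid inversion)."""
        return np.interp(p, self._vals, self._grid)

    @classmethod
    def identity(cls, length: float) -> "MonotoneWarp":
        return cls(np.array([0.0, length]), np.array([0.0, length]))

    @classmethod
    def random(
        cls,
        length: float,
        rng: np.random.Generator,
        knot_spacing: float = 8.0,
        slope_range: tuple[float, float] = (0.8, 1.25),
        slope_sd: float = 0.08,
    ) -> "MonotoneWarp":
        """Random pullback warp: segment slopes model pullback-speed
        variation around the nominal motorized speed — normal with SD
        ``slope_sd`` around 1, clamped to ``slope_range``."""
        n_seg = max(int(round(length / knot_spacing)), 1)
        knots_s = np.linspace(0.0, length, n_seg + 1)
        slopes = np.clip(rng.normal(1.0, slope_sd, size=n_seg), *slope_range)
        knots_p = np.concatenate([[0.0], np.cumsum(slopes * np.diff(knots_s))])
        return cls(knots_s, knots_p)


def emulate_ivus_pullback(
    truth: GroundTruth,
    area_noise_cv: float = 0.05,
    warp: MonotoneWarp | None = None,
    seed: int = 0,
) -> PullbackProfile:
    """Emulate a motorized-pullback measurement of the phantom.

    Stations sit at 1 mm increments of warped pullback distance; lumen and
    vessel areas are the true areas at the warp-inverse arclengths times
    mean-one lognormal factors of coefficient of variation ``area_noise_cv``
    (independent per station and measure). The measured vessel area is
    clamped to at least the measured lumen area, as planimetry would enforce.
    Calcified/attenuated arcs copy the deposit sectors; anchors mark the
    pullback start, end and each bifurcation.
    """
    if area_noise_cv < 0:
        raise ValueError("area_noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    L = truth.length
    if warp is None:
        warp = MonotoneWarp.identity(L)
    grid = np.linspace(0.0, L, 8192)
    vals = np.asarray(warp(grid), dtype=float)
    if np.any(np.diff(vals) <= 0):
        raise ValueError("warp must be strictly increasing over the pullback range")
    total = float(warp(L))
    positions = np.arange(0.0, total + 1e-9, 1.0)
    s_true = warp.inverse(positions)
    s_true[0], s_true[-1] = 0.0, min(s_true[-1], L)

    lumen = truth.lumen_area(s_true)
    vessel = truth.vessel_area(s_true)
    if area_noise_cv > 0:
        sig = np.sqrt(np.log1p(area_noise_cv**2))
        factors = rng.lognormal(-0.5 * sig * sig, sig, size=(2, len(positions)))
        lumen = lumen * factors[0]
        vessel = vessel * factors[1]
        vessel = np.maximum(vessel, lumen)
    cp_arc, lap_arc = truth.arcs(s_true)
    anchors = [(0.0, ANCHOR_START)]
    anchors += [(float(warp(b)), ANCHOR_BIFURCATION) for b in truth.bifurcations_mm]
    anchors += [(total, ANCHOR_END)]
    return PullbackProfile(
        position=positions,
        lumen_area=lumen,
        vessel_area=vessel,
        calc_arc_deg=cp_arc,
        atten_arc_deg=lap_arc,
        anchors=anchors,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortDistribution:
    """Ranges and probabilities from which cohort lesions are drawn.

    Defaults describe a desk-scale study population: one focal lesion per
    vessel with randomized stenosis geometry, CP deposits in 60% and LAP
    deposits in 50% of lesions (so zero-CP, zero-LAP and mixed lesions all
    occur), 5% IVUS area noise and a bounded-slope pullback warp.
    """

    length_range: tuple = (25.0, 40.0)
    lumen_radius_range: tuple = (1.5, 1.9)
    base_wall_range: tuple = (0.18, 0.30)
    lesion_center_frac: tuple = (0.35, 0.65)
    lesion_halfwidth_range: tuple = (4.0, 7.0)
    wall_extra_range: tuple = (0.9, 1.6)
    stenosis_severity_range: tuple = (0.10, 0.45)
    minor_stenosis_severity: tuple = (0.03, 0.10)
    p_cp: float = 0.6
    cp_span_range: tuple = (40.0, 130.0)
    cp_length_range: tuple = (3.0, 8.0)
    p_lap: float = 0.5
    lap_span_range: tuple = (20.0, 100.0)
    lap_length_range: tuple = (2.0, 8.0)
    p_helical: float = 0.25
    helix_radius_range: tuple = (0.5, 1.5)
    max_bifurcations: int = 2
    area_noise_cv: float = 0.05
    warp_knot_spacing: float = 8.0
    warp_slope_range: tuple = (0.8, 1.25)
    warp_slope_sd: float = 0.08
    voxel_spacing_mm: float = 0.4
    psf_sigma_mm: float = 0.3
    noise_sd_hu: float = 20.0
    hu_params: dict = field(default_factory=lambda: dict(DEFAULT_HU_PARAMS))


@dataclass
class PairedCase:
    """One cohort member: phantom spec + ground truth + emulated pullback,
    with the rendered image/labels/centerline when voxelized."""

    case_id: int
    spec: PhantomSpec
    truth: GroundTruth
    pullback: PullbackProfile
    warp: MonotoneWarp
    image: ImageVolume | None = None
    labels: LabelVolume | None = None
    centerline: Centerline | None = None


def _draw_spec(dist: CohortDistribution, rng: np.random.Generator, seed: int) -> PhantomSpec:
    u = rng.uniform
    L = u(*dist.length_range)
    r0 = u(*dist.lumen_radius_range)
    wall = u(*dist.base_wall_range)
    center = u(*dist.lesion_center_frac) * L
    halfw = u(*dist.lesion_halfwidth_range)
    stenoses = [Stenosis(center, 2 * halfw / 1.5, u(*dist.stenosis_severity_range))]
    # minor lumen undulations give the co-registration texture away from the lesion
    for c in (0.15 * L, 0.85 * L):
        stenoses.append(Stenosis(c, u(4.0, 8.0), u(*dist.minor_stenosis_severity)))
    thick = [WallThickening(center, 2 * halfw, u(*dist.wall_extra_range))]
    deposits = []
    lo, hi = center - halfw, center + halfw
    if rng.random() < dist.p_cp:
        dl = min(u(*dist.cp_length_range), hi - lo)
        d0 = u(lo, hi - dl)
        span = u(*dist.cp_span_range)
        deposits.append(Deposit(d0, d0 + dl, u(0.0, 180.0 - span), span, "CP"))
    if rng.random() < dist.p_lap:
        dl = min(u(*dist.lap_length_range), hi - lo)
        d0 = u(lo, hi - dl)
        span = u(*dist.lap_span_range)
        # LAP sectors live in [180, 360), CP in [0, 180): never overlapping
        deposits.append(Deposit(d0, d0 + dl, 180.0 + u(0.0, 180.0 - span), span, "LAP"))
    n_bif = rng.integers(0, dist.max_bifurcations + 1)
    bifs = sorted(u(0.2 * L, 0.8 * L) for _ in range(n_bif))
    bifs = [b for i, b in enumerate(bifs) if i == 0 or b - bifs[i - 1] > 5.0]
    helical = rng.random() < dist.p_helical
    return PhantomSpec(
        length_mm=L,
        centerline_kind="helical" if helical else "straight",
        helix_radius_mm=u(*dist.helix_radius_range) if helical else 0.0,
        helix_turns=u(0.2, 0.5) if helical else 0.0,
        lumen_radius_mm=r0,
        outer_radius_mm=r0 + wall,
        stenoses=stenoses,
        wall_thickenings=thick,
        deposits=deposits,
        bifurcations_mm=bifs,
        hu_params=dict(dist.hu_params),
        psf_sigma_mm=dist.psf_sigma_mm,
        noise_sd_hu=dist.noise_sd_hu,
        voxel_spacing_mm=dist.voxel_spacing_mm,
        seed=seed,
    )


def sample_cohort(
    n_lesions: int,
    spec_distribution: CohortDistribution | None = None,
    seed: int = 0,
    voxelize: bool = True,
) -> list[PairedCase]:
    """Draw a reproducible cohort of paired (phantom, pullback) cases.

    With ``voxelize=False`` only the analytic truth and the emulated pullback
    are produced (enough for co-registration studies); with ``voxelize=True``
    the full HU image and label volumes are rendered per case.
    """
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    dist = spec_distribution or CohortDistribution()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_lesions):
        spec_seed = int(rng.integers(0, 2**31 - 1))
        pull_seed = int(rng.integers(0, 2**31 - 1))
        warp_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        spec = _draw_spec(dist, rng, spec_seed)
        truth = GroundTruth(spec=spec, bifurcations_mm=list(spec.bifurcations_mm))
        warp = MonotoneWarp.random(
            spec.length_mm,
            warp_rng,
            dist.warp_knot_spacing,
            dist.warp_slope_range,
            dist.warp_slope_sd,
        )
        pullback = emulate_ivus_pullback(
            truth, area_noise_cv=dist.area_noise_cv, warp=warp, seed=pull_seed
        )
        case = PairedCase(
            case_id=i, spec=spec, truth=truth, pullback=pullback, warp=warp
        )
        if voxelize:
            image, labels, centerline, _ = make_phantom(spec)
            case.image, case.labels, case.centerline = image, labels, centerline
        cases.append(case)
    return cases
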