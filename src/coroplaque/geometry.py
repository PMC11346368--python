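"""Centerline geometry, cross-sectional area extraction and Simpson volumetrics.

The 1D backbone of the pipeline: a vessel is reduced to per-station
cross-sectional areas along its centerline (lumen, vessel = lumen + wall,
plaque = vessel - lumen), and volumes are obtained by numerically
integrating area profiles with a composite Simpson rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_WALL = 2


# ---------------------------------------------------------------------------
# containers


@dataclass
class ImageVolume:
    """A 3D scalar grid of HU values on a regular lattice.

    ``data`` is indexed ``[x, y, z]``; ``spacing`` and ``origin`` are in mm.
    World coordinates of voxel (i, j, k) are ``origin + spacing * (i, j, k)``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3D")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing


@dataclass
class LabelVolume(ImageVolume):
    """Label grid over the same lattice as its paired :class:`ImageVolume`.

    Labels: 0 background, 1 lumen, 2 wall.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(np.uint8)


@dataclass
class Centerline:
    """Ordered 3D polyline with cumulative arclength, zero at the ostial end."""

    points: np.ndarray
    arclength: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be (N, 3)")
        if self.arclength is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arclength = np.concatenate([[0.0], np.cumsum(seg)])
        self.arclength = np.asarray(self.arclength, dtype=float)
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences (one-sided at the ends)."""
        t = np.gradient(self.points, self.arclength, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arclength_mm": self.arclength,
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Centerline":
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        return cls(points=pts, arclength=df["arclength_mm"].to_numpy(dtype=float))


@dataclass
class CrossSectionSeries:
    """Per-station areas (mm^2) along the centerline, at arclengths ``arclength``.

    ``plaque_area == vessel_area - lumen_area`` holds exactly by construction.
    Component areas (cp/ncp/lap/excluded) partition the plaque area once the
    wall HU samples have been classified; they are NaN until then.
    ``wall_hu`` keeps the raw HU of every wall-labelled in-plane sample per
    station so characterization can classify them later.
    """

    arclength: np.ndarray
    lumen_area: np.ndarray
    vessel_area: np.ndarray
    cp_area: np.ndarray = None  # type: ignore[assignment]
    ncp_area: np.ndarray = None  # type: ignore[assignment]
    lap_area: np.ndarray = None  # type: ignore[assignment]
    excluded_area: np.ndarray = None  # type: ignore[assignment]
    wall_hu: list = None  # type: ignore[assignment]
    sample_area: float = np.nan  # mm^2 contributed by one in-plane sample
    n_excluded_stations: int = 0

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.lumen_area = np.asarray(self.lumen_area, dtype=float)
        self.vessel_area = np.asarray(self.vessel_area, dtype=float)
        n = len(self.arclength)
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("station arclengths must be strictly increasing")
        if np.any(self.vessel_area < self.lumen_area - 1e-12):
            raise ValueError("vessel area must be >= lumen area at every station")
        for name in ("cp_area", "ncp_area", "lap_area", "excluded_area"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(n, np.nan))
            else:
                setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def plaque_area(self) -> np.ndarray:
        return self.vessel_area - self.lumen_area

    @property
    def step(self) -> float:
        d = np.diff(self.arclength)
        if len(d) and not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("series is not uniformly spaced")
        return float(d[0]) if len(d) else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "arclength_mm": self.arclength,
                "lumen_area_mm2": self.lumen_area,
                "vessel_area_mm2": self.vessel_area,
                "plaque_area_mm2": self.plaque_area,
                "cp_area_mm2": self.cp_area,
                "ncp_area_mm2": self.ncp_area,
                "lap_area_mm2": self.lap_area,
                "excluded_area_mm2": self.excluded_area,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CrossSectionSeries":
        return cls(
            arclength=df["arclength_mm"].to_numpy(),
            lumen_area=df["lumen_area_mm2"].to_numpy(),
            vessel_area=df["vessel_area_mm2"].to_numpy(),
            cp_area=df["cp_area_mm2"].to_numpy(),
            ncp_area=df["ncp_area_mm2"].to_numpy(),
            lap_area=df["lap_area_mm2"].to_numpy(),
            excluded_area=df["excluded_area_mm2"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# operations


def resample_centerline(points: np.ndarray, step: float) -> Centerline:
    """Resample a polyline to arclength-uniform stations by linear interpolation.

    Endpoints are preserved; the final station falls at the original total
    arclength even when it is not a multiple of ``step``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2 or points.shape[1] != 3:
        raise ValueError("need at least two 3D points")
    if step <= 0:
        raise ValueError("step must be positive")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("duplicate consecutive points in centerline")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    # exactly uniform stations with spacing as close to `step` as possible
    # while preserving both endpoints
    n = max(int(round(total / step)), 1)
    stations = np.linspace(0.0, total, n + 1)
    new_pts = np.column_stack([np.interp(stations, s, points[:, k]) for k in range(3)])
    return Centerline(points=new_pts, arclength=stations)


def _plane_basis(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous in-plane orthonormal frames along the centerline.

    The first normal is seeded from whichever world axis is least aligned with
    the tangent; subsequent normals are propagated by projecting the previous
    one onto each new plane (discrete parallel transport), avoiding frame flips.
    """
    n_sta = len(tangents)
    u = np.empty((n_sta, 3))
    v = np.empty((n_sta, 3))
    seed = np.eye(3)[np.argmin(np.abs(tangents[0]))]
    prev = seed - np.dot(seed, tangents[0]) * tangents[0]
    prev /= np.linalg.norm(prev)
    for i, t in enumerate(tangents):
        w = prev - np.dot(prev, t) * t
        norm = np.linalg.norm(w)
        if norm < 1e-12:  # degenerate: tangent flipped by ~90 deg in one step
            w = seed - np.dot(seed, t) * t
            norm = np.linalg.norm(w)
        u[i] = w / norm
        v[i] = np.cross(t, u[i])
        prev = u[i]
    return u, v


def extract_cross_sections(
    image: ImageVolume,
    labels: LabelVolume,
    centerline: Centerline,
    step: float = 0.5,
    inplane_res: float = 0.1,
    half_width: float = 5.0,
) -> CrossSectionSeries:
    """Measure lumen/vessel areas on planes orthogonal to the centerline.

    At each station a square grid of pitch ``inplane_res`` spanning
    ``+/- half_width`` mm is laid in the plane normal to the local tangent.
    Membership is by label at the sample center (nearest voxel, no
    anti-aliasing); lumen area counts lumen-labelled samples, vessel area
    counts lumen or wall. HU values of wall samples are interpolated
    trilinearly and retained for plaque characterization.

    Stations whose sampling plane leaves the label volume entirely are
    excluded and counted in ``n_excluded_stations``.
    """
    if labels.data.shape != image.data.shape:
        raise ValueError("image and label lattices differ")
    cl = resample_centerline(centerline.points, step)
    tangents = cl.tangents()
    u, v = _plane_basis(tangents)

    m = int(np.floor(half_width / inplane_res))
    offs = np.arange(-m, m + 1) * inplane_res
    gu, gv = np.meshgrid(offs, offs, indexing="ij")
    gu = gu.ravel()
    gv = gv.ravel()
    samp_area = inplane_res * inplane_res

    keep_s, lum, ves, hu_lists = [], [], [], []
    n_excl = 0
    shape = np.asarray(labels.data.shape)
    for i in range(len(cl.arclength)):
        pts = cl.points[i] + gu[:, None] * u[i] + gv[:, None] * v[i]
        idx = labels.world_to_index(pts)
        inside = np.all((idx > -0.5) & (idx < shape - 0.5), axis=1)
        if not inside.any():
            n_excl += 1
            continue
        lab = np.zeros(len(pts), dtype=np.uint8)
        lab[inside] = map_coordinates(
            labels.data, idx[inside].T, order=0, mode="grid-constant", cval=0
        )
        wall = lab == LABEL_WALL
        lum.append(np.count_nonzero(lab == LABEL_LUMEN) * samp_area)
        ves.append((np.count_nonzero(wall) + np.count_nonzero(lab == LABEL_LUMEN)) * samp_area)
        if wall.any():
            hu = map_coordinates(
                image.data.astype(float), idx[wall].T, order=1, mode="nearest"
            )
        else:
            hu = np.empty(0)
        hu_lists.append(hu)
        keep_s.append(cl.arclength[i])

    series = CrossSectionSeries(
        arclength=np.asarray(keep_s),
        lumen_area=np.asarray(lum),
        vessel_area=np.asarray(ves),
        wall_hu=hu_lists,
        sample_area=samp_area,
        n_excluded_stations=n_excl,
    )
    return series


def simpson_volume(areas: np.ndarray, spacing: float) -> float:
    """Integrate a uniformly spaced area profile (mm^2) into a volume (mm^3).

    Composite Simpson 1/3 rule; when the number of intervals is odd, the last
    three intervals are handled by the Simpson 3/8 rule so every point
    contributes to exactly one panel.
    """
    a = np.asarray(areas, dtype=float)
    if a.ndim != 1 or len(a) < 3:
        raise ValueError("need at least 3 stations for Simpson integration")
    if np.any(a < 0):
        raise ValueError("negative area input")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n_int = len(a) - 1
    h = float(spacing)
    if n_int % 2 == 0:
        return float(_simpson13(a, h))
    if n_int == 3:
        return float(_simpson38(a, h))
    # even-count head + 3/8 tail over the final three intervals
    return float(_simpson13(a[: n_int - 3 + 1], h) + _simpson38(a[n_int - 3 :], h))


def _simpson13(a: np.ndarray, h: float) -> float:
    return h / 3.0 * (a[0] + a[-1] + 4.0 * a[1:-1:2].sum() + 2.0 * a[2:-1:2].sum())


def _simpson38(a: np.ndarray, h: float) -> float:
    assert len(a) == 4
    return 3.0 * h / 8.0 * (a[0] + 3.0 * a[1] + 3.0 * a[2] + a[3])


def resample_profile(
    positions: np.ndarray, values: np.ndarray, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample an area profile onto a uniform grid spanning its range.

    Used before Simpson integration when stations are not uniformly spaced or
    when integrating over a sub-interval whose endpoints fall between stations.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    lo, hi = positions[0], positions[-1]
    n = max(int(np.ceil((hi - lo) / step)), 2)
    grid = np.linspace(lo, hi, n + 1)
    return grid, np.interp(grid, positions, values)


def interval_volume(
    positions: np.ndarray,
    values: np.ndarray,
    start: float,
    end: float,
    step: float = 0.5,
) -> float:
    """Simpson volume of a profile restricted to [start, end].

    The profile is linearly resampled to a uniform grid over the interval
    (composite Simpson needs uniform nodes); endpoints are clamped to the
    profile's coverage.
    """
    if end <= start:
        raise ValueError("interval must have positive length")
    positions = np.asarray(positions, dtype=float)
    lo = max(start, positions[0])
    hi = min(end, positions[-1])
    if hi <= lo:
        raise ValueError("interval outside profile coverage")
    n = max(int(np.ceil((hi - lo) / step)), 2)
    grid = np.linspace(lo, hi, n + 1)
    vals = np.interp(grid, positions, np.asarray(values, dtype=float))
    return simpson_volume(np.clip(vals, 0.0, None), grid[1] - grid[0])
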