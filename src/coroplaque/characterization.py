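"""Plaque component characterization by Hounsfield-unit windows.

Wall tissue is partitioned into low-attenuation plaque (LAP, [-30, 30) HU),
non-calcified plaque (NCP, [30, CP-threshold) HU) and calcified plaque
(CP, >= threshold). The CP threshold adapts to lumen contrast: it is the
maximum of 350 HU and the mean lumen intensity plus one sample SD, so a
brightly opacified lumen pushes the calcium cutoff upward. Samples below
-30 HU fall outside every window and are excluded from total plaque volume.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import binary_erosion

from .geometry import (
    LABEL_LUMEN,
    CrossSectionSeries,
    ImageVolume,
    LabelVolume,
    simpson_volume,
)

LAP_LOW = -30.0
LAP_HIGH = 30.0
CP_FLOOR = 350.0

COMPONENT_LAP = "LAP"
COMPONENT_NCP = "NCP"
COMPONENT_CP = "CP"
COMPONENT_EXCLUDED = "excluded"


@dataclass(frozen=True)
class ComponentThresholds:
    """HU window edges for one vessel. ``cp_threshold`` is adaptive, >= 350."""

    cp_threshold: float
    lap_low: float = LAP_LOW
    lap_high: float = LAP_HIGH

    def __post_init__(self) -> None:
        if self.cp_threshold < CP_FLOOR:
            raise ValueError(f"cp_threshold {self.cp_threshold} below floor {CP_FLOOR}")
        if not (self.lap_low < self.lap_high <= self.cp_threshold):
            raise ValueError("require lap_low < lap_high <= cp_threshold")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlaqueVolumes:
    """Component volumes (mm^3) and percent composition of one vessel/lesion.

    TPV = CP + NCP with NCP reported as TPV - CP; LAP is a sub-component of
    NCP. Wall tissue below -30 HU is tallied in ``excluded_below_lap`` and
    does not enter TPV. Percentages are None when TPV is zero.
    """

    tpv: float
    cp: float
    ncp: float
    lap: float
    excluded_below_lap: float
    lumen: float = np.nan
    vessel: float = np.nan
    pct_cp: float | None = None
    pct_ncp: float | None = None
    pct_lap: float | None = None
    thresholds: ComponentThresholds | None = None

    def as_dict(self) -> dict:
        d = {
            "tpv_mm3": self.tpv,
            "cp_mm3": self.cp,
            "ncp_mm3": self.ncp,
            "lap_mm3": self.lap,
            "excluded_below_lap_mm3": self.excluded_below_lap,
            "lumen_mm3": self.lumen,
            "vessel_mm3": self.vessel,
            "pct_cp": self.pct_cp,
            "pct_ncp": self.pct_ncp,
            "pct_lap": self.pct_lap,
        }
        if self.thresholds is not None:
            d["thresholds"] = self.thresholds.as_dict()
        return d


def adaptive_cp_threshold(lumen_hu_samples: np.ndarray) -> float:
    """CP threshold = max(350, lumen mean + 1 sample SD (n-1 denominator))."""
    hu = np.asarray(lumen_hu_samples, dtype=float).ravel()
    if hu.size < 2:
        raise ValueError("need at least 2 lumen HU samples for the adaptive threshold")
    return float(max(CP_FLOOR, hu.mean() + hu.std(ddof=1)))


def lumen_hu_samples(image: ImageVolume, labels: LabelVolume) -> np.ndarray:
    """Lumen-voxel HU values after one-voxel erosion of the lumen mask.

    Erosion suppresses partial-volume contamination at the lumen border; if
    it empties the mask (very small lumen) the uneroded mask is used.
    """
    mask = labels.data == LABEL_LUMEN
    eroded = binary_erosion(mask)
    if not eroded.any():
        eroded = mask
    return np.asarray(image.data, dtype=float)[eroded]


def classify_wall_sample(hu, thresholds: ComponentThresholds) -> np.ndarray:
    """Classify wall HU values into component labels.

    Half-open windows make the partition exact: LAP [-30, 30), NCP
    [30, cp_threshold), CP [cp_threshold, inf); below -30 -> excluded.
    Accepts a scalar (returns a str) or an array (returns an object array).
    """
    arr = np.asarray(hu, dtype=float)
    out = np.empty(arr.shape, dtype=object)
    out[arr < thresholds.lap_low] = COMPONENT_EXCLUDED
    out[(arr >= thresholds.lap_low) & (arr < thresholds.lap_high)] = COMPONENT_LAP
    out[(arr >= thresholds.lap_high) & (arr < thresholds.cp_threshold)] = COMPONENT_NCP
    out[arr >= thresholds.cp_threshold] = COMPONENT_CP
    if np.isscalar(hu) or arr.ndim == 0:
        return out[()]
    return out


def classify_series(series: CrossSectionSeries, thresholds: ComponentThresholds) -> CrossSectionSeries:
    """Fill per-station component areas by classifying retained wall HU samples.

    Each wall sample carries ``series.sample_area`` mm^2, so
    cp + ncp + lap + excluded equals the plaque area exactly at every station.
    """
    if series.wall_hu is None:
        raise ValueError("series has no retained wall HU samples")
    n = len(series.arclength)
    if len(series.wall_hu) != n:
        raise ValueError("wall_hu length inconsistent with station count")
    a = series.sample_area
    for i, hu in enumerate(series.wall_hu):
        hu = np.asarray(hu, dtype=float)
        series.cp_area[i] = np.count_nonzero(hu >= thresholds.cp_threshold) * a
        series.lap_area[i] = (
            np.count_nonzero((hu >= thresholds.lap_low) & (hu < thresholds.lap_high)) * a
        )
        series.ncp_area[i] = (
            np.count_nonzero((hu >= thresholds.lap_high) & (hu < thresholds.cp_threshold)) * a
        )
        series.excluded_area[i] = np.count_nonzero(hu < thresholds.lap_low) * a
    return series


def component_volumes(
    series: CrossSectionSeries,
    spacing: float | None = None,
    thresholds: ComponentThresholds | None = None,
) -> PlaqueVolumes:
    """Integrate classified component area profiles into a volume report.

    TPV integrates cp + ncp + lap (the in-window plaque); the reported NCP is
    TPV - CP so that LAP remains a sub-component of NCP and CP/NCP
    percentages sum to 100.
    """
    for name in ("cp_area", "ncp_area", "lap_area", "excluded_area"):
        arr = getattr(series, name)
        if len(arr) != len(series.arclength):
            raise ValueError(f"{name} length inconsistent with station count")
        if np.any(np.isnan(arr)):
            raise ValueError("series has unclassified component areas")
    h = spacing if spacing is not None else series.step
    in_window = series.cp_area + series.ncp_area + series.lap_area
    tpv = simpson_volume(in_window, h)
    cp = simpson_volume(series.cp_area, h)
    lap = simpson_volume(series.lap_area, h)
    ncp = tpv - cp
    excl = simpson_volume(series.excluded_area, h)
    if tpv > 0:
        pct = (100.0 * cp / tpv, 100.0 * ncp / tpv, 100.0 * lap / tpv)
    else:
        pct = (None, None, None)
    return PlaqueVolumes(
        tpv=tpv,
        cp=cp,
        ncp=ncp,
        lap=lap,
        excluded_below_lap=excl,
        lumen=simpson_volume(series.lumen_area, h),
        vessel=simpson_volume(series.vessel_area, h),
        pct_cp=pct[0],
        pct_ncp=pct[1],
        pct_lap=pct[2],
        thresholds=thresholds,
    )
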