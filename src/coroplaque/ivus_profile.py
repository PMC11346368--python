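"""IVUS pullback quantification: per-mm areas, plaque burden, lesions.

The pullback is a 1D sequence of cross-sectional measurements at 1 mm
increments: lumen area and vessel area (external elastic membrane, EEM).
Plaque-plus-media area is vessel minus lumen; plaque burden is that
difference as a fraction of vessel area. A lesion is any contiguous segment
with plaque burden >= 40% that is at least 2 mm long. Qualitative
calcified/attenuated findings are angular arcs; their areas follow the
full-thickness assumption: the surface arc is taken to occupy the entire
wall thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import simpson_volume

BURDEN_THRESHOLD_PCT = 40.0
MIN_LESION_LENGTH_MM = 2.0

ANCHOR_START = "start"
ANCHOR_END = "end"
ANCHOR_BIFURCATION = "bifurcation"


@dataclass
class PullbackProfile:
    """Per-station IVUS measurements at uniform 1 mm pullback increments.

    ``anchors`` is a list of (position_mm, kind) landmarks containing exactly
    one start, one end, and any bifurcations strictly between them.
    """

    position: np.ndarray
    lumen_area: np.ndarray
    vessel_area: np.ndarray
    calc_arc_deg: np.ndarray
    atten_arc_deg: np.ndarray
    anchors: list = field(default_factory=list)
    spacing: float = 1.0

    def __post_init__(self) -> None:
        for name in ("position", "lumen_area", "vessel_area", "calc_arc_deg", "atten_arc_deg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        d = np.diff(self.position)
        if len(d) and not np.allclose(d, self.spacing, atol=1e-9):
            raise ValueError("stations must be at uniform spacing")
        if np.any(self.lumen_area < 0) or np.any(self.vessel_area < self.lumen_area - 1e-12):
            raise ValueError("require vessel >= lumen >= 0 at every station")
        for arc in (self.calc_arc_deg, self.atten_arc_deg):
            if np.any((arc < 0) | (arc > 360)):
                raise ValueError("arcs must lie in [0, 360] degrees")
        kinds = [k for _, k in self.anchors]
        if self.anchors:
            if kinds.count(ANCHOR_START) != 1 or kinds.count(ANCHOR_END) != 1:
                raise ValueError("anchors must contain exactly one start and one end")
            start = next(p for p, k in self.anchors if k == ANCHOR_START)
            end = next(p for p, k in self.anchors if k == ANCHOR_END)
            for p, k in self.anchors:
                if k == ANCHOR_BIFURCATION and not (start < p < end):
                    raise ValueError("bifurcation anchors must lie strictly inside the pullback")

    @property
    def anchor_positions(self) -> np.ndarray:
        """Anchor positions in canonical order: start, bifurcations, end."""
        start = [p for p, k in self.anchors if k == ANCHOR_START]
        bifs = sorted(p for p, k in self.anchors if k == ANCHOR_BIFURCATION)
        end = [p for p, k in self.anchors if k == ANCHOR_END]
        return np.asarray(start + bifs + end, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_mm": self.position,
                "lumen_area_mm2": self.lumen_area,
                "vessel_area_mm2": self.vessel_area,
                "calc_arc_deg": self.calc_arc_deg,
                "atten_arc_deg": self.atten_arc_deg,
            }
        )

    def write(self, csv_path: str | Path) -> None:
        """Write stations as CSV plus a JSON sidecar of anchors."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".anchors.json")
        sidecar.write_text(
            json.dumps([{"position_mm": float(p), "kind": k} for p, k in self.anchors], indent=1)
        )

    @classmethod
    def read(cls, csv_path: str | Path) -> "PullbackProfile":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        sidecar = csv_path.with_suffix(".anchors.json")
        anchors = []
        if sidecar.exists():
            anchors = [(a["position_mm"], a["kind"]) for a in json.loads(sidecar.read_text())]
        return cls(
            position=df["station_mm"].to_numpy(),
            lumen_area=df["lumen_area_mm2"].to_numpy(),
            vessel_area=df["vessel_area_mm2"].to_numpy(),
            calc_arc_deg=df["calc_arc_deg"].to_numpy(),
            atten_arc_deg=df["atten_arc_deg"].to_numpy(),
            anchors=anchors,
        )


@dataclass
class Lesion:
    """A contiguous pullback segment with plaque burden >= 40% and length >= 2 mm.

    ``start``/``end`` are the first/last qualifying station positions; a run
    of k stations at 1 mm spacing spans (k - 1) mm, so >= 2 mm requires at
    least 3 consecutive qualifying stations.
    """

    start: float
    end: float
    max_burden_pct: float
    index_start: int
    index_end: int  # inclusive

    @property
    def length(self) -> float:
        return self.end - self.start

    def as_dict(self) -> dict:
        return {
            "start_mm": self.start,
            "end_mm": self.end,
            "length_mm": self.length,
            "max_burden_pct": self.max_burden_pct,
            "index_start": self.index_start,
            "index_end": self.index_end,
        }


def plaque_burden_profile(profile: PullbackProfile) -> np.ndarray:
    """Per-station plaque burden, 100 * (vessel - lumen) / vessel, in percent.

    Stations with zero vessel area yield NaN.
    """
    bad = np.nonzero(profile.lumen_area > profile.vessel_area + 1e-12)[0]
    if bad.size:
        raise ValueError(f"lumen area exceeds vessel area at station {bad[0]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        burden = 100.0 * (profile.vessel_area - profile.lumen_area) / profile.vessel_area
    burden[profile.vessel_area == 0] = np.nan
    return burden


def detect_lesions(
    burden: np.ndarray,
    spacing: float = 1.0,
    positions: np.ndarray | None = None,
    threshold_pct: float = BURDEN_THRESHOLD_PCT,
    min_length: float = MIN_LESION_LENGTH_MM,
) -> list[Lesion]:
    """Find maximal runs of stations with burden >= threshold, length >= 2 mm.

    Runs are strictly contiguous (no gap bridging); a run of k stations spans
    (k - 1) * spacing mm. Lesions are returned proximal to distal.
    """
    burden = np.asarray(burden, dtype=float)
    if positions is None:
        positions = np.arange(len(burden)) * spacing
    qual = np.nan_to_num(burden, nan=-np.inf) >= threshold_pct
    lesions: list[Lesion] = []
    i = 0
    n = len(qual)
    while i < n:
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qual[j + 1]:
            j += 1
        length = positions[j] - positions[i]
        if length >= min_length - 1e-9:
            lesions.append(
                Lesion(
                    start=float(positions[i]),
                    end=float(positions[j]),
                    max_burden_pct=float(np.nanmax(burden[i : j + 1])),
                    index_start=i,
                    index_end=j,
                )
            )
        i = j + 1
    return lesions


def qualitative_component_areas(profile: PullbackProfile) -> tuple[np.ndarray, np.ndarray]:
    """Calcified and attenuated plaque areas under the full-thickness assumption.

    The angular arc seen at the plaque surface is assumed to occupy the whole
    wall, so component area = (arc / 360) * (vessel - lumen). Returns
    (calcified areas, attenuated areas) in mm^2 per station.
    """
    total_arc = profile.calc_arc_deg + profile.atten_arc_deg
    bad = np.nonzero(total_arc > 360.0 + 1e-9)[0]
    if bad.size:
        raise ValueError(f"calcified + attenuated arcs exceed 360 deg at station {bad[0]}")
    plaque = profile.vessel_area - profile.lumen_area
    return profile.calc_arc_deg / 360.0 * plaque, profile.atten_arc_deg / 360.0 * plaque


def ivus_lesion_volumes(profile: PullbackProfile, lesions: list[Lesion]) -> pd.DataFrame:
    """Simpson-rule volumes of each area profile restricted to each lesion.

    One row per lesion: lumen, vessel, plaque (plaque-plus-media), calcified
    and attenuated volumes in mm^3.
    """
    calc_area, atten_area = qualitative_component_areas(profile)
    plaque = profile.vessel_area - profile.lumen_area
    rows = []
    for les in lesions:
        i0, i1 = les.index_start, les.index_end
        if i0 < 0 or i1 >= len(profile.position):
            raise ValueError("lesion outside pullback range")
        if i1 - i0 < 2:
            raise ValueError("lesion interval too short to integrate")
        sl = slice(i0, i1 + 1)
        h = profile.spacing
        rows.append(
            {
                "start_mm": les.start,
                "end_mm": les.end,
                "length_mm": les.length,
                "max_burden_pct": les.max_burden_pct,
                "lumen_mm3": simpson_volume(profile.lumen_area[sl], h),
                "vessel_mm3": simpson_volume(profile.vessel_area[sl], h),
                "plaque_mm3": simpson_volume(plaque[sl], h),
                "cp_mm3": simpson_volume(calc_area[sl], h),
                "attenuated_mm3": simpson_volume(atten_area[sl], h),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "start_mm",
            "end_mm",
            "length_mm",
            "max_burden_pct",
            "lumen_mm3",
            "vessel_mm3",
            "plaque_mm3",
            "cp_mm3",
            "attenuated_mm3",
        ],
    )
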