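"""1D co-registration of IVUS pullback positions to CCTA centerline arclength.

The pullback start/end and bifurcation landmarks exist on both sides and
anchor a monotone piecewise-linear map from pullback distance to arclength.
Optional refinement subdivides each inter-anchor segment with extra knots
taken from a banded, slope-limited dynamic alignment of the two (z-scored,
uniformly resampled) lumen-area profiles; anchors are never moved. Lesion intervals detected on IVUS are
mapped through the warp to delimit the CCTA volume extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .characterization import ComponentThresholds, component_volumes
from .geometry import CrossSectionSeries
from .ivus_profile import (
    ANCHOR_BIFURCATION,
    ANCHOR_END,
    ANCHOR_START,
    Lesion,
    PullbackProfile,
    detect_lesions,
    ivus_lesion_volumes,
    plaque_burden_profile,
)


@dataclass
class WarpMap:
    """Monotone piecewise-linear map, IVUS pullback mm -> CCTA arclength mm.

    Passes exactly through every anchor pair; domain is the pullback range.
    """

    knots_ivus: np.ndarray
    knots_ccta: np.ndarray
    anchor_ivus: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.knots_ivus = np.asarray(self.knots_ivus, dtype=float)
        self.knots_ccta = np.asarray(self.knots_ccta, dtype=float)
        if len(self.knots_ivus) < 2:
            raise ValueError("warp needs at least two knots")
        if np.any(np.diff(self.knots_ivus) <= 0) or np.any(np.diff(self.knots_ccta) <= 0):
            raise ValueError("warp knots must be strictly increasing")
        if self.anchor_ivus is None:
            self.anchor_ivus = self.knots_ivus.copy()
        self.anchor_ivus = np.asarray(self.anchor_ivus, dtype=float)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots_ivus[0]), float(self.knots_ivus[-1])

    def __call__(self, p):
        lo, hi = self.domain
        p_arr = np.asarray(p, dtype=float)
        if np.any(p_arr < lo - 1e-9) or np.any(p_arr > hi + 1e-9):
            raise ValueError("position outside warp domain")
        return np.interp(p_arr, self.knots_ivus, self.knots_ccta)

    def inverse(self, c):
        return np.interp(np.asarray(c, dtype=float), self.knots_ccta, self.knots_ivus)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "knots_ivus_mm": self.knots_ivus.tolist(),
                    "knots_ccta_mm": self.knots_ccta.tolist(),
                    "anchor_ivus_mm": self.anchor_ivus.tolist(),
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "WarpMap":
        d = json.loads(Path(path).read_text())
        return cls(
            knots_ivus=d["knots_ivus_mm"],
            knots_ccta=d["knots_ccta_mm"],
            anchor_ivus=d.get("anchor_ivus_mm"),
        )


def _ordered_anchors(anchors: list) -> np.ndarray:
    start = [p for p, k in anchors if k == ANCHOR_START]
    bifs = sorted(p for p, k in anchors if k == ANCHOR_BIFURCATION)
    end = [p for p, k in anchors if k == ANCHOR_END]
    if len(start) != 1 or len(end) != 1:
        raise ValueError("anchors must contain exactly one start and one end")
    pos = np.asarray(start + bifs + end, dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("anchors out of order or degenerate segment")
    return pos


def build_warp(
    ivus: PullbackProfile,
    ccta: CrossSectionSeries,
    ccta_anchors: list,
    refine: bool = False,
    window_mm: float = 5.0,
    pitch_mm: float = 0.25,
    knot_spacing_mm: float = 5.0,
    max_shift_frac: float = 0.2,
) -> WarpMap:
    """Anchor the pullback to the centerline; optionally refine between anchors.

    ``ccta_anchors`` is a list of (arclength mm, kind) matching the pullback's
    anchors one-to-one in kind and order. The base map is piecewise-linear
    through the anchor pairs. With ``refine``, each inter-anchor segment is
    subdivided by a banded dynamic alignment of the z-scored lumen-area
    profiles (resampled at ``pitch_mm``), with the search band limited to
    ±``max_shift_frac`` of the segment length around the base map; interior
    knots are sampled from the optimal path every ``knot_spacing_mm``. The
    result is always anchor-exact and strictly increasing.
    """
    p_anchor = _ordered_anchors(ivus.anchors)
    c_anchor = _ordered_anchors(ccta_anchors)
    if len(p_anchor) != len(c_anchor):
        raise ValueError(
            f"anchor count mismatch: {len(p_anchor)} on IVUS vs {len(c_anchor)} on CCTA"
        )
    if not refine:
        return WarpMap(p_anchor, c_anchor, anchor_ivus=p_anchor)

    # uniformly resampled, z-scored lumen profiles on both sides
    def _zscore(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v * 0.0

    p_grid = np.arange(ivus.position[0], ivus.position[-1] + 1e-9, pitch_mm)
    ivus_prof = _zscore(np.interp(p_grid, ivus.position, ivus.lumen_area))
    c_grid = np.arange(ccta.arclength[0], ccta.arclength[-1] + 1e-9, pitch_mm)
    ccta_prof = _zscore(np.interp(c_grid, ccta.arclength, ccta.lumen_area))

    knots_p = [p_anchor[0]]
    knots_c = [c_anchor[0]]
    for seg in range(len(p_anchor) - 1):
        p0, p1 = p_anchor[seg], p_anchor[seg + 1]
        c0, c1 = c_anchor[seg], c_anchor[seg + 1]
        pk, ck = _refine_segment(
            p0, p1, c0, c1,
            p_grid, ivus_prof, c_grid, ccta_prof,
            pitch_mm, knot_spacing_mm, max_shift_frac,
        )
        for a, b in zip(pk, ck):
            if a > knots_p[-1] + 1e-9 and b > knots_c[-1] + 1e-9:
                knots_p.append(a)
                knots_c.append(b)
        knots_p.append(p1)
        knots_c.append(c1)
    return WarpMap(np.asarray(knots_p), np.asarray(knots_c), anchor_ivus=p_anchor)


def _refine_segment(
    p0, p1, c0, c1,
    p_grid, ivus_prof, c_grid, ccta_prof,
    pitch, knot_spacing, max_shift_frac,
):
    """Interior knots for one inter-anchor segment by banded, slope-limited
    dynamic-time-warping of the z-scored lumen profiles.

    States are (pullback sample i, offset j) where the mapped arclength is
    the base linear map plus ``offsets[j]``; transitions keep the offset or
    move it by one pitch (elastic, monotone on average), with a small
    elasticity cost and a quadratic pull toward the base map so featureless
    stretches stay anchored-linear. Returns interior knots sampled from the
    optimal path every ``knot_spacing`` mm, with strictly increasing outputs.
    """
    seg_len = p1 - p0
    if seg_len < 2 * knot_spacing:
        return [], []
    slope = (c1 - c0) / seg_len
    n = max(int(round(seg_len / pitch)), 4)
    P = np.linspace(p0, p1, n + 1)
    iv = np.interp(P, p_grid, ivus_prof)
    max_shift = max_shift_frac * (c1 - c0)
    m_half = max(int(round(max_shift / pitch)), 1)
    offsets = np.arange(-m_half, m_half + 1) * pitch
    n_m = len(offsets)
    c_base = c0 + slope * (P - p0)
    # local cost: profile mismatch + pull toward the base map
    cc = np.interp(
        (c_base[:, None] + offsets[None, :]).ravel(), c_grid, ccta_prof
    ).reshape(n + 1, n_m)
    cost = (iv[:, None] - cc) ** 2 + 0.5 * (offsets[None, :] / (max_shift + 1e-9)) ** 2
    elastic = 0.1  # cost of changing the offset by one pitch
    BIG = 1e12
    acc = np.full((n + 1, n_m), BIG)
    back = np.zeros((n + 1, n_m), dtype=np.int8)
    j0 = m_half  # anchors are exact: start and end at zero offset
    acc[0, j0] = cost[0, j0]
    for i in range(1, n + 1):
        prev = acc[i - 1]
        stay = prev
        up = np.concatenate([[BIG], prev[:-1]])     # offset increased by one
        down = np.concatenate([prev[1:], [BIG]])    # offset decreased by one
        choices = np.stack([stay, up + elastic, down + elastic])
        pick = np.argmin(choices, axis=0)
        acc[i] = np.take_along_axis(choices, pick[None, :], 0)[0] + cost[i]
        back[i] = pick
    # backtrack from the zero-offset end state
    path = np.empty(n + 1, dtype=int)
    path[n] = j0
    for i in range(n, 0, -1):
        move = back[i, path[i]]
        path[i - 1] = path[i] - 1 if move == 1 else path[i] + 1 if move == 2 else path[i]
    c_path = c_base + offsets[path]
    n_knots = int(seg_len / knot_spacing) - 1
    pk, ck = [], []
    for k in range(1, n_knots + 1):
        p = p0 + seg_len * k / (n_knots + 1)
        i = int(round((p - p0) / (seg_len / n)))
        pk.append(float(P[i]))
        ck.append(float(c_path[i]))
    return pk, ck


def map_interval(warp: WarpMap, start: float, end: float) -> tuple[float, float]:
    """Map an IVUS interval endpoint-wise into CCTA arclength."""
    if end <= start:
        raise ValueError("interval must have positive length")
    lo, hi = warp.domain
    if start < lo - 1e-9 or end > hi + 1e-9:
        raise ValueError("interval outside warp domain")
    return float(warp(start)), float(warp(end))


def lesion_matched_volumes(
    ivus: PullbackProfile,
    ccta: CrossSectionSeries,
    warp: WarpMap,
    lesions: list[Lesion] | None = None,
    thresholds: ComponentThresholds | None = None,
    case_id: int | None = None,
) -> pd.DataFrame:
    """Per-lesion paired volumes: IVUS over [start, end], CCTA over the mapped
    interval. One row per lesion with both modalities' lumen/vessel/TPV/CP/
    NCP/LAP(attenuated) volumes; lesions whose mapped interval falls outside
    the CCTA series coverage are dropped and flagged in the ``excluded``
    column of an accompanying record.
    """
    if lesions is None:
        lesions = detect_lesions(plaque_burden_profile(ivus), spacing=ivus.spacing)
    ivus_vols = ivus_lesion_volumes(ivus, lesions)
    rows = []
    for i, les in enumerate(lesions):
        c_start, c_end = map_interval(warp, les.start, les.end)
        cov_lo, cov_hi = ccta.arclength[0], ccta.arclength[-1]
        if c_end <= cov_lo or c_start >= cov_hi:
            rows.append(
                {"case_id": case_id, "lesion": i, "excluded": True,
                 "exclusion_reason": "mapped interval outside CCTA coverage"}
            )
            continue
        row = {
            "case_id": case_id,
            "lesion": i,
            "excluded": False,
            "exclusion_reason": "",
            "ivus_start_mm": les.start,
            "ivus_end_mm": les.end,
            "ccta_start_mm": c_start,
            "ccta_end_mm": c_end,
            "length_mm": les.length,
            "max_burden_pct": les.max_burden_pct,
        }
        iv = ivus_vols.iloc[i]
        row.update(
            {
                "ivus_lumen_mm3": iv["lumen_mm3"],
                "ivus_vessel_mm3": iv["vessel_mm3"],
                "ivus_tpv_mm3": iv["plaque_mm3"],
                "ivus_cp_mm3": iv["cp_mm3"],
                "ivus_lap_mm3": iv["attenuated_mm3"],
            }
        )
        row["ivus_ncp_mm3"] = row["ivus_tpv_mm3"] - row["ivus_cp_mm3"]
        sub = _slice_series(ccta, c_start, c_end)
        vols = component_volumes(sub, thresholds=thresholds)
        row.update(
            {
                "ccta_lumen_mm3": vols.lumen,
                "ccta_vessel_mm3": vols.vessel,
                "ccta_tpv_mm3": vols.tpv,
                "ccta_cp_mm3": vols.cp,
                "ccta_ncp_mm3": vols.ncp,
                "ccta_lap_mm3": vols.lap,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _slice_series(ccta: CrossSectionSeries, start: float, end: float) -> CrossSectionSeries:
    """Restrict a classified series to [start, end] on a uniform grid by
    linear interpolation of each area profile (endpoints clamped to
    coverage)."""
    s = ccta.arclength
    lo = max(start, float(s[0]))
    hi = min(end, float(s[-1]))
    step = ccta.step
    n = max(int(np.ceil((hi - lo) / step)), 2)
    grid = np.linspace(lo, hi, n + 1)

    def interp(v):
        return np.interp(grid, s, np.asarray(v, dtype=float))

    return CrossSectionSeries(
        arclength=grid,
        lumen_area=interp(ccta.lumen_area),
        vessel_area=np.maximum(interp(ccta.vessel_area), interp(ccta.lumen_area)),
        cp_area=interp(ccta.cp_area),
        ncp_area=interp(ccta.ncp_area),
        lap_area=interp(ccta.lap_area),
        excluded_area=interp(ccta.excluded_area),
    )
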