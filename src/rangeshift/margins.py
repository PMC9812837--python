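"""From georeferenced surveys to range-margin and range-periphery series.

The functions here take a survey table — one row per visited site and survey
period, with planar (projected) coordinates in km and a 0/1 detection — and
produce the two regression inputs of a range-shift analysis:

* a *margin series* of (year, distance) pairs, the distance of each selected
  range-margin occurrence from a fixed reference range centre, and
* a *periphery series* of (year, detected) records: every survey site falling
  inside the minimum enclosing circle of a period's margin occurrences.

Margin occurrences are selected either by a distance percentile (suitable for
range-wide surveys) or as the k most distant sites (suitable for surveys
restricted to the periphery), optionally restricted to sites north of the
centre. Surveys of heterogeneous effort are first thinned to one record per
grid cell.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DataFormatError,
    InsufficientDataError,
    InvalidConfigurationError,
)
from .geometry import Circle, distance_km, minimum_enclosing_circle

__all__ = [
    "GridSpec",
    "RangeCenter",
    "SURVEY_COLUMNS",
    "validate_survey",
    "resample_to_grid",
    "range_center",
    "distance_km",
    "distances_from",
    "select_margin_percentile",
    "select_margin_topk",
    "select_margins",
    "minimum_enclosing_circle",
    "extract_periphery",
    "build_margin_series",
    "parse_period_year",
    "default_year_map",
]

SURVEY_COLUMNS = ("site_id", "x", "y", "period", "detected")


@dataclass(frozen=True)
class GridSpec:
    """Square resampling grid: ``cell_size`` km, anchored at (origin_x, origin_y)."""

    cell_size: float = 10.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self):
        if not self.cell_size > 0:
            raise InvalidConfigurationError(
                f"cell_size must be positive, got {self.cell_size}"
            )

    def cell_index(self, x, y):
        ix = np.floor((np.asarray(x, float) - self.origin_x) / self.cell_size)
        iy = np.floor((np.asarray(y, float) - self.origin_y) / self.cell_size)
        return ix.astype(int), iy.astype(int)


@dataclass(frozen=True)
class RangeCenter:
    """Reference range centre (km) against which margin distances are measured."""

    x: float
    y: float
    reference_period: str = "1985"


def validate_survey(records: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a survey table; returns the frame."""
    missing = [c for c in SURVEY_COLUMNS if c not in records.columns]
    if missing:
        raise DataFormatError(f"survey table lacks columns {missing}")
    bad = ~np.isfinite(records["x"].to_numpy(float)) | ~np.isfinite(
        records["y"].to_numpy(float)
    )
    if bad.any():
        rows = list(np.nonzero(bad)[0][:5])
        raise DataFormatError(f"non-finite coordinates at rows {rows}")
    det = records["detected"].to_numpy()
    if not np.isin(det, (0, 1, True, False)).all():
        raise DataFormatError("detected must be 0/1")
    return records


def resample_to_grid(
    records: pd.DataFrame, grid: GridSpec, seed: int
) -> pd.DataFrame:
    """Thin a survey to at most one record per (grid cell, period).

    Detections and non-detections are drawn independently per cell; when a
    cell holds both, the surviving record is a detection, so thinning never
    masks an occurrence behind a non-detection. Deterministic given ``seed``.
    """
    if not isinstance(grid, GridSpec):
        grid = GridSpec(*grid) if np.iterable(grid) else GridSpec(grid)
    if len(records) == 0:
        return records.copy()
    validate_survey(records)
    rng = np.random.default_rng(seed)
    ix, iy = grid.cell_index(records["x"], records["y"])
    df = records.copy()
    df["_ix"], df["_iy"] = ix, iy
    keep = []
    for (_, _, _), group in df.groupby(["_ix", "_iy", "period"], sort=True):
        pos = group.index[group["detected"].astype(bool)]
        neg = group.index[~group["detected"].astype(bool)]
        if len(pos):
            keep.append(pos[rng.integers(len(pos))])
        elif len(neg):
            keep.append(neg[rng.integers(len(neg))])
    out = records.loc[sorted(keep)].copy()
    out.attrs["grid"] = grid
    out.attrs["seed"] = seed
    return out


def range_center(points, reference_period: str = "1985") -> RangeCenter:
    """Coordinate-wise mean (centroid) of a set of (x, y) points."""
    if isinstance(points, pd.DataFrame):
        pts = points[["x", "y"]].to_numpy(float)
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise InsufficientDataError("range centre of an empty point set")
    cx, cy = pts.mean(axis=0)
    return RangeCenter(float(cx), float(cy), reference_period)


def distances_from(records: pd.DataFrame, center: RangeCenter) -> np.ndarray:
    """Distance (km) of each record from the reference centre."""
    return np.hypot(
        records["x"].to_numpy(float) - center.x,
        records["y"].to_numpy(float) - center.y,
    )


def select_margin_percentile(
    occurrences: pd.DataFrame,
    center: RangeCenter,
    q: float = 0.95,
    northern_only: bool = True,
    quantile_on: str = "all",
) -> pd.DataFrame:
    """Occurrences strictly farther from ``center`` than the q-quantile of distances.

    The quantile (linear interpolation between order statistics) is taken over
    all of the period's occurrence distances by default, or over the northern
    subset only with ``quantile_on="northern"``; with ``northern_only`` the
    selected set is restricted to sites with y above the centre.
    """
    if not 0 < q < 1:
        raise InvalidConfigurationError(f"q must be in (0, 1), got {q}")
    if len(occurrences) < 2:
        raise InsufficientDataError(
            "need at least 2 occurrences for a percentile margin rule"
        )
    d = distances_from(occurrences, center)
    north = occurrences["y"].to_numpy(float) > center.y
    if quantile_on == "northern":
        if not north.any():
            raise InsufficientDataError("no occurrences north of the centre")
        thresh = float(np.quantile(d[north], q))
    elif quantile_on == "all":
        thresh = float(np.quantile(d, q))
    else:
        raise InvalidConfigurationError(f"quantile_on must be 'all' or 'northern'")
    mask = d > thresh
    if northern_only:
        mask &= north
    out = occurrences.loc[mask].copy()
    out["distance"] = d[mask]
    return out


def select_margin_topk(
    occurrences: pd.DataFrame, center: RangeCenter, k: int
) -> pd.DataFrame:
    """The k occurrences most distant from ``center``; ties broken by site_id.

    If fewer than k occurrences exist, all are returned and the result is
    flagged (``attrs["short"] = True``) with a warning.
    """
    if k < 1:
        raise InvalidConfigurationError(f"k must be >= 1, got {k}")
    d = distances_from(occurrences, center)
    out = occurrences.copy()
    out["distance"] = d
    # stable sort: distance descending, then site_id ascending
    out = out.sort_values(
        ["distance", "site_id"], ascending=[False, True], kind="mergesort"
    )
    short = len(out) < k
    if short:
        warnings.warn(
            f"only {len(out)} occurrences available for top-{k} selection",
            stacklevel=2,
        )
    out = out.head(k)
    out.attrs["short"] = short
    return out


def select_margins(
    records: pd.DataFrame,
    center: RangeCenter,
    *,
    q: float = 0.95,
    k: int | str | None = None,
    percentile_periods=None,
    northern_only: bool = True,
    quantile_on: str = "all",
) -> dict:
    """Margin occurrences per period, mixing the percentile and top-k rules.

    Periods listed in ``percentile_periods`` (default: the centre's reference
    period) use the percentile rule; the rest use top-k. ``k="auto"`` copies
    the margin count of the first percentile period — the convention for
    survey series whose later campaigns cover only the range periphery.
    ``k=None`` applies the percentile rule everywhere.
    """
    occ = records.loc[records["detected"].astype(bool)]
    if northern_only:
        # "northernmost sites": the top-k rule ranks only sites north of the
        # centre; the percentile rule applies its own restriction internally
        occ_topk = occ.loc[occ["y"].to_numpy(float) > center.y]
    else:
        occ_topk = occ
    periods = list(dict.fromkeys(records["period"]))
    if percentile_periods is None:
        percentile_periods = [
            p for p in periods if str(p) == str(center.reference_period)
        ] or periods[:1]
    percentile_periods = [str(p) for p in percentile_periods]
    margins: dict = {}
    k_eff = None if k in (None, "auto") else int(k)
    for period in periods:
        if k is None or str(period) in percentile_periods:
            grp = occ.loc[occ["period"] == period]
            sel = select_margin_percentile(
                grp, center, q=q, northern_only=northern_only,
                quantile_on=quantile_on,
            )
            if k == "auto" and k_eff is None:
                if len(sel) == 0:
                    raise InsufficientDataError(
                        f"percentile rule selected no margin sites in "
                        f"period {period!r}; cannot infer k"
                    )
                k_eff = len(sel)
        else:
            if k_eff is None:
                raise InvalidConfigurationError(
                    "k='auto' requires a percentile period before any top-k period"
                )
            grp = occ_topk.loc[occ_topk["period"] == period]
            sel = select_margin_topk(grp, center, k_eff)
        margins[period] = sel
    return margins


def extract_periphery(
    records: pd.DataFrame,
    margins: dict,
    year_map: dict | None = None,
    *,
    tol: float = 1e-9,
    global_circle: bool = False,
) -> pd.DataFrame:
    """Survey records inside the minimum enclosing circle of each period's margins.

    One circle per period by default (the periphery shifts over time); with
    ``global_circle`` a single circle over all margin occurrences is used for
    every period. Returns rows (year, detected, site_id, period); circles are
    attached as ``attrs["circles"]``.
    """
    validate_survey(records)
    circles: dict[object, Circle] = {}
    if global_circle:
        pts = pd.concat(margins.values())[["x", "y"]].to_numpy(float)
        circ = minimum_enclosing_circle(pts)
        circles = {period: circ for period in margins}
    else:
        for period, m in margins.items():
            if len(m) == 0:
                raise InsufficientDataError(f"no margin occurrences for {period!r}")
            circles[period] = minimum_enclosing_circle(m[["x", "y"]].to_numpy(float))
    rows = []
    for period, circ in circles.items():
        grp = records.loc[records["period"] == period]
        inside = grp.loc[circ.contains(grp["x"], grp["y"], tol=tol)]
        if len(inside) == 0:
            warnings.warn(
                f"no survey records inside the periphery circle of {period!r}",
                stacklevel=2,
            )
        year = _year_of(period, year_map, inside)
        for _, r in inside.iterrows():
            rows.append((year, int(bool(r["detected"])), r["site_id"], period))
    out = pd.DataFrame(rows, columns=["year", "detected", "site_id", "period"])
    out.attrs["circles"] = circles
    return out


def build_margin_series(
    margins: dict, center: RangeCenter, year_map: dict | None = None
) -> pd.DataFrame:
    """(year, distance, site_id) rows for every selected margin occurrence."""
    rows = []
    for period, m in margins.items():
        year = _year_of(period, year_map, m)
        d = distances_from(m, center)
        for (_, r), dist in zip(m.iterrows(), d):
            rows.append((year, float(dist), r["site_id"], period))
    return pd.DataFrame(rows, columns=["year", "distance", "site_id", "period"])


def parse_period_year(label) -> float:
    """Numeric year for a period label; pooled spans map to their midpoint.

    ``"2003"`` -> 2003; ``"2012-14"`` (or an en-dash) -> 2013.
    """
    s = str(label).strip()
    try:
        return float(s)
    except ValueError:
        pass
    m = re.fullmatch(r"(\d{4})\s*[-–/]\s*(\d{2,4})", s)
    if m:
        y0 = int(m.group(1))
        y1 = int(m.group(2))
        if y1 < 100:
            y1 += (y0 // 100) * 100
        return (y0 + y1) / 2.0
    raise InvalidConfigurationError(f"cannot map period {label!r} to a year")


def default_year_map(periods) -> dict:
    """period -> numeric year, via :func:`parse_period_year`."""
    return {p: parse_period_year(p) for p in dict.fromkeys(periods)}


def _year_of(period, year_map, frame: pd.DataFrame) -> float:
    if year_map is not None:
        if period not in year_map:
            raise InvalidConfigurationError(
                f"period {period!r} missing from the year map"
            )
        return float(year_map[period])
    if "year" in frame.columns and len(frame):
        return float(frame["year"].iloc[0])
    return parse_period_year(period)
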