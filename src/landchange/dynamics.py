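"""Zone-level land-cover change dynamics and kernel-smoothed surfaces.

For each zone (village, township, ...) the per-class change components
are tallied from an aligned map pair:

    Nochange_i : area persisting in class i,
    Increase_i : area entering class i from any other class,
    Decrease_i : area leaving class i for any other class,

and combined into the land-cover change dynamic index

    LUCDI = (sum_i Increase_i + sum_i Decrease_i) / (2 * zone area),

the changed-area fraction of the zone: 0 when nothing moved, 1 when no
cell persisted.  Because every changed cell appears exactly once among
the increases and once among the decreases, the index is bounded in
[0, 1] and invariant to relabelling classes.  Dividing by the elapsed
years would break that range, so the annualized rate is reported as a
separate field, LUCDI / (t2 - t1).

Zone values are then attached to zone representative points and spread
into a continuous intensity surface with a weighted kernel density
(quartic kernel by default, the choice of GIS density tools).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .maps import (
    NO_ZONE,
    AlignmentError,
    CategoricalMap,
    GridTransform,
    ZoneSet,
    check_alignment,
    rasterize_zones,
    write_surface,
)

__all__ = [
    "ZoneDynamics",
    "DynamicsSurface",
    "zone_change_components",
    "lucdi",
    "kernel_surface",
    "covariate_report",
    "default_bandwidth",
]


def zone_change_components(
    map_1: CategoricalMap,
    map_2: CategoricalMap,
    zones: ZoneSet,
    as_area: bool = False,
) -> pd.DataFrame:
    """Per-zone, per-class Nochange/Increase/Decrease components.

    Returns a long-format frame (zone_id, class, nochange, increase,
    decrease) in cell counts, or map-unit area when ``as_area``.  Only
    cells valid at both dates count; a zone with no valid cell keeps
    all-zero components and is flagged in ``.attrs["empty_zones"]``.
    """
    report = check_alignment(map_1, map_2)
    if not report.ok:
        raise AlignmentError("maps are not co-registered")
    legend = report.legend_union
    codes = sorted(legend)
    k = len(codes)
    code_to_idx = np.zeros(max(codes) + 1, dtype=np.int64)
    for idx, code in enumerate(codes):
        code_to_idx[code] = idx

    zone_grid = rasterize_zones(zones, map_1)
    valid = map_1.valid_mask & map_2.valid_mask & (zone_grid != NO_ZONE)
    zids = sorted(z.zone_id for z in zones)
    zid_to_idx = {z: i for i, z in enumerate(zids)}
    nz = len(zids)

    z = np.vectorize(zid_to_idx.get, otypes=[np.int64])(zone_grid[valid]) if valid.any() else np.empty(0, np.int64)
    a = code_to_idx[map_1.grid[valid]]
    b = code_to_idx[map_2.grid[valid]]
    # full per-zone transition cube, then marginalize
    cube = np.bincount(z * k * k + a * k + b, minlength=nz * k * k).reshape(nz, k, k)

    diag = cube[:, np.arange(k), np.arange(k)]
    increase = cube.sum(axis=1) - diag  # entering class j from elsewhere
    decrease = cube.sum(axis=2) - diag  # leaving class i
    scale = map_1.transform.cell_area if as_area else 1.0

    rows = pd.DataFrame(
        {
            "zone_id": np.repeat(zids, k),
            "class": [legend[c] for c in codes] * nz,
            "nochange": diag.ravel() * scale,
            "increase": increase.ravel() * scale,
            "decrease": decrease.ravel() * scale,
        }
    )
    totals = cube.sum(axis=(1, 2))
    rows.attrs["empty_zones"] = [zids[i] for i in np.nonzero(totals == 0)[0]]
    rows.attrs["unit"] = "area" if as_area else "cells"
    return rows


@dataclass
class ZoneDynamics:
    """Per-zone change components, LUCDI values and representative points."""

    summary_table: pd.DataFrame  # one row per zone
    components: pd.DataFrame  # long format per zone x class
    period: tuple[float, float]

    def lucdi_of(self, zone_id: int) -> float:
        return float(self.summary_table.set_index("zone_id").loc[zone_id, "lucdi"])

    def to_csv(self, path: str | Path) -> None:
        self.summary_table.to_csv(path, index=False)


def lucdi(
    components: pd.DataFrame,
    t_1: float,
    t_2: float,
    zones: ZoneSet | None = None,
    transform: GridTransform | None = None,
) -> ZoneDynamics:
    """Fold per-zone components into LUCDI and its annualized rate.

    Zones with zero valid area get NaN indices and a ``flagged`` mark.
    When a :class:`ZoneSet` (and, for raster zones, the grid transform)
    is supplied, each zone's representative point is attached for the
    surface stage.
    """
    if t_2 <= t_1:
        raise ValueError(f"t_2 must exceed t_1, got {t_1} -> {t_2}")
    grouped = components.groupby("zone_id", sort=True)
    agg = grouped[["nochange", "increase", "decrease"]].sum()
    area = agg["nochange"] + agg["increase"]  # each changed cell counted once in increase
    with np.errstate(invalid="ignore", divide="ignore"):
        index = (agg["increase"] + agg["decrease"]) / (2.0 * area)
    index[area == 0] = np.nan

    out = pd.DataFrame(
        {
            "zone_id": agg.index,
            "valid_area": area.to_numpy(),
            "lucdi": index.to_numpy(),
            "lucdi_annual": index.to_numpy() / (t_2 - t_1),
            "flagged": (area == 0).to_numpy(),
        }
    ).reset_index(drop=True)

    if zones is not None:
        pts = {z.zone_id: z.representative_point(transform) for z in zones}
        out["centroid_x"] = out["zone_id"].map(lambda z: pts.get(z, (np.nan, np.nan))[0])
        out["centroid_y"] = out["zone_id"].map(lambda z: pts.get(z, (np.nan, np.nan))[1])
    return ZoneDynamics(summary_table=out, components=components, period=(t_1, t_2))


@dataclass
class DynamicsSurface:
    """Kernel-smoothed change-intensity surface on a template grid."""

    grid: np.ndarray
    transform: GridTransform
    bandwidth: float
    kernel_name: str
    crs_id: str = ""

    def to_geotiff(self, path: str | Path) -> None:
        write_surface(self.grid, self.transform, path, crs_id=self.crs_id)


def default_bandwidth(template: CategoricalMap) -> float:
    """One tenth of the longer map extent, in map units."""
    ny, nx = template.shape
    return 0.1 * max(nx * template.transform.dx, ny * template.transform.dy)


def _kernel_2d(d2: np.ndarray, h: float, name: str) -> np.ndarray:
    """Planar kernel value at squared distance ``d2`` for bandwidth ``h``."""
    if name == "quartic":
        u2 = d2 / (h * h)
        k = np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0)
        return (3.0 / (np.pi * h * h)) * k
    if name == "gaussian":
        return np.exp(-0.5 * d2 / (h * h)) / (2.0 * np.pi * h * h)
    raise ValueError(f"unknown kernel {name!r}; use 'quartic' or 'gaussian'")


def kernel_surface(
    points: np.ndarray,
    weights: np.ndarray,
    template: CategoricalMap,
    bandwidth: float | None = None,
    kernel_name: str = "quartic",
) -> DynamicsSurface:
    """Weighted kernel density of zone points, evaluated at cell centres.

    ``surface(x) = sum_k w_k K_h(|x - c_k|)`` — a relative intensity
    field (unnormalized weighted KDE), linear in the weights, matching
    what GIS kernel-density tools emit up to their area scaling.  Points
    with NaN weights are dropped; all-zero weights give a zero surface.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if points.shape[0] != weights.shape[0]:
        raise ValueError("points and weights differ in length")
    keep = np.isfinite(weights) & np.isfinite(points).all(axis=1)
    points, weights = points[keep], weights[keep]
    if points.shape[0] == 0:
        raise ValueError("no points with finite weights")
    if bandwidth is None:
        bandwidth = default_bandwidth(template)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    x, y = template.transform.cell_centers(template.shape)
    out = np.zeros(template.shape, dtype=float)
    for (cx, cy), w in zip(points, weights):
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        out += w * _kernel_2d(d2, bandwidth, kernel_name)
    return DynamicsSurface(
        grid=out,
        transform=template.transform,
        bandwidth=float(bandwidth),
        kernel_name=kernel_name,
        crs_id=template.crs_id,
    )


def covariate_report(
    zone_dynamics: ZoneDynamics, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Rank (Spearman) correlation of LUCDI with per-zone covariates.

    ``covariates`` is keyed by ``zone_id`` (index or column); every
    other numeric column is a candidate driver.  Purely descriptive: one
    row per covariate with rho, p-value and the number of matched zones.
    """
    cov = covariates.copy()
    if "zone_id" in cov.columns:
        cov = cov.set_index("zone_id")
    zd = zone_dynamics.summary_table.set_index("zone_id")["lucdi"].dropna()
    matched = cov.loc[cov.index.intersection(zd.index)]
    if len(matched) < 3:
        raise ValueError(
            f"need at least 3 zones with matching covariates, found {len(matched)}"
        )
    rows = []
    for col in matched.columns:
        vals = pd.to_numeric(matched[col], errors="coerce")
        ok = vals.notna()
        rho, p = stats.spearmanr(zd.loc[matched.index[ok]], vals[ok])
        rows.append({"covariate": col, "spearman_rho": rho, "p_value": p, "n_zones": int(ok.sum())})
    report = pd.DataFrame(rows)
    # plotting-ready paired values travel with the report
    paired = matched.copy()
    paired.insert(0, "lucdi", zd.loc[matched.index])
    report.attrs["paired_data"] = paired.reset_index()
    return report
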