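"""High-level model objects tying the analysis stages together.

Two entry points mirror the two ways the analysis is driven in
practice: :class:`LandCoverChange` fits the cross-tabulation change
budget and the systematic-transition signals to a pair of maps (or to a
published matrix), and :class:`ZoneDynamicsModel` fits the zone-level
change dynamic index and its kernel surface.  Both return results
objects that hold the fitted tables and render a text summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from .crosstab import ChangeBudget, TransitionMatrix, change_budget, cross_tabulate
from .dynamics import (
    ZoneDynamics,
    DynamicsSurface,
    covariate_report,
    kernel_surface,
    lucdi,
    zone_change_components,
)
from .maps import CategoricalMap, ZoneSet
from .signals import (
    DEFAULT_THRESHOLD_D,
    DEFAULT_THRESHOLD_R,
    SignalTable,
    rank_signals,
    transition_signals,
)
from .synthetic import table1_fixture

__all__ = [
    "LandCoverChange",
    "LandCoverChangeResults",
    "ZoneDynamicsModel",
    "ZoneDynamicsResults",
]


class LandCoverChange:
    """Change analysis of one map pair or one published transition matrix.

    Examples
    --------
    >>> from landchange import LandCoverChange
    >>> res = LandCoverChange.from_fixture("2000-2013").fit()
    >>> res.budget["FL"]["total"]
    19.73
    """

    def __init__(
        self,
        map_1: CategoricalMap | None = None,
        map_2: CategoricalMap | None = None,
        *,
        matrix: TransitionMatrix | None = None,
        class_order: list[str] | None = None,
    ) -> None:
        if matrix is None and (map_1 is None or map_2 is None):
            raise ValueError("provide either a map pair or a transition matrix")
        self.map_1 = map_1
        self.map_2 = map_2
        self.matrix = matrix
        self.class_order = class_order

    @classmethod
    def from_matrix(cls, matrix: TransitionMatrix) -> "LandCoverChange":
        return cls(matrix=matrix)

    @classmethod
    def from_fixture(cls, period: str) -> "LandCoverChange":
        """Analysis of one of the packaged published matrices."""
        return cls(matrix=table1_fixture(period))

    @classmethod
    def from_csv(
        cls, path: str | Path, period: tuple[float, float] | None = None
    ) -> "LandCoverChange":
        return cls(matrix=TransitionMatrix.from_csv(path, period=period))

    def fit(
        self,
        threshold_d: float = DEFAULT_THRESHOLD_D,
        threshold_r: float = DEFAULT_THRESHOLD_R,
        rounding: str = "full",
    ) -> "LandCoverChangeResults":
        """Cross-tabulate (if needed), build the budget and the signals."""
        T = self.matrix
        if T is None:
            T = cross_tabulate(self.map_1, self.map_2, class_order=self.class_order)
        T = T.to_percent()
        budget = change_budget(T)
        signals = transition_signals(
            T, threshold_d=threshold_d, threshold_r=threshold_r, rounding=rounding
        )
        ranking = rank_signals(signals)
        return LandCoverChangeResults(
            transition_matrix=T, budget=budget, signals=signals, ranking=ranking
        )


@dataclass
class LandCoverChangeResults:
    """Fitted change budget and systematic-transition signals."""

    transition_matrix: TransitionMatrix
    budget: ChangeBudget
    signals: SignalTable
    ranking: pd.DataFrame

    def summary(self, decimals: int = 2) -> str:
        T = self.transition_matrix
        lines = []
        period = ""
        if T.period:
            period = f" {T.period[0]:g}-{T.period[1]:g}"
        lines.append(f"Land-cover change analysis{period}")
        lines.append("=" * 60)
        lines.append("Transition matrix (% of study area, time 1 rows -> time 2 columns)")
        lines.append(T.to_frame().round(decimals).to_string())
        if abs(T.residual) > 1e-9:
            lines.append(f"(published-matrix rounding residual: {T.residual:+.3f})")
        lines.append("")
        lines.append("Change budget (% of study area)")
        lines.append(self.budget.to_frame(decimals).to_string())
        lines.append(
            f"overall persistence {self.budget.overall_persistence:.{decimals}f}  "
            f"overall change {self.budget.overall_change:.{decimals}f}"
        )
        lines.append("")
        lines.append(
            "Systematic transitions (both perspectives; "
            f"|D| > {self.signals.threshold_d:g}, |R| > {self.signals.threshold_r:g})"
        )
        if len(self.ranking):
            cols = ["from", "to", "observed", "d_gain", "r_gain", "d_loss", "r_loss"]
            lines.append(self.ranking[cols].round(decimals).to_string(index=False))
        else:
            lines.append("  none detected")
        return "\n".join(lines)

    def save(self, outdir: str | Path, decimals: int | None = None) -> None:
        """Write the standard report bundle (CSV tables + metadata JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        T = self.transition_matrix
        frame = T.to_frame() if decimals is None else T.to_frame().round(decimals)
        frame.rename_axis("class").to_csv(outdir / "transition_matrix.csv")
        self.budget.to_csv(outdir / "change_budget.csv", decimals)
        self.signals.to_csv(outdir / "signals.csv")
        self.ranking.to_csv(outdir / "ranking.csv", index=False)
        meta = {
            "package_version": _pkg_version,
            "rounding_mode": self.signals.rounding,
            "threshold_d": self.signals.threshold_d,
            "threshold_r": self.signals.threshold_r,
            "period": list(T.period) if T.period else None,
            "percent_basis": "share of jointly valid (non-nodata) cells",
            "matrix_residual": T.residual,
        }
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=1))


class ZoneDynamicsModel:
    """Zone-level change dynamics (LUCDI) for an aligned map pair."""

    def __init__(
        self,
        map_1: CategoricalMap,
        map_2: CategoricalMap,
        zones: ZoneSet,
        period: tuple[float, float] | None = None,
    ) -> None:
        self.map_1 = map_1
        self.map_2 = map_2
        self.zones = zones
        if period is None:
            if map_1.timestamp is None or map_2.timestamp is None:
                raise ValueError("period not given and maps carry no timestamps")
            period = (map_1.timestamp, map_2.timestamp)
        self.period = period

    def fit(
        self,
        bandwidth: float | None = None,
        kernel_name: str = "quartic",
        surface: bool = True,
    ) -> "ZoneDynamicsResults":
        components = zone_change_components(self.map_1, self.map_2, self.zones)
        zd = lucdi(
            components,
            self.period[0],
            self.period[1],
            zones=self.zones,
            transform=self.map_1.transform,
        )
        surf = None
        if surface:
            tab = zd.summary_table.dropna(subset=["lucdi"])
            surf = kernel_surface(
                tab[["centroid_x", "centroid_y"]].to_numpy(),
                tab["lucdi"].to_numpy(),
                self.map_1,
                bandwidth=bandwidth,
                kernel_name=kernel_name,
            )
        return ZoneDynamicsResults(dynamics=zd, surface=surf)


@dataclass
class ZoneDynamicsResults:
    """Fitted zone dynamics table and (optionally) its kernel surface."""

    dynamics: ZoneDynamics
    surface: DynamicsSurface | None = None

    def summary(self, decimals: int = 4) -> str:
        t1, t2 = self.dynamics.period
        lines = [
            f"Zone change dynamics {t1:g}-{t2:g} "
            f"({len(self.dynamics.summary_table)} zones)",
            "=" * 60,
            self.dynamics.summary_table.round(decimals).to_string(index=False),
        ]
        if self.surface is not None:
            lines.append(
                f"surface: {self.surface.kernel_name} kernel, "
                f"bandwidth {self.surface.bandwidth:g} map units, "
                f"max intensity {self.surface.grid.max():.3g}"
            )
        return "\n".join(lines)

    def covariate_report(self, covariates: pd.DataFrame) -> pd.DataFrame:
        return covariate_report(self.dynamics, covariates)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.dynamics.to_csv(outdir / "zone_dynamics.csv")
        if self.surface is not None:
            self.surface.to_geotiff(outdir / "surface.tif")
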