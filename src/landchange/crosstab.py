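"""Cross-tabulation of categorical map pairs and the per-class change budget.

The transition matrix C holds, in entry (i, j), the share of the study
area that was class i at time 1 and class j at time 2; the diagonal is
persistence.  The budget decomposes each class's change into

    gain_j  = C_+j - C_jj          (gross gain)
    loss_j  = C_j+ - C_jj          (gross loss)
    net_j   = |gain_j - loss_j|    (quantity change)
    swap_j  = 2 * min(gain_j, loss_j)   (location-only change)
    total_j = gain_j + loss_j = net_j + swap_j

Published matrices are supported alongside raster pairs: a table copied
from a paper carries rounded entries (and often independently rounded
gain/loss marginals), so those matrices get a relaxed mass-balance
tolerance and may carry the printed marginals explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .maps import AlignmentError, CategoricalMap, check_alignment

__all__ = ["TransitionMatrix", "ChangeBudget", "cross_tabulate", "from_published_table", "change_budget"]

#: mass-balance tolerance for matrices built from full-precision counts
EXACT_TOL = 1e-9
#: tolerance for matrices re-keyed from rounded publications
PUBLISHED_TOL = 0.2


@dataclass
class TransitionMatrix:
    """Square class-by-class table of area shares between two dates.

    ``P[i, j]`` is the percent of the study area (or the cell count, in
    ``"cells"`` basis) moving from ``classes[i]`` at ``period[0]`` to
    ``classes[j]`` at ``period[1]``.
    """

    classes: list[str]
    P: np.ndarray
    period: tuple[float, float] | None = None
    basis: str = "percent"  # "percent" | "cells"
    cell_area: float | None = None
    published: bool = False  # re-keyed from a rounded publication
    published_gain: np.ndarray | None = None
    published_loss: np.ndarray | None = None
    published_row_totals: np.ndarray | None = None
    published_col_totals: np.ndarray | None = None
    residual: float = field(default=0.0)  # deviation of sum from 100 (percent basis)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.classes)
        if self.P.shape != (k, k):
            raise ValueError(f"matrix shape {self.P.shape} does not match {k} classes")
        if (self.P < 0).any():
            raise ValueError("transition matrix entries must be non-negative")
        if self.basis not in ("percent", "cells"):
            raise ValueError("basis must be 'percent' or 'cells'")
        if self.basis == "percent":
            tol = PUBLISHED_TOL if self.is_published else EXACT_TOL
            self.residual = float(self.P.sum() - 100.0)
            if abs(self.residual) > tol:
                raise ValueError(
                    f"percent-basis matrix sums to {self.P.sum():.6f}, not 100"
                )

    @property
    def is_published(self) -> bool:
        return self.published or self.published_gain is not None

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def row_totals(self) -> np.ndarray:
        """Time-1 class shares C_i+ (printed marginals win when present:
        rounded publications print totals that drift from their own cell
        sums by a few hundredths)."""
        if self.published_row_totals is not None:
            return np.asarray(self.published_row_totals, dtype=float)
        return self.P.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Time-2 class shares C_+j."""
        if self.published_col_totals is not None:
            return np.asarray(self.published_col_totals, dtype=float)
        return self.P.sum(axis=0)

    @property
    def persistence(self) -> np.ndarray:
        return np.diag(self.P)

    def gains(self) -> np.ndarray:
        """Gross gain per class; printed marginals win over recomputed ones."""
        if self.published_gain is not None:
            return np.asarray(self.published_gain, dtype=float)
        return self.col_totals - self.persistence

    def losses(self) -> np.ndarray:
        if self.published_loss is not None:
            return np.asarray(self.published_loss, dtype=float)
        return self.row_totals - self.persistence

    def to_percent(self) -> "TransitionMatrix":
        """Convert a cell-basis matrix to percent of the valid area."""
        if self.basis == "percent":
            return self
        total = self.P.sum()
        if total == 0:
            raise ValueError("empty matrix cannot be converted to percent")
        return TransitionMatrix(
            classes=list(self.classes),
            P=self.P * (100.0 / total),
            period=self.period,
            basis="percent",
            cell_area=self.cell_area,
        )

    def index_of(self, cls: str) -> int:
        return self.classes.index(cls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.classes, columns=self.classes)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("class").to_csv(path)

    @classmethod
    def from_csv(
        cls, path: str | Path, period: tuple[float, float] | None = None
    ) -> "TransitionMatrix":
        """Read a matrix CSV (classes as header row and first column).

        Optional trailing ``loss``/``row_total`` columns and ``gain``/
        ``col_total`` rows carry published marginals, matching the
        packaged fixtures.
        """
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        extras: dict[str, np.ndarray | None] = {}
        for col in ("loss", "row_total"):
            if col in df.columns:
                extras[col] = df[col]
                df = df.drop(columns=col)
        for row in ("gain", "col_total"):
            if row in df.index:
                extras[row] = df.loc[row].to_numpy(dtype=float)
                df = df.drop(index=row)
        for col in ("loss", "row_total"):
            if col in extras:
                s = extras[col].drop(index=["gain", "col_total"], errors="ignore")
                extras[col] = s.to_numpy(dtype=float)
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"matrix CSV is not square: {df.shape}")
        return cls(
            classes=list(df.index),
            P=df.to_numpy(dtype=float),
            period=period,
            basis="percent",
            published=True,
            published_gain=extras.get("gain"),
            published_loss=extras.get("loss"),
            published_row_totals=extras.get("row_total"),
            published_col_totals=extras.get("col_total"),
        )


@dataclass
class ChangeBudget:
    """Per-class persistence / gain / loss / net / swap / total decomposition."""

    classes: list[str]
    persistence: np.ndarray
    gain: np.ndarray
    loss: np.ndarray
    net: np.ndarray
    swap: np.ndarray
    total: np.ndarray
    overall_persistence: float
    overall_change: float
    period: tuple[float, float] | None = None

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "persistence": self.persistence,
                "gain": self.gain,
                "loss": self.loss,
                "net": self.net,
                "swap": self.swap,
                "total": self.total,
            },
            index=pd.Index(self.classes, name="class"),
        )
        if decimals is not None:
            df = df.round(decimals)
        return df

    def to_csv(self, path: str | Path, decimals: int | None = None) -> None:
        self.to_frame(decimals).to_csv(path)

    def __getitem__(self, cls: str) -> pd.Series:
        return self.to_frame().loc[cls]


def cross_tabulate(
    map_1: CategoricalMap,
    map_2: CategoricalMap,
    class_order: list[str] | None = None,
    basis: str = "percent",
) -> TransitionMatrix:
    """Cross-tabulate two aligned maps over cells valid at both dates.

    Classes listed in ``class_order`` but absent from both maps appear
    as zero rows/columns, keeping report shapes stable across periods.
    """
    report = check_alignment(map_1, map_2)
    if not report.ok:
        raise AlignmentError(
            f"maps are not co-registered: shape={report.same_shape} "
            f"transform={report.same_transform} crs={report.same_crs}"
        )
    legend = report.legend_union
    if class_order is None:
        class_order = [legend[c] for c in sorted(legend)]
    else:
        unknown = set(legend.values()) - set(class_order)
        if unknown:
            raise ValueError(f"class_order omits classes present in the maps: {sorted(unknown)}")
    k = len(class_order)
    name_to_idx = {name: i for i, name in enumerate(class_order)}
    code_to_idx = {code: name_to_idx[name] for code, name in legend.items()}

    valid = map_1.valid_mask & map_2.valid_mask
    if not valid.any():
        raise ValueError("maps share no valid (non-nodata) cells")
    a = map_1.grid[valid]
    b = map_2.grid[valid]
    lut_size = max(code_to_idx) + 1
    lut = np.zeros(lut_size, dtype=np.int64)
    for code, idx in code_to_idx.items():
        lut[code] = idx
    joint = np.bincount(lut[a] * k + lut[b], minlength=k * k).reshape(k, k)

    period = None
    if map_1.timestamp is not None and map_2.timestamp is not None:
        period = (map_1.timestamp, map_2.timestamp)
    cells = TransitionMatrix(
        classes=class_order,
        P=joint.astype(float),
        period=period,
        basis="cells",
        cell_area=map_1.transform.cell_area,
    )
    return cells if basis == "cells" else cells.to_percent()


def from_published_table(
    rows: np.ndarray | list[list[float]],
    classes: list[str],
    period: tuple[float, float] | None = None,
    gain: np.ndarray | None = None,
    loss: np.ndarray | None = None,
    row_totals: np.ndarray | None = None,
    col_totals: np.ndarray | None = None,
) -> TransitionMatrix:
    """Build a percent-basis matrix from values copied out of a publication.

    Rounded tables rarely sum to exactly 100; the residual is recorded
    and tolerated up to +/-0.2.  The optional arguments accept the
    printed marginal vectors (gross gain/loss and C_i+/C_+j totals),
    which downstream computations then use verbatim — a publication's
    own derived cells are only reproducible from its own marginals.
    """
    P = np.asarray(rows, dtype=float)
    if (P < 0).any():
        raise ValueError("published matrix has a negative entry")

    def opt(v):
        return None if v is None else np.asarray(v, dtype=float)

    return TransitionMatrix(
        classes=list(classes),
        P=P,
        period=period,
        basis="percent",
        published=True,
        published_gain=opt(gain),
        published_loss=opt(loss),
        published_row_totals=opt(row_totals),
        published_col_totals=opt(col_totals),
    )


def change_budget(T: TransitionMatrix) -> ChangeBudget:
    """Decompose a transition matrix into the per-class change budget."""
    T = T.to_percent()
    gain = T.gains()
    loss = T.losses()
    net = np.abs(gain - loss)
    swap = 2.0 * np.minimum(gain, loss)
    trace = float(T.persistence.sum())
    return ChangeBudget(
        classes=list(T.classes),
        persistence=T.persistence.copy(),
        gain=gain,
        loss=loss,
        net=net,
        swap=swap,
        total=gain + loss,
        overall_persistence=trace,
        overall_change=100.0 - trace,
        period=T.period,
    )
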