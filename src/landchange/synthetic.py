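"""Synthetic categorical landscape pairs, zones and packaged fixtures.

Real classified satellite scenes are rarely redistributable, so every
stage of the analysis is exercised on generated data with known ground
truth: a time-1 landscape drawn from target class shares, a time-2
landscape evolved cell-by-cell under a user-specified Markov transition
matrix, and a wall-to-wall Voronoi zoning standing in for villages.
Optional majority-smoothing passes impose spatial autocorrelation while
staying deterministic for a given seed.

The two published six-class percentage transition matrices shipped as
package data (periods 1992-2000 and 2000-2013, classes FL forest land,
IFL immature forest land, CL cultivated land, O orchards, CoL
construction land, W water) double as realistic Markov generators: row
``i`` of ``C_ij / C_i+`` is the empirical probability that a cell of
class i transitions to class j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage

from .crosstab import TransitionMatrix
from .maps import CategoricalMap, GridTransform, Zone, ZoneSet

__all__ = [
    "SyntheticConfig",
    "generate_landscape",
    "evolve_landscape",
    "generate_pair",
    "generate_zones",
    "table1_fixture",
    "markov_from_matrix",
    "FIXTURE_PERIODS",
    "FIXTURE_CLASSES",
]

FIXTURE_CLASSES = ["FL", "IFL", "CL", "O", "CoL", "W"]
FIXTURE_PERIODS = {
    "1992-2000": ("table1_1992_2000.csv", (1992.0, 2000.0)),
    "2000-2013": ("table1_2000_2013.csv", (2000.0, 2013.0)),
}

#: long-hand legend for the six-class fixtures
FIXTURE_LEGEND = {
    "FL": "forest land",
    "IFL": "immature forest land",
    "CL": "cultivated land",
    "O": "orchards",
    "CoL": "construction land",
    "W": "water",
}


@dataclass
class SyntheticConfig:
    """Recipe for one landscape pair plus zoning.

    ``class_shares`` are the target time-1 composition; ``markov`` the
    row-stochastic per-cell transition law; ``clustering`` the number of
    3x3 majority-smoothing passes applied to the time-1 map (0 keeps
    cells i.i.d.).
    """

    n_rows: int = 200
    n_cols: int = 200
    class_shares: np.ndarray = field(
        default_factory=lambda: np.array([0.21, 0.31, 0.35, 0.10, 0.025, 0.005])
    )
    markov: np.ndarray | None = None
    clustering: int = 0
    change_clustering: int = 0
    n_zones: int = 13
    seed: int = 0
    period: tuple[float, float] = (2000.0, 2013.0)
    cell_size: float = 30.0  # metres; Landsat-class pixels

    def __post_init__(self) -> None:
        self.class_shares = np.asarray(self.class_shares, dtype=float)
        k = self.class_shares.size
        if k < 2:
            raise ValueError("need at least 2 classes")
        if (self.class_shares < 0).any() or abs(self.class_shares.sum() - 1.0) > 1e-9:
            raise ValueError("class_shares must be non-negative and sum to 1")
        if self.markov is None:
            self.markov = np.eye(k)
        self.markov = np.asarray(self.markov, dtype=float)
        _check_stochastic(self.markov, k)


def _check_stochastic(markov: np.ndarray, k: int) -> None:
    if markov.shape != (k, k):
        raise ValueError(f"markov matrix must be {k}x{k}")
    if (markov < 0).any() or np.abs(markov.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("markov rows must be non-negative and sum to 1")


def _majority_smooth(grid: np.ndarray, k: int, passes: int,
                     freeze: np.ndarray | None = None) -> np.ndarray:
    """3x3 majority filter; ties break to the lowest class index.

    ``freeze`` marks cells never updated (used to confine smoothing to
    changed cells).  Deterministic, so smoothed maps stay reproducible.
    """
    kernel = np.ones((3, 3))
    out = grid
    for _ in range(passes):
        counts = np.empty((k,) + out.shape)
        for c in range(k):
            counts[c] = ndimage.correlate(
                (out == c).astype(float), kernel, mode="nearest"
            )
        winner = counts.argmax(axis=0)  # argmax takes the lowest index on ties
        if freeze is not None:
            winner = np.where(freeze, out, winner)
        out = winner
    return out


def generate_landscape(config: SyntheticConfig) -> CategoricalMap:
    """Draw the time-1 landscape; class codes are 1..K.

    Cells are sampled i.i.d. from ``class_shares``; each clustering
    pass then applies deterministic majority smoothing, which leaves the
    expected composition approximately intact while building contiguous
    patches.  Identical config + seed gives an identical map.
    """
    rng = np.random.default_rng(config.seed)
    k = config.class_shares.size
    idx = rng.choice(k, size=(config.n_rows, config.n_cols), p=config.class_shares)
    idx = _majority_smooth(idx, k, config.clustering)
    names = (
        FIXTURE_CLASSES if k == len(FIXTURE_CLASSES) else [f"class_{c + 1}" for c in range(k)]
    )
    return CategoricalMap(
        grid=(idx + 1).astype(np.int64),
        transform=GridTransform(0.0, config.n_rows * config.cell_size,
                                config.cell_size, config.cell_size),
        legend={c + 1: names[c] for c in range(k)},
        crs_id="synthetic",
        timestamp=config.period[0],
    )


def evolve_landscape(
    map_1: CategoricalMap,
    markov: np.ndarray,
    seed: int,
    change_clustering: int = 0,
    timestamp: float | None = None,
) -> CategoricalMap:
    """Evolve each cell independently under the Markov transition law.

    The time-2 class of a cell of class i is drawn from row i of
    ``markov``; as the grid grows, the joint empirical matrix converges
    to ``share_i * markov_ij``.  ``change_clustering`` passes of
    majority smoothing restricted to changed cells spatially aggregate
    the change while leaving persistent cells untouched.
    """
    markov = np.asarray(markov, dtype=float)
    codes = sorted(map_1.legend)
    k = len(codes)
    _check_stochastic(markov, k)
    rng = np.random.default_rng(seed)

    code_to_idx = {c: i for i, c in enumerate(codes)}
    idx1 = np.vectorize(code_to_idx.get)(map_1.grid)
    cdf = np.cumsum(markov, axis=1)
    u = rng.random(map_1.shape)
    idx2 = (u[..., None] > cdf[idx1, :]).sum(axis=-1)
    if change_clustering:
        idx2 = _majority_smooth(idx2, k, change_clustering, freeze=idx2 == idx1)
    grid2 = np.asarray(codes, dtype=np.int64)[idx2]
    if map_1.nodata_code is not None:
        grid2 = np.where(map_1.valid_mask, grid2, map_1.nodata_code)
    return CategoricalMap(
        grid=grid2,
        transform=map_1.transform,
        legend=dict(map_1.legend),
        crs_id=map_1.crs_id,
        nodata_code=map_1.nodata_code,
        timestamp=timestamp,
    )


def generate_pair(config: SyntheticConfig) -> tuple[CategoricalMap, CategoricalMap]:
    """Convenience: time-1 landscape plus its Markov-evolved time-2 partner."""
    m1 = generate_landscape(config)
    # derive an independent stream for the evolution step from the config seed
    evolve_seed = int(np.random.default_rng(config.seed).integers(0, 2**31 - 1))
    m2 = evolve_landscape(
        m1, config.markov, evolve_seed,
        change_clustering=config.change_clustering,
        timestamp=config.period[1],
    )
    return m1, m2


def generate_zones(template: CategoricalMap, n_zones: int, seed: int) -> ZoneSet:
    """Wall-to-wall Voronoi zones grown from random seed cells.

    Every cell joins the zone of its nearest seed cell (Euclidean cell
    distance, ties to the lowest zone id), so zones partition the grid
    exactly and are reproducible per seed.
    """
    ny, nx = template.shape
    if not 1 <= n_zones <= ny * nx:
        raise ValueError("n_zones must be between 1 and the cell count")
    rng = np.random.default_rng(seed)
    flat = rng.choice(ny * nx, size=n_zones, replace=False)
    sr, sc = np.divmod(flat, nx)
    rows, cols = np.mgrid[0:ny, 0:nx]
    d2 = (rows[None] - sr[:, None, None]) ** 2 + (cols[None] - sc[:, None, None]) ** 2
    assign = d2.argmin(axis=0)
    zones = [
        Zone(zone_id=z + 1, mask=assign == z, name=f"village_{z + 1}")
        for z in range(n_zones)
    ]
    return ZoneSet(zones=zones)


def table1_fixture(period: str) -> TransitionMatrix:
    """Published six-class percent transition matrix for one period.

    Valid keys: ``"1992-2000"``, ``"2000-2013"``.  The matrix carries
    the published gain/loss marginal vectors, which the change budget
    and the expectation formulas then use verbatim.
    """
    if period not in FIXTURE_PERIODS:
        raise KeyError(
            f"unknown period {period!r}; valid: {sorted(FIXTURE_PERIODS)}"
        )
    fname, years = FIXTURE_PERIODS[period]
    ref = resources.files("landchange.data") / fname
    with resources.as_file(ref) as path:
        return TransitionMatrix.from_csv(path, period=years)


def markov_from_matrix(T: TransitionMatrix) -> np.ndarray:
    """Row-normalize a transition matrix into a Markov law.

    Rows with zero time-1 share become identity rows (a class absent at
    time 1 trivially persists).
    """
    P = T.P
    row = P.sum(axis=1)
    out = np.eye(T.n_classes)
    nz = row > 0
    out[nz] = P[nz] / row[nz, None]
    return out
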