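"""Systematic versus random inter-category transition detection.

A transition is judged against a null model in which change is
distributed at random.  Under random *gain*, a class j acquires its
total gross gain from the other classes in proportion to their time-1
prevalence:

    G_ij = gain_j * C_i+ / (100 - C_j+)        (i != j)

and under random *loss*, class i sheds its gross loss toward the other
classes in proportion to their time-2 prevalence:

    L_ij = loss_i * C_+j / (100 - C_+i)        (i != j).

The deviation D_ij = C_ij - expectation flags systematic transitions
(large positive: i systematically converts to j; large negative: the
conversion is systematically avoided), and the prevalence-corrected
ratio R_ij = D_ij / expectation measures the strength of the tendency
independently of class area.  Diagonal cells carry persistence, which
the null model holds fixed, so their deviation is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .crosstab import TransitionMatrix

__all__ = [
    "SignalTable",
    "expected_gains",
    "expected_losses",
    "transition_signals",
    "rank_signals",
    "DEFAULT_THRESHOLD_D",
    "DEFAULT_THRESHOLD_R",
]

# Defaults for calling a deviation systematic.  The D threshold is in
# percentage points of study area, the R threshold is dimensionless.
# D alone misses small classes (construction land gains a fraction of a
# percent yet does so almost exclusively from orchards), while R alone
# amplifies noise on near-zero expectations, so both must clear their
# threshold.  0.15 points of study area is small enough to keep such
# small-class signals and large enough to drop rounding-level noise.
DEFAULT_THRESHOLD_D = 0.15
DEFAULT_THRESHOLD_R = 0.5

LABEL_TO = "systematic-to"
LABEL_AVOID = "systematic-avoid"
LABEL_RANDOM = "random"


def _expectation(T: TransitionMatrix, marginal: np.ndarray, prevalence: np.ndarray,
                 conditioning: np.ndarray, axis: int) -> np.ndarray:
    """Shared closed form for both expectation tables.

    ``marginal`` is the per-class gross gain (axis=0) or loss (axis=1);
    ``prevalence`` the donor/recipient shares; ``conditioning`` the
    share excluded from the proportional split (C_j+ for gains, C_+i
    for losses).  Entries where conditioning reaches 100 are undefined
    and returned as NaN.
    """
    k = T.n_classes
    denom = 100.0 - conditioning
    with np.errstate(divide="ignore", invalid="ignore"):
        if axis == 0:  # gains: E[i, j] = gain_j * prev_i / (100 - cond_j)
            E = np.outer(prevalence, marginal / denom)
            E[:, denom <= 0] = np.nan
        else:  # losses: E[i, j] = loss_i * prev_j / (100 - cond_i)
            E = np.outer(marginal / denom, prevalence)
            E[denom <= 0, :] = np.nan
    E[np.diag_indices(k)] = T.persistence
    return E


def expected_gains(T: TransitionMatrix) -> np.ndarray:
    """Expected transition shares under the random-gain null model.

    Off-diagonal entry (i, j) is G_ij; the diagonal carries the observed
    persistence (held fixed by the null model).  Columns whose class
    occupies the whole area at time 1 have no defined expectation and
    are NaN off-diagonal.
    """
    T = T.to_percent()
    return _expectation(T, T.gains(), T.row_totals, T.row_totals, axis=0)


def expected_losses(T: TransitionMatrix) -> np.ndarray:
    """Expected transition shares under the random-loss null model (L_ij)."""
    T = T.to_percent()
    return _expectation(T, T.losses(), T.col_totals, T.col_totals, axis=1)


@dataclass
class SignalTable:
    """Observed-vs-expected statistics for every ordered class pair i -> j.

    Stored long-format: one row per off-diagonal pair, with the gain-
    and loss-perspective expectation, deviation D, ratio R and label.
    R is NaN (and the row flagged) where the expectation is zero or
    undefined.
    """

    table: pd.DataFrame
    classes: list[str]
    threshold_d: float
    threshold_r: float
    rounding: str = "full"

    def pair(self, source: str, dest: str) -> pd.Series:
        sel = (self.table["from"] == source) & (self.table["to"] == dest)
        if not sel.any():
            raise KeyError(f"no off-diagonal pair {source} -> {dest}")
        return self.table[sel].iloc[0]

    def matrix(self, column: str) -> pd.DataFrame:
        """Pivot one long-format column back to a class-by-class table."""
        out = self.table.pivot(index="from", columns="to", values=column)
        return out.reindex(index=self.classes, columns=self.classes)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        self.table.to_json(path, orient="records", indent=1)


def _labels(d: np.ndarray, r: np.ndarray, td: float, tr: float) -> np.ndarray:
    lab = np.full(d.shape, LABEL_RANDOM, dtype=object)
    with np.errstate(invalid="ignore"):
        lab[(d > td) & (r > tr)] = LABEL_TO
        lab[(d < -td) & (r < -tr)] = LABEL_AVOID
    return lab


def transition_signals(
    T: TransitionMatrix,
    threshold_d: float = DEFAULT_THRESHOLD_D,
    threshold_r: float = DEFAULT_THRESHOLD_R,
    rounding: str = "full",
) -> SignalTable:
    """Compute D_ij / R_ij for both perspectives and label each pair.

    ``rounding="paper"`` rounds the deviation and the expectation to two
    decimals before taking their ratio, mimicking report tables computed
    from already-rounded intermediates; the default keeps full
    precision.  Pairs with an undefined ratio (zero or undefined
    expectation) are labelled random and flagged.
    """
    if rounding not in ("full", "paper"):
        raise ValueError("rounding must be 'full' or 'paper'")
    T = T.to_percent()
    k = T.n_classes
    G = expected_gains(T)
    L = expected_losses(T)
    C = T.P

    def stats(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        D = C - E
        if rounding == "paper":
            D = np.round(D, 2)
            E = np.round(E, 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(np.abs(E) > 0, D / E, np.nan)
        return D, R

    d_gain, r_gain = stats(G)
    d_loss, r_loss = stats(L)

    i_idx, j_idx = np.nonzero(~np.eye(k, dtype=bool))
    rows = pd.DataFrame(
        {
            "from": [T.classes[i] for i in i_idx],
            "to": [T.classes[j] for j in j_idx],
            "observed": C[i_idx, j_idx],
            "expected_gain": G[i_idx, j_idx],
            "d_gain": d_gain[i_idx, j_idx],
            "r_gain": r_gain[i_idx, j_idx],
            "expected_loss": L[i_idx, j_idx],
            "d_loss": d_loss[i_idx, j_idx],
            "r_loss": r_loss[i_idx, j_idx],
        }
    )
    rows["label_gain"] = _labels(
        rows["d_gain"].to_numpy(), rows["r_gain"].to_numpy(), threshold_d, threshold_r
    )
    rows["label_loss"] = _labels(
        rows["d_loss"].to_numpy(), rows["r_loss"].to_numpy(), threshold_d, threshold_r
    )
    rows["undefined_ratio"] = rows["r_gain"].isna() | rows["r_loss"].isna()
    return SignalTable(
        table=rows,
        classes=list(T.classes),
        threshold_d=threshold_d,
        threshold_r=threshold_r,
        rounding=rounding,
    )


def rank_signals(S: SignalTable, k: int | None = None) -> pd.DataFrame:
    """Rank the transitions systematic on *both* perspectives.

    The ranking key is min(|D_gain|, |D_loss|), descending — a pair must
    stand out from the null model from the gaining class's view and the
    losing class's view to rank highly.  Ties break on (from, to) class
    order.  Asking for more pairs than qualify returns them all, with
    ``truncated=False`` recorded in ``.attrs``.
    """
    t = S.table
    both = t[(t["label_gain"] == "systematic-to") & (t["label_loss"] == "systematic-to")].copy()
    both["rank_key"] = np.minimum(both["d_gain"].abs(), both["d_loss"].abs())
    order = {name: i for i, name in enumerate(S.classes)}
    both["_i"] = both["from"].map(order)
    both["_j"] = both["to"].map(order)
    both = both.sort_values(
        by=["rank_key", "_i", "_j"], ascending=[False, True, True]
    ).drop(columns=["_i", "_j"])
    truncated = False
    if k is not None:
        truncated = len(both) > k
        both = both.head(k)
    both = both.reset_index(drop=True)
    both.attrs["truncated"] = truncated
    return both
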