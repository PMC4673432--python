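"""Inequality statistics over clone-size vectors.

A clone-size vector holds the number of living cells descended from each
founder cell (one entry per micro-well seeded with a single cell); extinct
clones are kept as explicit zeros.  The Gini coefficient

    G = sum_{i,j} |x_i - x_j| / (2 N^2 mu),      mu = (sum_i x_i) / N,

is 0 when every founder contributes equally and approaches 1 when the whole
population descends from a single founder.  For a finite number of clones the
attainable maximum is (N - 1)/N, reached when exactly one clone survives.

The production implementation uses the sorted rearrangement
``sum_i (2 i - N - 1) x_(i) / (N sum_i x_i)`` (ascending order, 1-based i),
which is algebraically identical to the pairwise double sum but O(N log N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "gini_coefficient",
    "gini_matrix",
    "lorenz_curve",
    "gini_from_lorenz",
    "gini_series",
]


def _as_sizes(sizes) -> np.ndarray:
    x = np.asarray(sizes, dtype=float)
    if x.ndim != 1:
        raise ValueError("clone-size vector must be one-dimensional")
    if x.size == 0:
        raise ValueError("clone-size vector has no clones")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("clone sizes must be finite and non-negative")
    return x


def gini_coefficient(sizes) -> float:
    """Gini coefficient of a clone-size vector.

    Parameters
    ----------
    sizes
        Non-negative cell counts, one per founder clone.  Extinct clones
        must be included as zeros.

    Returns
    -------
    float
        The inequality index in ``[0, (N-1)/N]``, or ``nan`` when every
        clone is empty (mean size zero, Gini undefined).
    """
    x = _as_sizes(sizes)
    total = x.sum()
    if total == 0:
        return math.nan
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


def gini_matrix(sizes: np.ndarray) -> np.ndarray:
    """Column-wise Gini of a (n_clones, n_timepoints) count matrix.

    Columns whose total is zero yield ``nan``.  Vectorised equivalent of
    applying :func:`gini_coefficient` to each column.
    """
    x = np.asarray(sizes, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("expected a non-empty (n_clones, n_hours) matrix")
    n = x.shape[0]
    xs = np.sort(x, axis=0)
    w = (2 * np.arange(1, n + 1) - n - 1).astype(float)
    num = w @ xs
    tot = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = num / (n * tot)
    g[tot == 0] = np.nan
    return g


def lorenz_curve(sizes) -> np.ndarray:
    """Empirical Lorenz curve of a clone-size vector.

    Returns an ``(N + 1, 2)`` array of (cumulative clone fraction,
    cumulative cell fraction) pairs after ascending sort, starting at
    (0, 0) and ending at (1, 1).
    """
    x = _as_sizes(sizes)
    if x.sum() == 0:
        raise ValueError("Lorenz curve undefined for an all-zero vector")
    xs = np.sort(x)
    n = x.size
    p = np.arange(n + 1) / n
    cum = np.concatenate([[0.0], np.cumsum(xs)]) / xs.sum()
    return np.column_stack([p, cum])


def gini_from_lorenz(curve: np.ndarray) -> float:
    """Gini via the trapezoid rule on a Lorenz polygon.

    ``1 - 2 * area`` with the area computed by trapezoids over the curve's
    vertices.  On the empirical Lorenz polygon of a clone-size vector this
    equals the pairwise-sum Gini exactly (no small-sample correction is
    required); it is used as a cross-check of :func:`gini_coefficient`.
    """
    c = np.asarray(curve, dtype=float)
    dp = np.diff(c[:, 0])
    area = float(np.sum(dp * (c[1:, 1] + c[:-1, 1])) / 2)
    return 1.0 - 2.0 * area


def gini_series(traj, gfp_artifice: bool = True) -> pd.DataFrame:
    """Hourly Gini coefficients for one simulated (or observed) population.

    Parameters
    ----------
    traj
        A :class:`~clonefate.model.PopulationTrajectory` (anything with
        ``hours``, ``living`` and ``gfp`` attributes, the latter two of
        shape (n_clones, n_hours)).
    gfp_artifice
        The GFP-positive Gini is computed over clones holding at least one
        GFP+ cell at the final hour.  When this flag is set (default), each
        such clone is credited one GFP+ cell from hour 0 until its first
        real GFP+ cell appears, so the GFP+ vector is never all-zero while
        any GFP+ clone exists.

    Returns
    -------
    pandas.DataFrame
        Columns ``hour``, ``gini_total``, ``gini_gfp``, ``n_cells``.
        Undefined values (mean clone size zero) are NaN.
    """
    living = np.asarray(traj.living)
    gfp = np.asarray(traj.gfp)
    if living.ndim != 2 or living.shape[0] == 0:
        raise ValueError("trajectory has no clones")
    hours = np.asarray(traj.hours)

    g_tot = gini_matrix(living)

    gfp_clone = gfp[:, -1] >= 1
    if gfp_clone.any():
        gm = gfp[gfp_clone].astype(float).copy()
        if gfp_artifice:
            # credit one GFP+ cell at t=0, carried until the first real one
            for row in gm:
                first = np.argmax(row >= 1)
                row[:first] = np.maximum(row[:first], 1.0)
        g_gfp = gini_matrix(gm)
    else:
        g_gfp = np.full(living.shape[1], np.nan)

    return pd.DataFrame(
        {
            "hour": hours,
            "gini_total": g_tot,
            "gini_gfp": g_gfp,
            "n_cells": living.sum(axis=0),
        }
    )


@dataclass
class GiniSeries:
    """Wrapper pairing a gini series table with its source run id."""

    table: pd.DataFrame
    run_id: int | None = None

    def to_csv(self, path) -> None:
        # empty field marks undefined Gini values
        self.table.to_csv(path, index=False)
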