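"""Exposure to ocean warming.

Per grid cell, the ensemble-mean change in SST between a 30-year baseline
and a 30-year future period is computed per climate model and averaged.
The distribution of |dSST| over all valid ocean cells is split into three
categories (0 = low, 1 = mid, 2 = high); per species, exposure is

    P = a*0 + b*1 + c*2

with a, b, c the fractions of the species' range cells in each category, so
P lies in [0, 2] and is independent of range size.  Warming and cooling
count alike (absolute change).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .grids import GridError, GridField, RangeMatrix

log = logging.getLogger(__name__)

SCHEMES = ("tertile", "equal_range")


class ExposureError(ValueError):
    pass


def ensemble_delta(baselines: Sequence[GridField], futures: Sequence[GridField],
                   scenario: str = "", period: str = "") -> GridField:
    """Ensemble-mean dSST field: mean over models of (future - baseline).

    The result is defined exactly on cells valid in every member model's
    baseline and future fields.  Scenario/period labels and the member count
    are carried in ``meta``.
    """
    if len(baselines) == 0 or len(baselines) != len(futures):
        raise ExposureError(
            f"need equal, non-zero numbers of baseline and future fields, "
            f"got {len(baselines)} and {len(futures)}")
    ref = baselines[0]
    for f in list(baselines) + list(futures):
        if not ref.same_grid(f):
            raise GridError("ensemble member grids are not aligned")
    mask = np.ones_like(ref.mask)
    total = np.zeros_like(ref.values)
    for b, f in zip(baselines, futures):
        mask &= b.mask & f.mask
        total += f.values - b.values
    delta = total / len(baselines)
    return GridField(lat=ref.lat.copy(), lon=ref.lon.copy(),
                     values=np.where(mask, delta, 0.0), mask=mask,
                     meta={"scenario": scenario, "period": period,
                           "n_models": len(baselines)})


def _category_breakpoints(abs_delta: np.ndarray, scheme: str) -> tuple[float, float]:
    if scheme == "tertile":
        q1, q2 = np.quantile(abs_delta, [1 / 3, 2 / 3])
    elif scheme == "equal_range":
        lo, hi = abs_delta.min(), abs_delta.max()
        q1 = lo + (hi - lo) / 3
        q2 = lo + 2 * (hi - lo) / 3
    else:
        raise ExposureError(f"unknown categorization scheme {scheme!r}; "
                            f"expected one of {SCHEMES}")
    return float(q1), float(q2)


def categorize_delta(delta: GridField, scheme: str = "tertile") -> GridField:
    """Split |dSST| over all valid cells into categories {0, 1, 2}.

    ``tertile`` uses equal-frequency breakpoints (33.3/66.7 percentiles of
    the all-ocean distribution); ``equal_range`` splits [min, max] of |dSST|
    into three equal widths.  Values exactly at a breakpoint fall in the
    lower category.  A constant field carries no contrast: every cell is
    category 0 (with a warning).
    """
    vals = np.abs(delta.valid_values())
    if vals.size == 0:
        raise ExposureError("delta field has no valid cells")
    cats = np.zeros_like(delta.values)
    if np.ptp(vals) == 0:
        log.warning("constant |dSST| field: all cells assigned category 0")
    else:
        q1, q2 = _category_breakpoints(vals, scheme)
        a = np.abs(delta.values)
        cats = np.where(a <= q1, 0, np.where(a <= q2, 1, 2)).astype(float)
    out = delta.copy(values=np.where(delta.mask, cats, 0.0))
    out.meta["scheme"] = scheme
    return out


def compute_exposure(ranges: RangeMatrix, categories: GridField) -> pd.DataFrame:
    """Per-species category fractions a, b, c and exposure P = b + 2c.

    Range cells falling on masked grid cells are ignored; a species whose
    entire range is masked gets missing a/b/c/P (with a warning) rather than
    a fabricated zero.
    """
    i, j = ranges.cell_indices_on(categories)
    cell_cat = categories.values[i, j]
    cell_ok = categories.mask[i, j]
    rows = []
    for sp, row in zip(ranges.species, ranges.presence):
        ok = row & cell_ok
        n = int(ok.sum())
        if n == 0:
            log.warning("species %s: entire range masked; exposure undefined", sp)
            rows.append({"species": sp, "a": np.nan, "b": np.nan, "c": np.nan,
                         "P": np.nan, "n_cells": 0})
            continue
        cats = cell_cat[ok]
        a = float((cats == 0).sum()) / n
        b = float((cats == 1).sum()) / n
        c = float((cats == 2).sum()) / n
        rows.append({"species": sp, "a": a, "b": b, "c": c,
                     "P": b + 2 * c, "n_cells": n})
    out = pd.DataFrame(rows).set_index("species")
    for key in ("scenario", "period", "scheme"):
        if key in categories.meta:
            out.attrs[key] = categories.meta[key]
    return out


class ExposureScorer(BaseEstimator):
    """Scikit-learn style wrapper: fit on a dSST field, transform ranges.

    ``fit`` learns the global |dSST| category breakpoints (per scenario x
    period field, applied identically to every species); ``transform`` turns
    a :class:`RangeMatrix` into the per-species a/b/c/P table.
    """

    def __init__(self, scheme: str = "tertile"):
        self.scheme = scheme

    def fit(self, delta: GridField, y=None) -> "ExposureScorer":
        self.categories_ = categorize_delta(delta, self.scheme)
        vals = np.abs(delta.valid_values())
        self.breakpoints_ = (_category_breakpoints(vals, self.scheme)
                             if np.ptp(vals) > 0 else (np.inf, np.inf))
        return self

    def transform(self, ranges: RangeMatrix) -> pd.DataFrame:
        check_is_fitted(self, "categories_")
        return compute_exposure(ranges, self.categories_)
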