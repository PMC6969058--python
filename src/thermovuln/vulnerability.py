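"""Vulnerability V = P x S, species ranking, and assemblage-level mapping.

A species that is intrinsically sensitive counts as vulnerable only where it
is actually exposed: the index is the plain product of sensitivity S (0..1)
and exposure P (0..2).  Assemblage maps average V over the species present
in each grid cell (unweighted), and latitudinal profiles average the map per
1-degree band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridField, RangeMatrix


class VulnerabilityError(ValueError):
    pass


def compute_vulnerability(S: pd.Series, P: pd.Series) -> pd.DataFrame:
    """Per-species table with S, P and V = P x S.

    ``S`` and ``P`` must cover the same species pool; species with missing
    exposure get missing V.
    """
    s_idx, p_idx = set(S.index), set(P.index)
    if s_idx != p_idx:
        raise VulnerabilityError(
            f"species mismatch between S and P: only-in-S={sorted(s_idx - p_idx)[:5]}, "
            f"only-in-P={sorted(p_idx - s_idx)[:5]}")
    out = pd.DataFrame({"S": S.astype(float), "P": P.reindex(S.index).astype(float)})
    out["V"] = out["S"] * out["P"]
    out.index.name = "species"
    return out


def rank_species(V: pd.DataFrame, top_k: int | None = None) -> pd.DataFrame:
    """Order species by descending V; ties by descending S, then species id.

    Adds a 1-based ``rank`` column (1 = most vulnerable).  Species with
    missing V are dropped from the ranking.
    """
    df = V.dropna(subset=["V"]).copy()
    if df.empty:
        raise VulnerabilityError("no species with defined vulnerability")
    df = df.iloc[np.lexsort((df.index.to_numpy(), -df["S"].to_numpy(),
                             -df["V"].to_numpy()))]
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top_k) if top_k is not None else df


def assemblage_map(ranges: RangeMatrix, V: pd.DataFrame,
                   grid: GridField) -> GridField:
    """Mean vulnerability of the species present in each grid cell.

    Cells with no species (or only species with undefined V) are masked.
    """
    v = V["V"].reindex(ranges.species)
    i, j = ranges.cell_indices_on(grid)
    total = np.zeros_like(grid.values)
    count = np.zeros_like(grid.values)
    vals = v.to_numpy(float)
    for row, val in zip(ranges.presence, vals):
        if not np.isfinite(val):
            continue
        total[i[row], j[row]] += val
        count[i[row], j[row]] += 1
    mask = (count > 0) & grid.mask
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(mask, total / np.maximum(count, 1), 0.0)
    return GridField(lat=grid.lat.copy(), lon=grid.lon.copy(),
                     values=mean, mask=mask, meta={"quantity": "assemblage_V"})


def latitudinal_profile(field: GridField) -> pd.DataFrame:
    """Mean of valid cell values per latitude band, with the peak flagged.

    Returns a DataFrame (lat, mean, n_cells, is_peak); bands with no valid
    cells carry NaN.  The peak is the band with the largest mean (ties: the
    southernmost such band).
    """
    if field.n_valid == 0:
        raise VulnerabilityError("cannot profile an all-masked field")
    sums = np.where(field.mask, field.values, 0.0).sum(axis=1)
    counts = field.mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    peak = int(np.nanargmax(means))
    df = pd.DataFrame({"lat": field.lat, "mean": means, "n_cells": counts})
    df["is_peak"] = False
    df.loc[peak, "is_peak"] = True
    return df


def peak_latitude(field: GridField) -> float:
    prof = latitudinal_profile(field)
    return float(prof.loc[prof["is_peak"], "lat"].iloc[0])
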