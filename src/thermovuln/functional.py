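"""Functional trait space: weighted Gower distances, PCoA, FRic, originality.

Functional traits are weighted so that each of the five ecological functions
contributes equally (1/5 split evenly among its traits).  Pairwise
dissimilarity is Gower's coefficient (range-normalised numeric contrast,
0/1 categorical mismatch, pairwise deletion of missing values).  A classical
principal-coordinates embedding of the distance matrix yields the reduced
functional space (default 4 axes); functional richness (FRic) is the convex
hull volume occupied by a species set in that space, and functional
originality is a species' distance to its nearest neighbour on the raw
Gower matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator, TransformerMixin

from .schema import CATEGORIES, QUALITATIVE, QUANTITATIVE, SchemaError, TraitSchema

log = logging.getLogger(__name__)


class FunctionalSpaceError(ValueError):
    pass


def function_weights(schema: TraitSchema) -> pd.Series:
    """Per-trait Gower weights giving each of the five functions weight 1/5.

    Within a function the 1/5 is split equally among its functional traits;
    the weights sum to 1.
    """
    schema.require_functional_coverage()
    traits = schema.functional_traits
    per_cat = {c: sum(1 for t in traits if t.category == c) for c in CATEGORIES}
    w = {t.name: 1.0 / (len(CATEGORIES) * per_cat[t.category]) for t in traits}
    return pd.Series(w, name="weight")


def gower_distance(traits: pd.DataFrame, schema: TraitSchema,
                   weights: pd.Series | None = None) -> pd.DataFrame:
    """Weighted Gower distance matrix over the functional traits.

    d(i,j) = sum_t w_t * delta_t(i,j) / sum_t w_t, the sums running over
    traits where both species have values.  delta is |x_i - x_j| / range for
    quantitative traits (0 if the trait is constant) and a 0/1 mismatch for
    qualitative ones.  Symmetric, zero diagonal, values in [0, 1].  A pair of
    species sharing no scored trait is an error.
    """
    if len(traits) < 2:
        raise FunctionalSpaceError("Gower distance needs at least 2 species")
    if weights is None:
        weights = function_weights(schema)
    n = len(traits)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for trait in schema.functional_traits:
        w = float(weights[trait.name])
        col = traits[trait.name]
        if trait.kind == QUANTITATIVE:
            x = col.to_numpy(float)
            ok = np.isfinite(x)
            rng = np.ptp(x[ok]) if ok.any() else 0.0
            diff = np.abs(x[:, None] - x[None, :])
            delta = diff / rng if rng > 0 else np.zeros((n, n))
        else:
            x = col.to_numpy(object)
            ok = pd.notna(col).to_numpy()
            delta = (x[:, None] != x[None, :]).astype(float)
        both = ok[:, None] & ok[None, :]
        num += np.where(both, delta, 0.0) * w
        den += both * w
    if (den == 0).any():
        ii, jj = np.nonzero(den == 0)
        off = [(traits.index[a], traits.index[b]) for a, b in zip(ii, jj) if a < b]
        raise FunctionalSpaceError(
            f"species pairs share no non-missing functional trait: {off[:5]}")
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against float noise
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


@dataclass
class FunctionalSpace:
    """A reduced PCoA embedding of a functional distance matrix."""

    coordinates: pd.DataFrame          # species x n_axes
    eigenvalues: np.ndarray            # per retained axis, decreasing
    quality_msd: float                 # mean squared deviation, lower = better
    distances: pd.DataFrame            # the source matrix
    negative_eigenvalue_magnitude: float = 0.0

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    @property
    def species(self) -> list[str]:
        return list(self.coordinates.index)


def pcoa(dist: pd.DataFrame, n_axes: int = 4) -> FunctionalSpace:
    """Classical scaling (principal coordinates) of a distance matrix.

    The doubly centred matrix -D^2/2 is eigendecomposed; coordinates are
    eigenvectors scaled by the square root of their (positive) eigenvalues.
    Negative eigenvalues -- possible because Gower distances need not be
    Euclidean -- are dropped and their total magnitude logged and recorded.
    """
    D = np.asarray(dist, float)
    n = D.shape[0]
    if n < n_axes + 1:
        raise FunctionalSpaceError(
            f"PCoA with {n_axes} axes needs at least {n_axes + 1} species, got {n}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-10, 1e-10 * abs(vals[0]) if vals.size else 0)
    pos = vals > tol
    neg_mag = float(-vals[vals < -tol].sum())
    if neg_mag > 0:
        log.info("PCoA: dropped negative eigenvalues of total magnitude %.3g",
                 neg_mag)
    if pos.sum() < n_axes:
        raise FunctionalSpaceError(
            f"only {int(pos.sum())} positive eigenvalues; reduce n_axes from {n_axes}")
    keep = np.flatnonzero(pos)[:n_axes]
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    coord_df = pd.DataFrame(coords, index=dist.index,
                            columns=[f"axis{k + 1}" for k in range(n_axes)])
    space = FunctionalSpace(coordinates=coord_df, eigenvalues=vals[keep],
                            quality_msd=np.nan, distances=dist.copy(),
                            negative_eigenvalue_magnitude=neg_mag)
    space.quality_msd = space_quality_msd(dist, space)
    return space


def space_quality_msd(dist: pd.DataFrame, space: FunctionalSpace) -> float:
    """Mean squared deviation between source and embedded distances.

    Euclidean distances in the reduced space are rescaled so their maximum
    matches the maximum source distance before comparison, making the metric
    comparable across dimensionalities; 0 means a faithful embedding.
    """
    D = np.asarray(dist, float)
    X = space.coordinates.to_numpy()
    diff = X[:, None, :] - X[None, :, :]
    E = np.sqrt((diff ** 2).sum(axis=-1))
    if E.max() > 0:
        E = E * (D.max() / E.max())
    iu = np.triu_indices(D.shape[0], k=1)
    return float(((D[iu] - E[iu]) ** 2).mean())


@dataclass
class FRicValue:
    """Convex-hull volume of a species set in the reduced space."""

    volume: float
    fraction_of_pool: float
    degenerate: bool = False


def hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """Convex hull volume in ``points.shape[1]`` dimensions.

    Fewer than d+1 points, or an affinely dependent set, has zero volume and
    is flagged degenerate.
    """
    pts = np.asarray(points, float)
    if pts.shape[0] < pts.shape[1] + 1:
        return 0.0, True
    try:
        return float(ConvexHull(pts).volume), False
    except QhullError:
        return 0.0, True


def fric(space: FunctionalSpace, subset: list[str] | None = None) -> FRicValue:
    """FRic of ``subset`` (default: full pool), absolute and as pool fraction."""
    pool_vol, pool_degen = hull_volume(space.coordinates.to_numpy())
    if subset is None:
        return FRicValue(pool_vol, 1.0 if pool_vol > 0 else 0.0, pool_degen)
    if len(subset) == 0:
        raise FunctionalSpaceError("FRic of an empty species set is undefined")
    missing = sorted(set(subset) - set(space.species))
    if missing:
        raise FunctionalSpaceError(f"species not in functional space: {missing[:5]}")
    vol, degen = hull_volume(space.coordinates.loc[list(subset)].to_numpy())
    frac = vol / pool_vol if pool_vol > 0 else 0.0
    return FRicValue(vol, frac, degen)


def functional_originality(dist: pd.DataFrame) -> pd.Series:
    """Distance of each species to its nearest neighbour (raw Gower matrix)."""
    D = np.asarray(dist, float)
    if D.shape[0] < 2:
        raise FunctionalSpaceError("originality needs at least 2 species")
    masked = D + np.diag(np.full(D.shape[0], np.inf))
    return pd.Series(masked.min(axis=1), index=dist.index, name="originality")


class GowerPCoA(BaseEstimator, TransformerMixin):
    """Estimator facade: trait table in, functional space out.

    ``fit`` builds the function weights, the Gower matrix and the reduced
    PCoA space; ``transform`` returns the species coordinates.  Fitted
    attributes: ``weights_``, ``distances_``, ``space_``, ``eigenvalues_``,
    ``quality_msd_``, ``originality_``.
    """

    def __init__(self, schema: TraitSchema, n_axes: int = 4):
        self.schema = schema
        self.n_axes = n_axes

    def fit(self, X: pd.DataFrame, y=None) -> "GowerPCoA":
        self.weights_ = function_weights(self.schema)
        self.distances_ = gower_distance(X, self.schema, self.weights_)
        self.space_ = pcoa(self.distances_, self.n_axes)
        self.eigenvalues_ = self.space_.eigenvalues
        self.quality_msd_ = self.space_.quality_msd
        self.originality_ = functional_originality(self.distances_)
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "space_")
        return self.space_.coordinates
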