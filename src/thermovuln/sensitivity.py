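"""Intrinsic sensitivity to ocean warming.

Each trait is scored on a three-point scale (0 = least, 2 = most sensitive).
Quantitative traits are binned by splitting the observed value range into
three equal-width parts; qualitative traits carry an explicit modality->rank
map.  The per-species sum of ranks is normalised by the maximum observed sum,
so the most sensitive species in the pool sits at S = 1 exactly.

The public surface is the scikit-learn style :class:`SensitivityScorer`
(fit learns the pool-dependent bin edges and normaliser, transform emits the
per-trait ranks, raw score and S), thin functional wrappers, and the
breakpoint-perturbation robustness analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .schema import QUALITATIVE, QUANTITATIVE, SchemaError, TraitSchema

log = logging.getLogger(__name__)

DEFAULT_BREAKPOINTS: tuple[float, float] = (1 / 3, 2 / 3)


class SensitivityError(ValueError):
    pass


def rank_quantitative_trait(values: pd.Series | np.ndarray,
                            breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS,
                            ) -> pd.Series:
    """Rank numeric values into {0, 1, 2} by equal parts of their range.

    ``breakpoints`` are fractions of the observed [min, max] range.  Bins are
    right-open except the last, which is closed at the maximum, so the extreme
    values deterministically take ranks 0 and 2.  A constant trait (zero-width
    range) carries no contrast and ranks every species 0.  Missing values stay
    missing.
    """
    s = pd.Series(values).astype(float)
    finite = s.dropna()
    if finite.empty:
        raise SensitivityError("all values missing for quantitative trait")
    b1, b2 = breakpoints
    if not 0 <= b1 <= b2 <= 1:
        raise SensitivityError(f"breakpoints must satisfy 0 <= b1 <= b2 <= 1, got {breakpoints}")
    lo, hi = float(finite.min()), float(finite.max())
    width = hi - lo
    out = pd.Series(np.nan, index=s.index)
    if width == 0:
        out[s.notna()] = 0.0
        return out
    edge1 = lo + b1 * width
    edge2 = lo + b2 * width
    vals = s[s.notna()]
    ranks = np.where(vals < edge1, 0, np.where(vals < edge2, 1, 2)).astype(float)
    out[s.notna()] = ranks
    return out


def rank_qualitative_trait(values: pd.Series, rank_map: dict) -> pd.Series:
    """Map modalities to their declared ranks; missing values stay missing."""
    s = pd.Series(values, dtype=object)
    bad = sorted({v for v in s.dropna().unique() if v not in rank_map})
    if bad:
        raise SchemaError(f"modalities without a rank: {bad}")
    return s.map(rank_map).astype(float)


class SensitivityScorer(BaseEstimator, TransformerMixin):
    """Trait-based sensitivity index on [0, 1].

    Parameters
    ----------
    schema:
        Trait schema; only traits with ``use_sensitivity`` contribute.
    breakpoints:
        Range fractions splitting quantitative traits into three bins
        (default equal thirds).

    Attributes (after fit)
    ----------------------
    trait_ranges_:
        ``{trait: (min, max)}`` learned per quantitative trait.
    max_raw_score_:
        Pool maximum of the rank sum; the normalisation denominator.
    """

    def __init__(self, schema: TraitSchema,
                 breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS):
        self.schema = schema
        self.breakpoints = breakpoints

    def _rank_table(self, X: pd.DataFrame) -> pd.DataFrame:
        ranks = {}
        for trait in self.schema.sensitivity_traits:
            if trait.kind == QUANTITATIVE:
                ranks[trait.name] = rank_quantitative_trait(
                    X[trait.name], self.breakpoints)
            else:
                ranks[trait.name] = rank_qualitative_trait(
                    X[trait.name], trait.rank_map)
        return pd.DataFrame(ranks, index=X.index)

    def fit(self, X: pd.DataFrame, y=None) -> "SensitivityScorer":
        if len(X) == 0:
            raise SensitivityError("empty species pool")
        if not self.schema.sensitivity_traits:
            raise SensitivityError("schema declares no sensitivity traits")
        ranks = self._rank_table(X)
        raw = ranks.fillna(0.0).sum(axis=1)
        self.n_traits_ = ranks.shape[1]
        self.max_raw_score_ = float(raw.max())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-trait ranks plus ``raw_score``, ``S`` and ``n_missing_traits``.

        Missing trait ranks contribute 0 to the raw score (conservative: no
        imputation) and are counted per species.  If every raw score in the
        fitted pool was 0 the index is identically 0.
        """
        check_is_fitted(self, "max_raw_score_")
        ranks = self._rank_table(X)
        out = ranks.copy()
        out["n_missing_traits"] = ranks.isna().sum(axis=1).astype(int)
        n_miss = int(out["n_missing_traits"].sum())
        if n_miss:
            log.info("sensitivity: %d missing trait ranks treated as 0", n_miss)
        out["raw_score"] = ranks.fillna(0.0).sum(axis=1)
        denom = self.max_raw_score_
        out["S"] = out["raw_score"] / denom if denom > 0 else 0.0
        return out

    def score_table(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)


def compute_sensitivity(traits: pd.DataFrame, schema: TraitSchema,
                        breakpoints: tuple[float, float] = DEFAULT_BREAKPOINTS,
                        ) -> pd.DataFrame:
    """Fit-and-score in one call; see :class:`SensitivityScorer`."""
    return SensitivityScorer(schema, breakpoints).score_table(traits)


def shifted_breakpoints(delta: float) -> tuple[float, float]:
    """Move both breakpoints inward by ``delta`` of one bin width (1/3).

    ``delta`` is the perturbation magnitude as a fraction of a bin; at 0.5
    the two edges would meet and the middle bin invert, so that is rejected.
    """
    if not 0 <= delta < 0.5:
        raise SensitivityError(
            f"breakpoint shift must be in [0, 0.5); at {delta} the bins invert")
    return ((1 + delta) / 3, (2 - delta) / 3)


def breakpoint_robustness(traits: pd.DataFrame, schema: TraitSchema,
                          deltas: np.ndarray | list[float] | None = None,
                          ) -> pd.DataFrame:
    """Rank-stability of S under perturbed quantitative-trait breakpoints.

    For each ``delta`` (default 1%..33% of a bin width) the index is
    recomputed with breakpoints shifted inward by that fraction and compared
    to the default ranking via Spearman correlation.  Qualitative traits are
    unaffected by construction.
    """
    if len(traits) < 2:
        raise SensitivityError("robustness analysis needs at least 2 species")
    if deltas is None:
        deltas = np.arange(0.01, 0.34, 0.01)
    base = compute_sensitivity(traits, schema)["S"]
    rows = []
    for d in np.asarray(deltas, float):
        shifted = compute_sensitivity(traits, schema, shifted_breakpoints(d))["S"]
        if base.nunique() == 1 and shifted.nunique() == 1:
            rho = 1.0  # both rankings fully tied: identical by convention
        else:
            rho = float(stats.spearmanr(base, shifted).statistic)
        rows.append({"delta": float(d), "spearman": rho})
    return pd.DataFrame(rows)
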