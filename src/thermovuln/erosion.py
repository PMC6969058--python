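"""Extinction-order simulations and diversity-erosion curves.

Species are removed one at a time from the global pool and the remaining
functional richness (FRic, convex-hull fraction) or phylogenetic diversity
(Faith PD fraction, averaged over the tree set) is recorded at every step.
Four scenario families are supported:

* ``vulnerability`` -- most vulnerable species go extinct first;
* ``random`` -- fully random orders (default 999 replicates, mean and SD);
* ``iucn_vulnerability`` -- IUCN groups in CR, EN, VU, NT, LC, DD order,
  by descending vulnerability within each group;
* ``iucn_random`` -- same group order, random within groups (999 replicates).

Replicate r draws its permutation from a generator seeded ``seed + r`` so
every replicate is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .functional import FunctionalSpace, hull_volume
from .io import IUCN_ORDER
from .trees import Phylogeny
from .vulnerability import rank_species

DETERMINISTIC_KINDS = ("vulnerability", "iucn_vulnerability")
RANDOM_KINDS = ("random", "iucn_random")


class ErosionError(ValueError):
    pass


@dataclass
class ErosionScenario:
    """One removal-order family; deterministic kinds have one replicate."""

    kind: str
    n_replicates: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DETERMINISTIC_KINDS + RANDOM_KINDS:
            raise ErosionError(f"unknown scenario kind {self.kind!r}")
        if self.kind in DETERMINISTIC_KINDS:
            self.n_replicates = 1
        elif self.n_replicates < 1:
            raise ErosionError("stochastic scenarios need n_replicates >= 1")


def vulnerability_order(V: pd.DataFrame) -> list[str]:
    """Removal order: descending V, ties by descending S then species id."""
    return list(rank_species(V).index)


def iucn_vulnerability_order(V: pd.DataFrame, status: pd.Series) -> list[str]:
    """CR -> EN -> VU -> NT -> LC -> DD groups, descending V within each."""
    ranked = rank_species(V)
    order: list[str] = []
    for cat in IUCN_ORDER:
        order.extend(s for s in ranked.index if status.get(s) == cat)
    leftover = [s for s in ranked.index if s not in set(order)]
    if leftover:
        raise ErosionError(f"species without IUCN status: {leftover[:5]}")
    return order


def _random_order(pool: list[str], rng: np.random.Generator) -> list[str]:
    return [pool[i] for i in rng.permutation(len(pool))]


def _iucn_random_order(pool: list[str], status: pd.Series,
                       rng: np.random.Generator) -> list[str]:
    order: list[str] = []
    for cat in IUCN_ORDER:
        members = [s for s in pool if status.get(s) == cat]
        order.extend(members[i] for i in rng.permutation(len(members)))
    if len(order) != len(pool):
        missing = sorted(set(pool) - set(order))
        raise ErosionError(f"species without IUCN status: {missing[:5]}")
    return order


def build_orders(scenario: ErosionScenario, pool: list[str],
                 V: pd.DataFrame | None = None,
                 iucn: pd.Series | None = None) -> list[list[str]]:
    """The removal orders (one per replicate) a scenario prescribes."""
    if scenario.kind in ("vulnerability", "iucn_vulnerability"):
        if V is None:
            raise ErosionError(f"{scenario.kind} scenario needs vulnerabilities")
        if scenario.kind == "vulnerability":
            order = vulnerability_order(V)
        else:
            if iucn is None:
                raise ErosionError("iucn_vulnerability scenario needs IUCN statuses")
            order = iucn_vulnerability_order(V, iucn)
        missing = sorted(set(pool) - set(order))
        if missing:
            raise ErosionError(f"pool species without vulnerability: {missing[:5]}")
        return [[s for s in order if s in set(pool)]]
    orders = []
    for r in range(scenario.n_replicates):
        rng = np.random.default_rng(scenario.seed + r)
        if scenario.kind == "random":
            orders.append(_random_order(pool, rng))
        else:
            if iucn is None:
                raise ErosionError("iucn_random scenario needs IUCN statuses")
            orders.append(_iucn_random_order(pool, iucn, rng))
    return orders


@dataclass
class ErosionCurve:
    """Remaining-diversity fraction per removal step.

    ``values`` is the replicate mean (= the single trajectory for
    deterministic kinds); ``sd`` is the across-replicate SD (zeros for a
    single replicate).  Step 0 is the intact pool (fraction 1).
    """

    metric: str
    kind: str
    steps: np.ndarray
    values: np.ndarray
    sd: np.ndarray
    n_pool: int
    n_replicates: int = 1
    species_removed: list[str] | None = None

    def at_step(self, k: int) -> float:
        if not 0 <= k < self.steps.size:
            raise ErosionError(f"step {k} outside computed range "
                               f"0..{self.steps.size - 1}")
        return float(self.values[k])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "step": self.steps,
            "pct_removed": 100.0 * self.steps / self.n_pool,
            "metric": self.metric,
            "scenario": self.kind,
            "mean": self.values,
            "sd": self.sd,
        })
        if self.species_removed is not None:
            df["species_removed"] = [""] + list(self.species_removed)[:len(df) - 1]
        return df


def fric_curve(space: FunctionalSpace, order: list[str],
               max_steps: int | None = None) -> np.ndarray:
    """FRic fraction remaining after each removal along ``order``.

    Below n_axes+1 remaining species the hull is degenerate and the fraction
    is 0 (the limiting value of a collapsed volume).
    """
    coords = space.coordinates
    pool_vol, _ = hull_volume(coords.to_numpy())
    if pool_vol <= 0:
        raise ErosionError("pool has zero functional volume; erosion undefined")
    n = len(order)
    kmax = n if max_steps is None else min(max_steps, n)
    out = np.empty(kmax + 1)
    out[0] = 1.0
    remaining = list(coords.index)
    for k in range(1, kmax + 1):
        remaining.remove(order[k - 1])
        if remaining:
            vol, _ = hull_volume(coords.loc[remaining].to_numpy())
        else:
            vol = 0.0
        out[k] = vol / pool_vol
    return out


def pd_curve(tree: Phylogeny, order: list[str],
             max_steps: int | None = None) -> np.ndarray:
    """PD fraction remaining after each removal along ``order`` (one tree).

    Vectorised: an edge survives while at least one of its descendant tips
    remains, so the per-step remaining-tip counts per edge come from one
    cumulative sum over the removal sequence.
    """
    idx = tree.tip_index(order)
    inc = tree.incidence
    if idx.size != inc.shape[0]:
        raise ErosionError("removal order must cover every tip of the tree")
    lengths = tree.edge_lengths
    total = lengths.sum()
    n = idx.size
    kmax = n if max_steps is None else min(max_steps, n)
    removed_cum = np.cumsum(inc[idx[:kmax]], axis=0)      # (kmax, n_edges)
    tips_per_edge = inc.sum(axis=0)
    remaining = tips_per_edge[None, :] - removed_cum
    pd_steps = (remaining > 0) @ lengths                  # (kmax,)
    out = np.empty(kmax + 1)
    out[0] = 1.0
    out[1:] = pd_steps / total
    return out


def run_erosion(scenario: ErosionScenario, metric: str,
                space: FunctionalSpace | None = None,
                trees: list[Phylogeny] | None = None,
                V: pd.DataFrame | None = None,
                iucn: pd.Series | None = None,
                max_steps: int | None = None) -> ErosionCurve:
    """Erosion curve for one scenario and one metric (``fric`` or ``pd``).

    PD is averaged over the supplied tree set at every step; stochastic
    scenarios report the mean and SD over replicates.
    """
    if metric == "fric":
        if space is None:
            raise ErosionError("FRic erosion needs a functional space")
        pool = space.species
    elif metric == "pd":
        if not trees:
            raise ErosionError("PD erosion needs at least one tree")
        pool = sorted(trees[0].tip_labels)
    else:
        raise ErosionError(f"unknown metric {metric!r}")

    orders = build_orders(scenario, pool, V=V, iucn=iucn)
    curves = []
    for order in orders:
        if metric == "fric":
            curves.append(fric_curve(space, order, max_steps))
        else:
            per_tree = [pd_curve(t, order, max_steps) for t in trees]
            curves.append(np.mean(per_tree, axis=0))
    stack = np.vstack(curves)
    values = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    return ErosionCurve(
        metric=metric, kind=scenario.kind,
        steps=np.arange(values.size), values=values, sd=sd,
        n_pool=len(pool), n_replicates=len(orders),
        species_removed=orders[0] if len(orders) == 1 else None,
    )


def compare_curves(scenario_curve: ErosionCurve, random_curve: ErosionCurve,
                   step: int) -> float:
    """Excess diversity loss of a scenario over the random mean, at ``step``.

    Returned in percentage points of the pool diversity; positive when the
    scenario has eroded more than random removal would.
    """
    if scenario_curve.metric != random_curve.metric \
            or scenario_curve.n_pool != random_curve.n_pool:
        raise ErosionError("curves compare only on the same pool and metric")
    return 100.0 * (random_curve.at_step(step) - scenario_curve.at_step(step))
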