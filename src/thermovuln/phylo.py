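"""Faith's phylogenetic diversity and evolutionary distinctiveness.

PD of a species subset is the total length of the branches on the union of
root-to-tip paths (rooted convention: PD of the full tip set equals the
tree's total branch length, and the erosion curve reaches 0 only when the
pool is empty).  Evolutionary distinctiveness apportions each branch among
species: under fair proportion every branch is split equally among its
descendant tips (so the per-species values sum exactly to the total branch
length); the equal-splits variant halves the contribution at every node on
the way down instead.  Both are averaged over a set of trees to absorb
topological uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .trees import Phylogeny, TreeError

FAIR_PROPORTION = "fair_proportion"
EQUAL_SPLITS = "equal_splits"


@dataclass
class PDValue:
    pd: float
    fraction_of_pool: float
    tree_id: int | None = None


def faith_pd(tree: Phylogeny, subset: Sequence[str]) -> PDValue:
    """Rooted Faith PD of ``subset``: branch length of the spanning paths."""
    if len(subset) == 0:
        raise TreeError("PD of an empty species set is undefined")
    idx = tree.tip_index(list(subset))
    keep = tree.incidence[idx].any(axis=0)
    total = tree.total_branch_length
    value = float(tree.edge_lengths[keep].sum())
    return PDValue(pd=value, fraction_of_pool=value / total if total > 0 else 0.0)


def evolutionary_distinctiveness(tree: Phylogeny,
                                 scheme: str = FAIR_PROPORTION) -> pd.Series:
    """Per-species ED on one tree (branch-length units)."""
    if scheme == FAIR_PROPORTION:
        inc = tree.incidence
        counts = inc.sum(axis=0)  # tips below each edge; >= 1 by construction
        shares = inc / counts
        ed = shares @ tree.edge_lengths
        return pd.Series(ed, index=tree.tip_labels, name="ed")
    if scheme == EQUAL_SPLITS:
        values: dict[str, float] = {}

        def walk(node, carried: float) -> None:
            children = node.child_nodes()
            if not children:
                values[node.taxon.label] = carried
                return
            share = carried / len(children)
            for child in children:
                walk(child, share + float(child.edge.length or 0.0))

        root = tree.dendropy_tree.seed_node
        if root is None:
            raise TreeError("equal-splits ED requires a rooted tree")
        walk(root, 0.0)
        return pd.Series([values[t] for t in tree.tip_labels],
                         index=tree.tip_labels, name="ed")
    raise ValueError(f"unknown ED scheme {scheme!r}")


def _check_consistent_tips(trees: Sequence[Phylogeny]) -> list[str]:
    tips = sorted(trees[0].tip_labels)
    for k, t in enumerate(trees[1:], start=2):
        if sorted(t.tip_labels) != tips:
            raise TreeError(f"tree {k} has a different tip set than tree 1")
    return tips


def aggregate_over_trees(trees: Sequence[Phylogeny],
                         per_tree: Callable[[Phylogeny], pd.Series],
                         ) -> pd.DataFrame:
    """Mean and SD across trees of any per-species (or per-item) statistic."""
    if len(trees) == 0:
        raise TreeError("need at least one tree")
    _check_consistent_tips(trees)
    table = pd.DataFrame({k: per_tree(t) for k, t in enumerate(trees)})
    return pd.DataFrame({"mean": table.mean(axis=1), "sd": table.std(axis=1, ddof=0)})


def ed_over_trees(trees: Sequence[Phylogeny],
                  scheme: str = FAIR_PROPORTION) -> pd.DataFrame:
    """Per-species ED mean and SD over a tree set (columns ed_mean, ed_sd)."""
    out = aggregate_over_trees(
        trees, lambda t: evolutionary_distinctiveness(t, scheme))
    return out.rename(columns={"mean": "ed_mean", "sd": "ed_sd"}) \
              .rename_axis("species")


def pd_over_trees(trees: Sequence[Phylogeny],
                  subset: Sequence[str]) -> pd.DataFrame:
    """PD (absolute and pool fraction) of one subset, mean and SD over trees."""
    if len(trees) == 0:
        raise TreeError("need at least one tree")
    _check_consistent_tips(trees)
    vals = np.array([faith_pd(t, subset).pd for t in trees])
    fracs = np.array([faith_pd(t, subset).fraction_of_pool for t in trees])
    return pd.DataFrame(
        {"mean": [vals.mean(), fracs.mean()], "sd": [vals.std(), fracs.std()]},
        index=["pd", "fraction_of_pool"])
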