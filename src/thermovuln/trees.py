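"""Phylogeny container and Newick/Nexus reading (dendropy-backed).

A :class:`Phylogeny` wraps a rooted dendropy tree and precomputes, on first
use, a tip x edge incidence matrix and the vector of edge lengths.  Both
Faith's PD and the diversity-erosion curves reduce to cheap boolean algebra
on that incidence structure.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for invalid trees or tip/species mismatches."""


class Phylogeny:
    """A rooted tree with non-negative branch lengths and unique tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label if leaf.taxon else None
                  for leaf in tree.leaf_node_iter()]
        if any(l is None for l in labels):
            raise TreeError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(
                    f"negative branch length {edge.length} on edge to "
                    f"{getattr(edge.head_node.taxon, 'label', '<internal>')}"
                )
        self.tip_labels: list[str] = labels
        self._edge_lengths: np.ndarray | None = None
        self._incidence: np.ndarray | None = None

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_edges(self) -> int:
        self._build()
        return int(self._edge_lengths.size)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def _build(self) -> None:
        """Precompute edge lengths and the tip x edge incidence matrix.

        The seed-node (root) edge has no length in Newick and is skipped; all
        other edges appear, so PD of the full tip set equals the total branch
        length.
        """
        if self._edge_lengths is not None:
            return
        tip_index = {label: i for i, label in enumerate(self.tip_labels)}
        lengths: list[float] = []
        cols: list[np.ndarray] = []
        # postorder: tips-below sets are unions of children's sets
        below: dict[int, np.ndarray] = {}
        n = self.n_tips
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                vec = np.zeros(n, bool)
                vec[tip_index[node.taxon.label]] = True
            else:
                vec = np.zeros(n, bool)
                for child in node.child_nodes():
                    vec |= below[id(child)]
            below[id(node)] = vec
            if node.parent_node is not None:  # skip the root's phantom edge
                lengths.append(float(node.edge.length or 0.0))
                cols.append(vec)
        self._edge_lengths = np.asarray(lengths, float)
        self._incidence = np.column_stack(cols) if cols else np.zeros((n, 0), bool)

    @property
    def edge_lengths(self) -> np.ndarray:
        self._build()
        return self._edge_lengths

    @property
    def incidence(self) -> np.ndarray:
        """Boolean ``(n_tips, n_edges)``: tip i descends from edge j."""
        self._build()
        return self._incidence

    @property
    def total_branch_length(self) -> float:
        return float(self.edge_lengths.sum())

    def tip_index(self, species: Sequence[str]) -> np.ndarray:
        lookup = {label: i for i, label in enumerate(self.tip_labels)}
        missing = [s for s in species if s not in lookup]
        if missing:
            raise TreeError(f"species not on tree: {missing[:10]}")
        return np.asarray([lookup[s] for s in species], int)

    def check_tips_against(self, pool: Iterable[str]) -> None:
        pool = set(pool)
        extra = sorted(set(self.tip_labels) - pool)
        if extra:
            raise TreeError(f"tree tips absent from species pool: {extra[:10]}")


def read_trees(path: str | Path, schema: str | None = None) -> list[Phylogeny]:
    """Read one or more trees from a Newick or Nexus file."""
    path = Path(path)
    if schema is None:
        schema = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".trees"} \
            else "newick"
    tl = dendropy.TreeList.get(path=str(path), schema=schema)
    if len(tl) == 0:
        raise TreeError(f"no trees found in {path}")
    return [Phylogeny(t) for t in tl]


def write_trees(trees: Sequence[Phylogeny], path: str | Path) -> None:
    text = "".join(t.as_newick() + "\n" for t in trees)
    Path(path).write_text(text)
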