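"""A rooted, binary, ultrametric dated tree in flat array form.

Node ids: tips are 0..n_tips-1; internal nodes follow in an order where
children always precede parents, so iterating internal rows in order is a
postorder sweep and the root is the last node.  Ages are in Ma with every tip
at the present (age 0); the branch above a node has length
``age[parent] - age[node]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import DataError

ULTRAMETRIC_TOL = 1e-6  # Myr


@dataclass(frozen=True)
class DatedTree:
    labels: tuple[str, ...]
    children: np.ndarray  # (n_internal, 2) node ids
    ages: np.ndarray      # (n_nodes,) Ma

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", np.asarray(self.children, dtype=np.intp).reshape(-1, 2))
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        n = self.n_tips
        if self.children.shape[0] != max(n - 1, 0):
            raise DataError("binary tree needs n_tips - 1 internal nodes")
        if len(self.ages) != self.n_nodes:
            raise DataError("ages length must equal node count")
        if (self.ages < 0).any():
            raise DataError("node ages must be non-negative")
        if len(set(self.labels)) != n:
            raise DataError("tip labels must be unique")
        for row, (a, b) in enumerate(self.children):
            node = n + row
            for c in (a, b):
                if not 0 <= c < node:
                    raise DataError("children must precede parents in node order")
                if self.ages[c] > self.ages[node] + 1e-12:
                    raise DataError(f"child {c} older than its parent {node}")

    # -- basic structure ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return self.n_tips + self.children.shape[0]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    @property
    def parent(self) -> np.ndarray:
        out = np.full(self.n_nodes, -1, dtype=np.intp)
        for row, (a, b) in enumerate(self.children):
            out[a] = out[b] = self.n_tips + row
        return out

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return 0.0 if p < 0 else float(self.ages[p] - self.ages[node])

    def internal_nodes(self) -> range:
        """Internal node ids in postorder (children before parents)."""
        return range(self.n_tips, self.n_nodes)

    @property
    def tip_index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels)}

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        parent = self.parent

        def render(node: int) -> str:
            if self.is_tip(node):
                core = self.labels[node]
            else:
                a, b = self.children[node - self.n_tips]
                core = f"({render(a)},{render(b)})"
            p = parent[node]
            if p < 0:
                return core
            return f"{core}:{float(self.ages[p] - self.ages[node])!r}"

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     suppress_internal_node_taxa=True)
        except Exception as exc:
            raise DataError(f"could not parse Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "DatedTree":
        root = tree.seed_node
        depth: dict = {root: 0.0}
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise DataError("every branch must carry a length")
            depth[node] = depth[node.parent_node] + float(node.edge.length)
        leaves = [n for n in tree.leaf_node_iter()]
        if len(leaves) < 1:
            raise DataError("tree has no tips")
        root_age = max(depth[n] for n in leaves)
        for n in leaves:
            if abs(depth[n] - root_age) > ULTRAMETRIC_TOL:
                name = n.taxon.label if n.taxon else "<unnamed>"
                raise DataError(
                    f"tree is not ultrametric: tip {name!r} sits at age "
                    f"{root_age - depth[n]:.6g} Ma, not 0"
                )
        labels: list[str] = []
        children_rows: list[tuple[int, int]] = []
        ages: list[float] = []
        ids: dict = {}
        # first pass: tips in postorder encounter order
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise DataError("every tip must be labelled")
                ids[node] = len(labels)
                labels.append(node.taxon.label)
        if len(set(labels)) != len(labels):
            raise DataError("duplicate tip labels")
        n_tips = len(labels)
        ages = [0.0] * n_tips
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            kids = node.child_nodes()
            if len(kids) != 2:
                raise DataError(
                    f"tree must be binary; found a node with {len(kids)} children"
                )
            ids[node] = n_tips + len(children_rows)
            children_rows.append((ids[kids[0]], ids[kids[1]]))
            ages.append(root_age - depth[node])
        return cls(tuple(labels), np.array(children_rows, dtype=np.intp).reshape(-1, 2),
                   np.array(ages))

    # -- convenience -------------------------------------------------------
    @classmethod
    def single_tip(cls, label: str, root_age: float = 0.0) -> "DatedTree":
        """Degenerate one-tip tree (the tip is its own root at ``root_age``).

        Represented with zero internal nodes; the root age is the tip age,
        which must be 0 for an ultrametric tree, so ``root_age`` > 0 is only
        meaningful for likelihood plumbing tests and is stored separately.
        """
        t = cls((label,), np.empty((0, 2), dtype=np.intp), np.zeros(1))
        object.__setattr__(t, "_single_root_age", float(root_age))
        return t

    @property
    def single_root_age(self) -> float:
        return getattr(self, "_single_root_age", self.root_age)
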