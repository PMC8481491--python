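"""Ultrametric-tree handling: Newick I/O, node ages, grafting, branching times.

All ages are expressed as time before present in Myr (present = 0, increasing
into the past); every module in the package shares this convention.  Trees are
stored in a flat array-backed form so that likelihood code can iterate branches
cheaply; dendropy is used only to tokenise Newick on input.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "UltrametricTree",
    "GraftPlan",
    "read_newick",
    "parse_newick",
    "write_newick",
    "graft_subclade",
    "branching_times",
]

#: absolute tolerance (Myr) within which a tree counts as ultrametric
ULTRAMETRIC_TOL = 1e-6
#: deviations below this are silently corrected by resetting tip ages to 0
ULTRAMETRIC_FIX_MAX = 1e-3


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


@dataclass
class UltrametricTree:
    """Rooted ultrametric tree with node ages in Myr before present.

    Nodes are integer ids ``0..n_nodes-1`` in a preorder-compatible order
    (every parent id precedes its children).  ``parent[root] == -1``.
    """

    parent: np.ndarray          # (n_nodes,) int; -1 at the root
    children: list[list[int]]   # (n_nodes,) child id lists; [] at tips
    labels: list[str | None]    # tip labels; internal labels optional
    age: np.ndarray             # (n_nodes,) float, Myr before present

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent == -1)[0][0])

    @property
    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_tips(self) -> int:
        return sum(1 for c in self.children if not c)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]  # type: ignore[misc]

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        if p < 0:
            return 0.0
        return float(self.age[p] - self.age[node])

    def tip_index(self) -> dict[str, int]:
        return {self.labels[i]: i for i in self.tips}  # type: ignore[misc]

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children[v]))
        return out

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def subtree_tips(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def mrca(self, labels: list[str]) -> int:
        idx = self.tip_index()
        nodes = set()
        for lab in labels:
            if lab not in idx:
                raise TreeError(f"tip label not in tree: {lab!r}")
            nodes.add(idx[lab])
        # walk each tip's ancestor path; MRCA = deepest common node
        paths = []
        for v in nodes:
            path = []
            while v != -1:
                path.append(v)
                v = int(self.parent[v])
            paths.append(set(path))
        common = set.intersection(*paths)
        return min(common, key=lambda v: float(self.age[v]))

    def is_bifurcating(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    # -- validation --------------------------------------------------------
    def max_ultrametric_deviation(self) -> float:
        tip_ages = self.age[[i for i in self.tips]]
        return float(np.max(np.abs(tip_ages)))

    def validate(self) -> None:
        if int(np.sum(self.parent == -1)) != 1:
            raise TreeError("tree must have exactly one root")
        labs = self.tip_labels
        if len(set(labs)) != len(labs):
            raise TreeError("duplicate tip labels")
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and self.age[p] < self.age[v] - 1e-12:
                raise TreeError(f"child {v} older than parent {p}")
        if np.any(self.age < -ULTRAMETRIC_TOL):
            raise TreeError("negative node ages")

    def copy(self) -> "UltrametricTree":
        return UltrametricTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            labels=list(self.labels),
            age=self.age.copy(),
        )

    # -- editing -----------------------------------------------------------
    def prune_tips(self, drop: set[str] | list[str]) -> "UltrametricTree":
        """Remove the named tips, suppressing resulting unifurcations."""
        drop = set(drop)
        keep = [lab for lab in self.tip_labels if lab not in drop]
        if len(keep) < 2:
            raise TreeError("pruning would leave fewer than 2 tips")
        return self.subtree_on_tips(keep)

    def subtree_on_tips(self, keep_labels: list[str]) -> "UltrametricTree":
        """Induced tree on the given tips (unifurcations collapsed)."""
        idx = self.tip_index()
        keep = set()
        for lab in keep_labels:
            if lab not in idx:
                raise TreeError(f"tip label not in tree: {lab!r}")
            keep.add(idx[lab])
        # count retained descendants per node
        ndesc = np.zeros(self.n_nodes, dtype=int)
        for v in self.postorder():
            if not self.children[v]:
                ndesc[v] = 1 if v in keep else 0
            else:
                ndesc[v] = sum(ndesc[c] for c in self.children[v])
        # new root: deepest node with all retained tips below
        total = ndesc[self.root]
        new_root = self.root
        while True:
            kids = [c for c in self.children[new_root] if ndesc[c] > 0]
            if len(kids) == 1 and ndesc[kids[0]] == total:
                new_root = kids[0]
            else:
                break
        parent, children, labels, age = [], [], [], []

        def build(v: int, new_parent: int) -> int:
            # descend through unifurcations
            while self.children[v]:
                kids = [c for c in self.children[v] if ndesc[c] > 0]
                if len(kids) == 1:
                    v = kids[0]
                else:
                    break
            me = len(parent)
            parent.append(new_parent)
            children.append([])
            labels.append(self.labels[v])
            age.append(float(self.age[v]))
            if new_parent >= 0:
                children[new_parent].append(me)
            if self.children[v]:
                for c in self.children[v]:
                    if ndesc[c] > 0:
                        build(c, me)
            return me

        import sys
        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, self.n_nodes + 100))
        try:
            build(new_root, -1)
        finally:
            sys.setrecursionlimit(old)
        return UltrametricTree(
            parent=np.array(parent, dtype=int),
            children=children,
            labels=labels,
            age=np.array(age, dtype=float),
        )


@dataclass
class GraftPlan:
    """Replace a placeholder tip in a backbone with a rescaled subclade."""

    placeholder: str
    subclade: UltrametricTree
    attachment_age: float


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> UltrametricTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    labels: list[str | None] = [None] * n
    depth = np.zeros(n)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            bl = nd.edge.length if nd.edge.length is not None else 0.0
            depth[i] = depth[p] + float(bl)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    height = float(depth.max())
    age = height - depth
    tree = UltrametricTree(parent=parent, children=children,
                           labels=labels, age=age)
    # enforce / repair ultrametricity
    dev = tree.max_ultrametric_deviation()
    if dev > ULTRAMETRIC_FIX_MAX:
        raise TreeError(
            f"tree is not ultrametric: max root-to-tip deviation {dev:.3g} Myr")
    if dev > 0:
        for t in tree.tips:
            tree.age[t] = 0.0
    tree.validate()
    return tree


def parse_newick(newick: str) -> UltrametricTree:
    """Parse a Newick string into an :class:`UltrametricTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"Newick parse failure: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise TreeError("empty tree")
    return _from_dendropy(dtree)


def read_newick(path) -> UltrametricTree:
    """Read a Newick file; the tree must be ultrametric (tol 1e-3 Myr)."""
    with open(path) as fh:
        return parse_newick(fh.read())


def _newick_token(label: str | None) -> str:
    if label is None:
        return ""
    if any(ch in label for ch in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: UltrametricTree, path=None, digits: int = 12) -> str:
    """Serialise to Newick with branch lengths at ``digits`` significant digits."""
    buf = io.StringIO()

    def rec(v: int) -> None:
        if tree.children[v]:
            buf.write("(")
            for k, c in enumerate(tree.children[v]):
                if k:
                    buf.write(",")
                rec(c)
            buf.write(")")
        buf.write(_newick_token(tree.labels[v]))
        if tree.parent[v] >= 0:
            buf.write(f":{tree.branch_length(v):.{digits}g}")

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, tree.n_nodes + 100))
    try:
        rec(tree.root)
    finally:
        sys.setrecursionlimit(old)
    buf.write(";")
    s = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------

def graft_subclade(backbone: UltrametricTree, plan: GraftPlan) -> UltrametricTree:
    """Replace a placeholder tip by a subclade rescaled to the attachment age.

    Every node age in the subclade is multiplied by
    ``attachment_age / subclade_root_age``, so the rescaled subclade root sits
    exactly at the attachment age; the placeholder's pendant branch is kept and
    shortened accordingly.
    """
    if plan.attachment_age <= 0:
        raise ValueError("attachment age must be positive")
    sub = plan.subclade
    sub_root_age = sub.root_age
    if sub_root_age <= 0:
        raise ValueError("subclade root age must be positive")
    idx = backbone.tip_index()
    if plan.placeholder not in idx:
        raise LookupError(f"placeholder tip {plan.placeholder!r} not in backbone")
    ph = idx[plan.placeholder]
    ph_parent = int(backbone.parent[ph])
    if ph_parent < 0:
        raise TreeError("placeholder may not be the root")
    if plan.attachment_age > backbone.age[ph_parent] + 1e-12:
        raise ValueError("attachment age exceeds the placeholder's parent age")

    scale = plan.attachment_age / sub_root_age
    nb = backbone.n_nodes
    parent = np.concatenate([backbone.parent, sub.parent + nb])
    children = [list(c) for c in backbone.children] + \
               [[c + nb for c in kids] for kids in sub.children]
    labels = list(backbone.labels) + list(sub.labels)
    age = np.concatenate([backbone.age, sub.age * scale])
    # splice: subclade root takes the placeholder's slot under ph_parent
    sub_root_new = nb + sub.root
    parent[sub_root_new] = ph_parent
    children[ph_parent] = [sub_root_new if c == ph else c
                           for c in children[ph_parent]]
    age[sub_root_new] = plan.attachment_age  # exact, not scale*root_age
    # drop the placeholder node by compacting ids
    keep = np.ones(len(parent), dtype=bool)
    keep[ph] = False
    remap = np.cumsum(keep) - 1
    new_parent = np.array([remap[p] if p >= 0 else -1
                           for p in parent[keep]], dtype=int)
    new_children = [[int(remap[c]) for c in children[i]]
                    for i in range(len(parent)) if keep[i]]
    new_labels = [labels[i] for i in range(len(parent)) if keep[i]]
    new_age = age[keep]
    out = UltrametricTree(parent=new_parent, children=new_children,
                          labels=new_labels, age=new_age)
    out.validate()
    return out


def branching_times(tree: UltrametricTree) -> np.ndarray:
    """Internal-node ages in descending order; first element is the crown age."""
    dev = tree.max_ultrametric_deviation()
    if dev > ULTRAMETRIC_TOL:
        raise TreeError(f"tree not ultrametric (max tip-age deviation {dev:.3g})")
    ages = [float(tree.age[v]) for v in range(tree.n_nodes) if tree.children[v]]
    return np.array(sorted(ages, reverse=True))
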