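"""Age-centric ultrametric tree model and temporal operations.

Everything downstream (lineage-through-time profiles, diversification model
fitting, ancestral-state reconstruction, split tallies) consumes the
:class:`TimeTree` defined here: a rooted tree whose primary per-node quantity
is the *age* — time before present in Ma — with branch lengths derived as
``parent.age - child.age``.  Tips of an ultrametric tree sit at age 0.

Newick/NEXUS parsing and serialisation are delegated to :mod:`dendropy`;
the temporal operations (branching profiles, truncation at an age line,
clade extraction, random tip pruning) are implemented here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Node",
    "TimeTree",
    "LTTProfile",
    "TreeError",
    "NotUltrametricError",
    "read_tree",
    "read_trees",
    "write_tree",
    "tree_from_newick",
    "branching_profile",
    "ltt_coordinates",
    "lineages_at",
    "truncate_tree",
    "extract_clade",
    "prune_random_tips",
]

#: tolerance (Ma) within which tip ages are snapped to zero
TIP_AGE_TOL = 1e-6
#: numerical slack for parent/child age ordering
AGE_ORDER_TOL = 1e-9


class TreeError(ValueError):
    """Structural problem with a tree or an operation's preconditions."""


class NotUltrametricError(TreeError):
    """Tip depths differ by more than the ultrametricity tolerance."""


class Node:
    """Tree node: parent/child links, optional tip label, age in Ma."""

    __slots__ = ("parent", "children", "label", "age")

    def __init__(self, label: str | None = None, age: float = 0.0):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.label = label
        self.age = age

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def branch_length(self) -> float | None:
        if self.parent is None:
            return None
        return self.parent.age - self.age

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.label if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {kind} age={self.age:.4g}>"


class TimeTree:
    """Rooted ultrametric tree with node ages in Ma (tips at age 0)."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            # reversed so children come out left-to-right
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_tip]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.preorder() if n.is_tip)

    @property
    def crown_age(self) -> float:
        return self.root.age

    @property
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    def find_tips(self, labels) -> list[Node]:
        wanted = set(labels)
        found = [t for t in self.tips() if t.label in wanted]
        missing = wanted - {t.label for t in found}
        if missing:
            raise TreeError(f"tip labels not in tree: {sorted(missing)}")
        return found

    def mrca(self, labels) -> Node:
        """Most recent common ancestor of a set of tip labels."""
        tips = self.find_tips(labels)
        paths = []
        for t in tips:
            path = []
            n: Node | None = t
            while n is not None:
                path.append(n)
                n = n.parent
            paths.append(path[::-1])
        depth = min(len(p) for p in paths)
        anc = self.root
        for i in range(depth):
            node = paths[0][i]
            if all(p[i] is node for p in paths):
                anc = node
            else:
                break
        return anc

    def copy(self) -> "TimeTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.age)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return TimeTree(clone(self.root))

    def validate(self) -> None:
        """Machine-check the TimeTree invariants; raise TreeError on failure."""
        n_tips = 0
        for node in self.preorder():
            if node.is_tip:
                n_tips += 1
                if node.label is None:
                    raise TreeError("unlabeled tip")
                if abs(node.age) > TIP_AGE_TOL:
                    raise NotUltrametricError(
                        f"tip {node.label!r} at age {node.age!r}, expected 0"
                    )
            if node.age < -AGE_ORDER_TOL:
                raise TreeError(f"negative node age {node.age!r}")
            for c in node.children:
                if c.age > node.age + AGE_ORDER_TOL:
                    raise TreeError(
                        f"child age {c.age!r} exceeds parent age {node.age!r}"
                    )
        if n_tips < 2:
            raise TreeError("tree must have at least 2 tips")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree n={self.n_tips} crown={self.crown_age:.4g} Ma>"


# ---------------------------------------------------------------------------
# I/O


def _from_dendropy(dtree: dendropy.Tree, force_ultrametric: bool) -> TimeTree:
    droot = dtree.seed_node
    # root-to-node depths from branch lengths
    depths: dict[dendropy.Node, float] = {droot: 0.0}
    for dnode in dtree.preorder_node_iter():
        if dnode is droot:
            continue
        if dnode.edge.length is None:
            raise TreeError("tree has missing branch lengths")
        depths[dnode] = depths[dnode.parent_node] + dnode.edge.length
    tip_depths = [depths[l] for l in dtree.leaf_node_iter()]
    height = max(tip_depths)
    if (height - min(tip_depths)) > TIP_AGE_TOL and not force_ultrametric:
        raise NotUltrametricError(
            f"tip depths span {min(tip_depths):.6g}..{height:.6g}; "
            "pass force_ultrametric=True to align tips to the deepest one"
        )

    def convert(dnode: dendropy.Node) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise TreeError("unlabeled tip")
            return Node(dnode.taxon.label, 0.0)
        age = height - depths[dnode]
        node = Node(None, max(age, 0.0))
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    tree = TimeTree(convert(droot))
    # clamp tiny negative branch lengths from rounding
    for node in tree.preorder():
        for c in node.children:
            if c.age > node.age:
                c.age = node.age
    tree.validate()
    return tree


def read_tree(source: str, schema: str = "newick",
              force_ultrametric: bool = False) -> TimeTree:
    """Read one tree from a path or a Newick/NEXUS string.

    Ages are reconstructed from root-to-tip path lengths; tips within
    1e-6 Ma of the maximum depth are snapped to age 0.  Larger deviations
    raise :class:`NotUltrametricError` unless ``force_ultrametric`` is set,
    in which case every tip is aligned to the deepest root-to-tip path.
    """
    trees = read_trees(source, schema=schema, force_ultrametric=force_ultrametric)
    if not trees:
        raise TreeError("no trees found in input")
    return trees[0]


def read_trees(source: str, schema: str = "newick",
               force_ultrametric: bool = False) -> list[TimeTree]:
    """Read a tree set (one Newick per line, or a NEXUS TREES block)."""
    import os

    if isinstance(source, str) and not source.lstrip().startswith(("(", "#")) \
            and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    tlist = dendropy.TreeList.get(data=text, schema=schema)
    return [_from_dendropy(t, force_ultrametric) for t in tlist]


def tree_from_newick(text: str, force_ultrametric: bool = False) -> TimeTree:
    return read_tree(text, schema="newick", force_ultrametric=force_ultrametric)


def write_tree(tree: TimeTree, path: str | None = None, digits: int = 12) -> str:
    """Serialise to Newick (branch lengths = parent age − own age)."""

    def render(node: Node) -> str:
        if node.is_tip:
            core = node.label
        else:
            core = "(" + ",".join(render(c) for c in node.children) + ")"
        if node.parent is None:
            return core
        return f"{core}:{node.branch_length:.{digits}g}"

    text = render(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Branching profiles / LTT


@dataclass(frozen=True)
class LTTProfile:
    """Ordered branching times and internode intervals of an ultrametric tree.

    ``branching_times`` are node ages b_1 > b_2 > ... > b_{n-1} measured from
    the present (b_1 = crown age).  ``intervals[j]`` is g_{j+2}: the duration
    during which exactly j+2 lineages existed; the last interval g_n ends at
    ``cut_age``.  ``weighted_cumsum[j]`` is T_{j+2} = sum_{k=2}^{j+2} k*g_k,
    so ``total`` T = T_n is the total lineage-time from the crown to the cut
    line.
    """

    branching_times: np.ndarray
    intervals: np.ndarray
    weighted_cumsum: np.ndarray
    cut_age: float = 0.0

    @property
    def n(self) -> int:
        """Number of lineages reaching the cut line."""
        return len(self.branching_times) + 1

    @property
    def total(self) -> float:
        return float(self.weighted_cumsum[-1])

    @property
    def crown_age(self) -> float:
        return float(self.branching_times[0])


def branching_profile(tree: TimeTree, cut_age: float = 0.0) -> LTTProfile:
    """Branching times and internode intervals measured down to ``cut_age``.

    Branching times are ages *relative to the cut line*; internal nodes
    younger than the cut are ignored (lineages are frozen below the line),
    so a profile cut at 1 Ma is identical to the profile of the tree
    truncated at 1 Ma.  A node sitting exactly on the line is kept.
    Simultaneous branching times are ordered by preorder index.
    """
    ages = []
    for idx, node in enumerate(tree.preorder()):
        if node.is_tip:
            continue
        if len(node.children) != 2:
            raise TreeError("branching profile requires a strictly binary tree")
        if node.age < cut_age:
            continue
        ages.append((node.age, idx))
    if len(ages) < 2:
        raise TreeError("need at least 3 lineages at the cut line")
    ages.sort(key=lambda t: (-t[0], t[1]))
    b = np.array([a for a, _ in ages], dtype=float) - cut_age
    n = len(b) + 1
    # g_k for k = 2..n ; g_n ends at the cut line (relative age 0)
    g = np.empty(n - 1)
    g[:-1] = b[:-1] - b[1:]
    g[-1] = b[-1]
    k = np.arange(2, n + 1, dtype=float)
    T = np.cumsum(k * g)
    return LTTProfile(branching_times=b, intervals=g, weighted_cumsum=T,
                      cut_age=cut_age)


def ltt_coordinates(tree: TimeTree) -> np.ndarray:
    """Step-plot coordinates (time before present, lineage count)."""
    prof = branching_profile(tree)
    times = np.concatenate([prof.branching_times, [0.0]])
    counts = np.arange(2, prof.n + 1)
    return np.column_stack([times, np.concatenate([counts, [prof.n]])])


def lineages_at(tree: TimeTree, age: float) -> int:
    """Number of branches crossing the given age line (parent older, self
    at or below the line)."""
    if age >= tree.crown_age:
        return 1
    count = 0
    for node in tree.preorder():
        if node.parent is not None and node.age <= age < node.parent.age:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Truncation / clade extraction / pruning


def truncate_tree(tree: TimeTree, age: float = 1.0) -> TimeTree:
    """Collapse all divergences younger than ``age`` Ma.

    Every branch crossing the age line becomes a tip sitting on the line;
    the line becomes the new present (ages are shifted down by ``age``, i.e.
    terminal branches are shortened by ``age`` Ma).  A node whose age equals
    the cutoff exactly is kept.  New tip labels are the lexicographically
    smallest descendant tip label.
    """
    if age == 0:
        return tree.copy()
    if age < 0:
        raise TreeError("truncation age must be nonnegative")
    if age >= tree.crown_age:
        raise TreeError(
            f"truncation age {age} is not below the crown age {tree.crown_age}"
        )

    def smallest_label(node: Node) -> str:
        if node.is_tip:
            return node.label
        return min(smallest_label(c) for c in node.children)

    def build(node: Node) -> Node:
        kept = [c for c in node.children if c.age >= age]
        crossing = [c for c in node.children if c.age < age]
        new = Node(None, node.age - age)
        for c in kept:
            new.add_child(build(c))
        for c in crossing:
            new.add_child(Node(smallest_label(c), 0.0))
        if not new.children:  # node sits exactly on the line
            new.label = smallest_label(node)
        return new

    out = TimeTree(build(tree.root))
    out.validate()
    return out


def extract_clade(tree: TimeTree, labels) -> TimeTree:
    """Subtree rooted at the MRCA of ``labels``; errors unless monophyletic."""
    labels = set(labels)
    anc = tree.mrca(labels)

    def clone(node: Node) -> Node:
        new = Node(node.label, node.age)
        for c in node.children:
            new.add_child(clone(c))
        return new

    sub = TimeTree(clone(anc))
    got = set(sub.tip_labels())
    if got != labels:
        extra = sorted(got - labels)
        raise TreeError(
            f"tip set is not monophyletic; MRCA also contains {extra[:10]}"
        )
    return sub


def prune_random_tips(tree: TimeTree, k: int, seed: int) -> TimeTree:
    """Remove ``k`` uniformly chosen tips, suppressing unary nodes.

    Deterministic for a given seed.  Requires ``0 <= k <= n - 3`` so that a
    usable (>= 3 tip) tree remains.
    """
    n = tree.n_tips
    if not 0 <= k <= n - 3:
        raise TreeError(f"cannot prune {k} of {n} tips (need 0 <= k <= n-3)")
    if k == 0:
        return tree.copy()
    rng = np.random.default_rng(seed)
    labels = sorted(tree.tip_labels())
    drop = set(rng.choice(labels, size=k, replace=False).tolist())
    return prune_tips(tree, drop)


def prune_tips(tree: TimeTree, drop) -> TimeTree:
    """Remove the named tips, suppressing resulting unary internal nodes."""
    drop = set(drop)
    out = tree.copy()
    for tip in [t for t in out.tips() if t.label in drop]:
        node = tip
        while node.parent is not None:
            parent = node.parent
            parent.children.remove(node)
            if parent.children:
                break
            node = parent
    # suppress unary nodes (ages are primary, so removal preserves timing)
    def suppress(node: Node) -> Node:
        while len(node.children) == 1:
            node = node.children[0]
        node.children = [suppress(c) for c in node.children]
        for c in node.children:
            c.parent = node
        return node

    root = suppress(out.root)
    root.parent = None
    result = TimeTree(root)
    result.validate()
    return result
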