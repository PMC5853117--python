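"""DNA-barcode haplotype-lineage delimitation and species clustering.

Works from a short mtCOI alignment: raw pairwise difference counts,
a neighbor-joining guide tree rooted on an outgroup, delimitation of the
finest monophyletic partition in which every between-lineage pair of
sequences differs by at least ``min_diff`` substitutions (default 3 of
~504 sites, ~0.5%), single-linkage "species" clusters below a proportional
divergence threshold (default 4%), and medoid exemplar selection.

Paraphyly handling: when a central haplotype bridges two or more groups
that are themselves mutually divergent (>= min_diff), it is excluded if it
is rare (<= 3 specimens) — treated as a sampled ancestral haplotype —
otherwise the groups are combined into one monophyletic lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "GuideTree",
    "GNode",
    "LineagePartition",
    "read_fasta",
    "write_fasta",
    "raw_distances",
    "neighbor_joining",
    "delimit_lineages",
    "cluster_species",
    "select_exemplars",
    "assign_species",
]


@dataclass
class Alignment:
    """Aligned DNA sequences: id -> residue string (IUPAC, same length)."""

    ids: list
    seqs: dict

    def __post_init__(self):
        if not self.seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences differ in length: {sorted(lengths)}")
        (self.length,) = lengths
        if self.length == 0:
            raise ValueError("zero-length alignment")

    @classmethod
    def from_pairs(cls, pairs) -> "Alignment":
        ids = [i for i, _ in pairs]
        return cls(ids=ids, seqs={i: s.upper() for i, s in pairs})

    def __len__(self) -> int:
        return len(self.ids)


def read_fasta(path: str) -> Alignment:
    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    return Alignment.from_pairs(pairs)


def write_fasta(aln: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for sid in aln.ids:
            fh.write(f">{sid}\n{aln.seqs[sid]}\n")


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    """Raw pairwise difference counts over pairwise-comparable sites.

    ``n_diff[i, j]`` counts columns where both sequences carry unambiguous,
    non-gap bases (A/C/G/T) that differ; ``comparable[i, j]`` counts columns
    where both are unambiguous non-gap.  ``proportional`` is their ratio.
    """

    ids: list
    n_diff: np.ndarray
    comparable: np.ndarray

    def __post_init__(self):
        self.index = {sid: i for i, sid in enumerate(self.ids)}

    @property
    def proportional(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.n_diff / self.comparable
        return np.nan_to_num(p)

    def diff(self, a: str, b: str) -> int:
        return int(self.n_diff[self.index[a], self.index[b]])

    def prop(self, a: str, b: str) -> float:
        return float(self.proportional[self.index[a], self.index[b]])


def raw_distances(aln: Alignment) -> DistanceMatrix:
    """Simple pairwise distances: count of differing unambiguous sites.

    Gaps and IUPAC ambiguity codes are excluded pairwise from both the
    difference count and the comparable-site count.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.frombuffer(
        "".join(aln.seqs[i] for i in aln.ids).encode(), dtype=np.uint8
    ).reshape(len(aln), aln.length)
    ok = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    if not ok.any(axis=1).all():
        bad = [aln.ids[i] for i in np.where(~ok.any(axis=1))[0]]
        raise ValueError(f"sequences with no unambiguous sites: {bad}")
    n = len(aln)
    nd = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        comp[i, i + 1:] = comp[i + 1:, i] = both.sum(axis=1)
        nd[i, i + 1:] = nd[i + 1:, i] = ((arr[i] != arr[i + 1:]) & both).sum(axis=1)
        comp[i, i] = ok[i].sum()
    return DistanceMatrix(ids=list(aln.ids), n_diff=nd, comparable=comp)


# ---------------------------------------------------------------------------
# Neighbor joining


class GNode:
    """Guide-tree node (branch lengths, not ages — NJ trees are additive,
    not ultrametric)."""

    __slots__ = ("parent", "children", "label", "length")

    def __init__(self, label=None, length=0.0):
        self.parent = None
        self.children = []
        self.label = label
        self.length = length

    def add_child(self, child):
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self):
        return not self.children


class GuideTree:
    """Rooted guide tree used for monophyly assessment."""

    def __init__(self, root: GNode, outgroup: str | None = None):
        self.root = root
        self.outgroup = outgroup

    def preorder(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def tips(self):
        return [n for n in self.preorder() if n.is_tip]

    def tip_labels(self):
        return [t.label for t in self.tips()]

    def ingroup_clades(self) -> list[frozenset]:
        """Descendant tip-label sets of every node, outgroup excluded."""
        out = []

        def walk(node) -> frozenset:
            if node.is_tip:
                s = (frozenset() if node.label == self.outgroup
                     else frozenset([node.label]))
            else:
                s = frozenset().union(*(walk(c) for c in node.children))
            if s:
                out.append(s)
            return s

        walk(self.root)
        return out

    def newick(self) -> str:
        def render(n):
            core = (n.label if n.is_tip
                    else "(" + ",".join(render(c) for c in n.children) + ")")
            return core if n.parent is None else f"{core}:{n.length:.10g}"

        return render(self.root) + ";"


def neighbor_joining(d: DistanceMatrix, outgroup: str,
                     use: str = "proportional") -> GuideTree:
    """Saitou–Nei neighbor joining, rooted on the designated outgroup.

    Ties in the Q matrix are broken by the smallest (input-order) index
    pair.  Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling branch.  The unrooted NJ tree is rooted by
    splitting the outgroup's subtending edge at its midpoint.
    """
    if outgroup is None or outgroup not in d.index:
        raise ValueError("an outgroup sequence present in the matrix is required")
    ids = list(d.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 sequences")
    base = d.proportional if use == "proportional" else d.n_diff.astype(float)

    nodes: list[GNode] = [GNode(label=sid) for sid in ids]
    dist: dict[tuple[int, int], float] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[(i, j)] = float(base[i, j])

    def D(i, j):
        return dist[(i, j)] if i < j else dist[(j, i)]

    active = list(range(len(ids)))
    next_id = len(ids)
    while len(active) > 2:
        m = len(active)
        R = {i: sum(D(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                key = ((m - 2) * D(i, j) - R[i] - R[j], i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = D(i, j)
        vi = 0.5 * dij + (R[i] - R[j]) / (2 * (m - 2))
        vj = dij - vi
        if vi < 0:
            vj, vi = vj - vi, 0.0
        if vj < 0:
            vi, vj = vi - vj, 0.0
        parent = GNode()
        nodes[i].length, nodes[j].length = vi, vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes.append(parent)
        u = next_id
        next_id += 1
        for k in active:
            if k not in (i, j):
                key = (min(u, k), max(u, k))
                dist[key] = 0.5 * (D(i, k) + D(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    root = GNode()
    nodes[i].length = nodes[j].length = 0.5 * D(i, j)
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    return _reroot_on_outgroup(GuideTree(root), outgroup)


def _reroot_on_outgroup(tree: GuideTree, outgroup: str) -> GuideTree:
    """Reroot an (arbitrarily rooted) guide tree on the outgroup's edge."""
    adj: dict[int, list] = {}
    labels: dict[int, str | None] = {}
    index: dict[int, int] = {}
    counter = [0]

    def nid(node):
        key = id(node)
        if key not in index:
            index[key] = counter[0]
            counter[0] += 1
        return index[key]

    for node in tree.preorder():
        i = nid(node)
        labels.setdefault(i, node.label)
        for c in node.children:
            j = nid(c)
            adj.setdefault(i, []).append([j, c.length])
            adj.setdefault(j, []).append([i, c.length])
    # fuse the old degree-2 root out of the unrooted graph
    old_root = nid(tree.root)
    if len(adj.get(old_root, [])) == 2:
        (a, la), (b, lb) = adj[old_root]
        adj[a] = [e for e in adj[a] if e[0] != old_root] + [[b, la + lb]]
        adj[b] = [e for e in adj[b] if e[0] != old_root] + [[a, la + lb]]
        del adj[old_root]
    try:
        og_id = next(i for i, lab in labels.items()
                     if lab == outgroup and len(adj.get(i, [])) == 1)
    except StopIteration:
        raise ValueError(f"outgroup {outgroup!r} not found as a tip")
    (nbr, elen), = adj[og_id]

    def build(i, parent_i, length) -> GNode:
        node = GNode(label=labels.get(i), length=length)
        for j, l in adj[i]:
            if j != parent_i:
                node.add_child(build(j, i, l))
        return node

    root = GNode()
    root.add_child(build(og_id, nbr, elen / 2.0))
    root.add_child(build(nbr, og_id, elen / 2.0))
    return GuideTree(root, outgroup=outgroup)


# ---------------------------------------------------------------------------
# Lineage delimitation


@dataclass
class LineagePartition:
    """Exhaustive, disjoint assignment of sequences to monophyletic lineages."""

    assignments: dict                 # sequence id -> lineage id
    lineages: dict                    # lineage id -> ordered member ids
    excluded: list = field(default_factory=list)   # dropped ancestral haplotypes
    exemplars: dict = field(default_factory=dict)  # lineage id -> member id
    species: dict = field(default_factory=dict)    # lineage id -> species id

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)


def _components(items, linked) -> list[list]:
    """Connected components under a pairwise predicate, preserving order."""
    items = list(items)
    pos = {x: i for i, x in enumerate(items)}
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(items):
        for b in items[i + 1:]:
            if linked(a, b):
                parent[find(pos[b])] = find(pos[a])
    comps: dict = {}
    for i, x in enumerate(items):
        comps.setdefault(find(i), []).append(x)
    return list(comps.values())


def delimit_lineages(guide: GuideTree, d: DistanceMatrix,
                     specimen_counts: dict | None = None,
                     min_diff: int = 3) -> LineagePartition:
    """Finest monophyletic partition in which all between-lineage sequence
    pairs differ by >= ``min_diff`` substitutions.

    Sequences closer than the threshold must share a lineage (transitive
    closure); groups are then enlarged to the smallest containing clade of
    the guide tree until each is monophyletic.  A rare "ancestral"
    haplotype — <= 3 specimens, lying within the threshold of two or more
    groups that are themselves mutually divergent — is excluded before
    grouping; a common one (> 3 specimens) chains its neighbors into one
    combined lineage via the closure.
    """
    if min_diff < 1:
        raise ValueError("min_diff must be >= 1")
    if guide.outgroup is None:
        raise ValueError("guide tree must be rooted on an outgroup")
    counts = specimen_counts or {}
    seqs = [s for s in d.ids if s != guide.outgroup]
    nd = d.n_diff

    def close(a, b):
        return nd[d.index[a], d.index[b]] < min_diff

    # exclude rare bridging (ancestral) haplotypes, to a fixpoint
    excluded: set = set()
    changed = True
    while changed:
        changed = False
        pool = [s for s in seqs if s not in excluded]
        for h in pool:
            if counts.get(h, 1) > 3:
                continue
            nbrs = [x for x in pool if x != h and close(h, x)]
            bridges = any(not close(a, b)
                          for i, a in enumerate(nbrs) for b in nbrs[i + 1:])
            if bridges:
                excluded.add(h)
                changed = True
                break

    kept = [s for s in seqs if s not in excluded]
    groups = _components(kept, close)

    # enforce monophyly on the guide tree (excluded tips ignored)
    universe = frozenset(kept)
    clades = [c & universe for c in guide.ingroup_clades()]
    clades = [c for c in clades if c]

    def smallest_clade(members: frozenset) -> frozenset:
        best = universe
        for c in clades:
            if members <= c and len(c) < len(best):
                best = c
        return best

    merged = True
    while merged:
        merged = False
        for g in groups:
            clade = smallest_clade(frozenset(g))
            if clade != frozenset(g):
                absorbed = [h for h in groups if frozenset(h) & clade]
                combined = sorted({x for h in absorbed for x in h},
                                  key=lambda s: d.index[s])
                groups = [h for h in groups if h not in absorbed] + [combined]
                merged = True
                break

    groups.sort(key=lambda g: min(d.index[s] for s in g))
    width = max(3, len(str(len(groups))))
    assignments, lineages = {}, {}
    for i, g in enumerate(groups, start=1):
        lid = f"L{i:0{width}d}"
        lineages[lid] = sorted(g, key=lambda s: d.index[s])
        for s in lineages[lid]:
            assignments[s] = lid
    part = LineagePartition(assignments=assignments, lineages=lineages,
                            excluded=sorted(excluded, key=lambda s: d.index[s]))
    part.exemplars = select_exemplars(part, d)
    return part


def cluster_species(d: DistanceMatrix, threshold: float = 0.04,
                    ids=None) -> dict:
    """Single-linkage clusters at proportional distance < ``threshold``.

    Returns id -> species id ("S01", ...); species are numbered in order of
    first member appearance in the matrix.
    """
    ids = list(ids) if ids is not None else list(d.ids)
    p = d.proportional

    def close(a, b):
        return p[d.index[a], d.index[b]] < threshold

    comps = _components(ids, close)
    comps.sort(key=lambda g: min(d.index[s] for s in g))
    width = max(2, len(str(len(comps))))
    out = {}
    for i, g in enumerate(comps, start=1):
        for s in g:
            out[s] = f"S{i:0{width}d}"
    return out


def select_exemplars(p: LineagePartition, d: DistanceMatrix) -> dict:
    """Medoid exemplar per lineage: the member minimizing mean
    within-lineage proportional distance; ties broken lexicographically."""
    out = {}
    for lid, members in p.lineages.items():
        idx = [d.index[m] for m in members]
        sub = d.proportional[np.ix_(idx, idx)]
        means = sub.mean(axis=1)
        order = sorted(range(len(members)), key=lambda i: (means[i], members[i]))
        out[lid] = members[order[0]]
    return out


def assign_species(p: LineagePartition, d: DistanceMatrix,
                   threshold: float = 0.04) -> dict:
    """Cluster lineage exemplars into species and label each lineage."""
    if not p.exemplars:
        p.exemplars = select_exemplars(p, d)
    ex_ids = [p.exemplars[lid] for lid in p.lineages]
    sp = cluster_species(d, threshold=threshold, ids=ex_ids)
    p.species = {lid: sp[p.exemplars[lid]] for lid in p.lineages}
    return p.species
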