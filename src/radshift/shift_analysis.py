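"""Split-shift tallies and the permutation test.

Cross-classifies lineage-splitting events (internal nodes of the time
tree) by age — older or younger than a breakpoint, default 3 Ma — and by
whether the split is accompanied by a character shift: the two immediate
descendants carry different states (or non-overlapping state sets, for
polymorphic tips).  A shift in either host species or host tissue counts
as a composite "host shift".  Tallies are computed from parsimony
reconstructions (ACCTRAN or DELTRAN resolutions), from stochastic-map
histories (one tally per sampled history, giving a distribution), and the
old-vs-young difference in shift proportions is tested against a null in
which the rows of a simplified (single-state) character matrix are
randomly reshuffled across lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ancestral_states import CodedMatrix, ParsimonyReconstruction, SimmapHistory
from .tree_core import TimeTree, TreeError

__all__ = [
    "TallyConfig",
    "SplitTally",
    "PermutationResult",
    "classify_splits",
    "tally_simmap",
    "permutation_test",
    "COMPOSITE",
]

#: name of the composite host-species-OR-host-tissue shift column
COMPOSITE = "host_or_tissue"

#: character pair that rolls up into the composite host shift
_HOST_CHARS = ("host_species", "host_tissue")


@dataclass(frozen=True)
class TallyConfig:
    """Breakpoint and exclusion settings for split tallies.

    ``breakpoint``: splits at age >= breakpoint are "old" (the boundary
    counts as old).  ``exclusion_age``: splits younger than this are left
    out entirely (1.0 reproduces the "only splits older than 1 Ma"
    variant).  ``variant`` names the reconstruction whose states feed the
    shift rule.
    """

    breakpoint: float = 3.0
    exclusion_age: float = 0.0
    variant: str = "parsimony_deltran"   # parsimony_acctran | parsimony_deltran
    #                                    # | parsimony_mpr | simmap_endpoint

    def __post_init__(self):
        if not self.breakpoint > self.exclusion_age >= 0:
            raise ValueError("need breakpoint > exclusion_age >= 0")


@dataclass
class SplitTally:
    """Counts of splits cross-classified age-bin x shift, per character.

    ``counts[char]`` holds old_shift / old_total / young_shift /
    young_total; the composite host-or-tissue column is present when both
    host characters were tallied.  ``annotations`` records, per counted
    node, (preorder index, age, is_old, {char: is_shift}).
    """

    config: TallyConfig
    counts: dict
    annotations: list = field(default_factory=list)

    def proportion(self, char: str, bin_: str) -> float:
        c = self.counts[char]
        total = c[f"{bin_}_total"]
        return c[f"{bin_}_shift"] / total if total else math.nan

    def difference(self, char: str) -> float:
        """D = P(shift | old) - P(shift | young); NaN if a bin is empty."""
        return self.proportion(char, "old") - self.proportion(char, "young")


def _iter_counted_nodes(tree: TimeTree, cfg: TallyConfig):
    """(preorder index, node, is_old) for every tallied internal node."""
    for idx, node in enumerate(tree.preorder()):
        if node.is_tip:
            continue
        if len(node.children) != 2:
            raise TreeError("split tallies require a binary tree")
        if node.age < cfg.exclusion_age:
            continue
        yield idx, node, node.age >= cfg.breakpoint


def _child_state_set(rec: ParsimonyReconstruction, child_idx: int,
                     is_tip: bool, resolution: str) -> frozenset:
    if is_tip:
        return rec.tip_states[child_idx]
    if resolution == "acctran":
        return frozenset([rec.acctran[child_idx]])
    if resolution == "deltran":
        return frozenset([rec.deltran[child_idx]])
    if resolution == "mpr":
        return rec.mpr[child_idx]
    raise ValueError(f"unknown resolution {resolution!r}")


def _tally_from_flags(tree, cfg, shift_flags: dict) -> SplitTally:
    """Assemble a SplitTally from per-node per-character shift booleans."""
    chars = list(shift_flags)
    if all(c in chars for c in _HOST_CHARS):
        chars.append(COMPOSITE)
    counts = {c: {"old_shift": 0, "old_total": 0,
                  "young_shift": 0, "young_total": 0} for c in chars}
    annotations = []
    index_nodes = list(_iter_counted_nodes(tree, cfg))
    for idx, node, is_old in index_nodes:
        flags = {c: shift_flags[c][idx] for c in shift_flags}
        if COMPOSITE in chars:
            flags[COMPOSITE] = (flags["host_species"] or flags["host_tissue"])
        bin_ = "old" if is_old else "young"
        for c in chars:
            counts[c][f"{bin_}_total"] += 1
            if flags[c]:
                counts[c][f"{bin_}_shift"] += 1
        annotations.append((idx, node.age, is_old, flags))
    return SplitTally(config=cfg, counts=counts, annotations=annotations)


def classify_splits(tree: TimeTree, recs: dict, cfg: TallyConfig) -> SplitTally:
    """Tally splits as shift/no-shift from parsimony reconstructions.

    ``recs`` maps character name -> :class:`ParsimonyReconstruction` made
    on this same tree.  A shift is counted when the two immediate
    descendants' state sets are disjoint: resolved single states for
    internal descendants (per ``cfg.variant``), coded state sets for tips.
    """
    resolution = cfg.variant.replace("parsimony_", "")
    pre = list(tree.preorder())
    node_index = {id(n): i for i, n in enumerate(pre)}
    tip_idx = {i for i, n in enumerate(pre) if n.is_tip}
    shift_flags: dict = {}
    for char, rec in recs.items():
        flags = {}
        for idx, node, _ in _iter_counted_nodes(tree, cfg):
            sets = []
            for c in node.children:
                ci = node_index[id(c)]
                if rec.mpr.get(ci) is None and ci not in rec.tip_states:
                    raise TreeError(f"node {ci} lacks a reconstructed state")
                sets.append(_child_state_set(rec, ci, ci in tip_idx, resolution))
            flags[idx] = bool(sets[0].isdisjoint(sets[1]))
        shift_flags[char] = flags
    return _tally_from_flags(tree, cfg, shift_flags)


def tally_simmap(histories_by_char: dict, trees, cfg: TallyConfig) -> list[SplitTally]:
    """One tally per sampled stochastic-map history.

    A shift is counted at a split when the two descendant branches end in
    different states immediately prior to their own terminal events — the
    sampled state at each descendant node (or tip) — regardless of how
    many transitions occurred along the branches.  Histories of different
    characters are paired by (tree index, simulation index) so the
    composite host-or-tissue column can be formed.
    """
    if isinstance(trees, TimeTree):
        trees = [trees]
    histories_by_char = {
        c: ([h] if isinstance(h, SimmapHistory) else list(h))
        for c, h in histories_by_char.items()
    }
    chars = list(histories_by_char)
    keyed = {
        c: {(h.tree_index, h.sim_index): h for h in histories_by_char[c]}
        for c in chars
    }
    keys = sorted(set.intersection(*(set(k) for k in keyed.values())))
    out = []
    for key in keys:
        tree = trees[key[0]]
        pre = list(tree.preorder())
        node_index = {id(n): i for i, n in enumerate(pre)}
        shift_flags: dict = {}
        for c in chars:
            h: SimmapHistory = keyed[c][key]
            _check_segments(h, tree, node_index)
            flags = {}
            for idx, node, _ in _iter_counted_nodes(tree, cfg):
                s1, s2 = (h.node_states[node_index[id(ch)]]
                          for ch in node.children)
                flags[idx] = s1 != s2
            shift_flags[c] = flags
        out.append(_tally_from_flags(tree, cfg, shift_flags))
    return out


def _check_segments(h: SimmapHistory, tree: TimeTree, node_index) -> None:
    """Segments must tile each non-root branch exactly."""
    for n in tree.preorder():
        for c in n.children:
            j = node_index[id(c)]
            segs = h.segments.get(j)
            if not segs:
                raise TreeError(f"history missing segments for node {j}")
            if abs(segs[0][0] - n.age) > 1e-6 or abs(segs[-1][1] - c.age) > 1e-6:
                raise TreeError(f"segment gap on branch to node {j}")


# ---------------------------------------------------------------------------
# Permutation test (vectorized MPR parsimony over permuted matrices)


@dataclass
class PermutationResult:
    """Observed old-minus-young shift-proportion difference and its
    row-shuffle permutation null."""

    observed: float
    m: int
    null_sample: np.ndarray
    p_raw: float                     # b/m, matching a reported "p = 0"
    p_corrected: float               # (b+1)/(m+1)
    seed: int
    characters: tuple


def _tree_arrays(tree: TimeTree, cfg: TallyConfig):
    """Static structure arrays for the vectorized Sankoff passes."""
    pre = list(tree.preorder())
    node_index = {id(n): i for i, n in enumerate(pre)}
    children = [[node_index[id(c)] for c in n.children] for n in pre]
    tip_pos = {}                     # preorder index -> tip rank
    labels = []
    for n in pre:
        if n.is_tip:
            tip_pos[node_index[id(n)]] = len(labels)
            labels.append(n.label)
    counted = [(i, pre[i].age >= cfg.breakpoint, children[i])
               for i, n in enumerate(pre)
               if not n.is_tip and n.age >= cfg.exclusion_age]
    for i, n in enumerate(pre):
        if not n.is_tip and len(n.children) != 2:
            raise TreeError("permutation test requires a binary tree")
    return pre, children, tip_pos, labels, counted


def _mpr_masks_vectorized(children, tip_pos, tip_states, k):
    """MPR membership masks for every node, vectorized over permutations.

    ``tip_states``: (n_perm, n_tips) integer state indices.  Returns a list
    of boolean arrays (n_perm, k), preorder-indexed, where entry [p, s] is
    True iff state s occurs at that node in some minimum-length
    reconstruction of permutation p, plus the (n_perm,) vector of tree
    lengths.
    """
    n_perm = tip_states.shape[0]
    n_nodes = len(children)
    S = [None] * n_nodes
    eye = np.eye(k, dtype=bool)
    for i in range(n_nodes - 1, -1, -1):
        if not children[i]:
            onehot = eye[tip_states[:, tip_pos[i]]]
            S[i] = np.where(onehot, 0.0, np.inf)
        else:
            total = np.zeros((n_perm, k))
            for c in children[i]:
                Sc = S[c]
                total += np.minimum(Sc, Sc.min(axis=1, keepdims=True) + 1.0)
            S[i] = total
    length = S[0].min(axis=1)
    A = [None] * n_nodes
    A[0] = np.zeros((n_perm, k))
    for i in range(n_nodes):
        if not children[i]:
            continue
        M = {c: np.minimum(S[c], S[c].min(axis=1, keepdims=True) + 1.0)
             for c in children[i]}
        for c in children[i]:
            B = A[i].copy()
            for c2 in children[i]:
                if c2 != c:
                    B += M[c2]
            A[c] = np.minimum(B, B.min(axis=1, keepdims=True) + 1.0)
    masks = [(S[i] + A[i]) <= (length[:, None] + 1e-9) for i in range(n_nodes)]
    return masks, length


def _shift_difference_vectorized(tree: TimeTree, matrices: dict,
                                 cfg: TallyConfig,
                                 perms: np.ndarray) -> np.ndarray:
    """D = P_old - P_young for each row-permutation of the matrices.

    ``perms``: (n_perm, n_tips) index arrays permuting the tip->state rows
    (the same permutation is applied to every character, preserving
    cross-character correlation under the null).  Shifts use MPR sets:
    a split counts as a shift only when the descendant MPR sets (tip
    states for tips) are disjoint.
    """
    pre, children, tip_pos, labels, counted = _tree_arrays(tree, cfg)
    if not counted:
        raise TreeError("no splits to tally")
    n_perm = perms.shape[0]
    shift_any = None
    for matrix in matrices.values():
        alphabet = matrix.alphabet
        k = len(alphabet)
        pos = {s: i for i, s in enumerate(alphabet)}
        base = np.array([pos[next(iter(matrix.states[lab]))] for lab in labels])
        tip_states = base[perms]
        masks, _ = _mpr_masks_vectorized(children, tip_pos, tip_states, k)
        char_shift = []
        for i, is_old, (c1, c2) in counted:
            disjoint = ~np.any(masks[c1] & masks[c2], axis=1)
            char_shift.append(disjoint)
        char_shift = np.stack(char_shift, axis=0)   # (n_nodes_counted, n_perm)
        shift_any = char_shift if shift_any is None else (shift_any | char_shift)
    old_mask = np.array([is_old for _, is_old, _ in counted])
    n_old = int(old_mask.sum())
    n_young = int((~old_mask).sum())
    if n_old == 0 or n_young == 0:
        return np.full(n_perm, np.nan)
    p_old = shift_any[old_mask].sum(axis=0) / n_old
    p_young = shift_any[~old_mask].sum(axis=0) / n_young
    return p_old - p_young


def permutation_test(tree: TimeTree, matrices, cfg: TallyConfig | None = None,
                     m: int = 1000, seed: int = 0) -> PermutationResult:
    """Row-shuffle permutation test of the old-vs-young shift contrast.

    ``matrices`` is a single simplified :class:`CodedMatrix` or a dict of
    them; with both host characters supplied the statistic uses the
    composite host-or-tissue shift.  The observed statistic
    D = P(shift | old) - P(shift | young) comes from an MPR parsimony
    reconstruction (a shift only when descendant MPR sets are disjoint);
    each of the ``m`` permutations shuffles the tip-to-row assignment
    uniformly (one shuffle applied to all characters) and recomputes D.
    One-tailed upper p-values: raw b/m and corrected (b+1)/(m+1).
    """
    if cfg is None:
        cfg = TallyConfig(variant="parsimony_mpr")
    if isinstance(matrices, CodedMatrix):
        matrices = {matrices.character: matrices}
    for mx in matrices.values():
        if not mx.is_singleton():
            raise ValueError("permutation test requires simplified matrices")
    if m < 1:
        raise ValueError("need at least one permutation")
    n_tips = tree.n_tips
    rng = np.random.default_rng(seed)
    identity = np.arange(n_tips)[None, :]
    observed = float(_shift_difference_vectorized(tree, matrices, cfg, identity)[0])
    perms = np.stack([rng.permutation(n_tips) for _ in range(m)])
    null = _shift_difference_vectorized(tree, matrices, cfg, perms)
    if math.isnan(observed):
        p_raw = p_corr = math.nan
    else:
        b = int(np.sum(null >= observed - 1e-12))
        p_raw = b / m
        p_corr = (b + 1) / (m + 1)
    return PermutationResult(
        observed=observed, m=m, null_sample=null, p_raw=p_raw,
        p_corrected=p_corr, seed=seed, characters=tuple(matrices),
    )
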