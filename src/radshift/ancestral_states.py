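"""Character coding and ancestral-state reconstruction.

Turns per-specimen records (host species, host tissue, biogeographic
region) into per-lineage state frequencies and coded character matrices,
then reconstructs ancestral states two ways:

* unordered (Fitch) parsimony via exact unit-cost Sankoff dynamic
  programming, with most-parsimonious-reconstruction (MPR) state sets and
  ACCTRAN/DELTRAN resolutions of ambiguity;
* Mk-model stochastic character mapping: a continuous-time Markov chain
  rate matrix is fitted per tree by maximum likelihood (pruning algorithm,
  tip partial likelihoods initialized to the observed state-frequency
  priors), then complete character histories are sampled conditional on
  the data (backward filtering, forward sampling; branch paths by
  endpoint-conditioned rejection sampling with a uniformization fallback).

Also fits equal-rates / early-burst / delta trait models by transforming
branch lengths and compares them by AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import expm

from .tree_core import Node, TimeTree, TreeError

__all__ = [
    "SpecimenTable",
    "StateFrequencies",
    "CodedMatrix",
    "ParsimonyReconstruction",
    "MkFit",
    "SimmapHistory",
    "TraitModelFit",
    "read_specimen_table",
    "summarize_frequencies",
    "code_matrix",
    "parsimony_reconstruct",
    "mk_fit",
    "mk_loglik",
    "stochastic_map",
    "fit_trait_models",
    "CHARACTERS",
]

#: default character columns of a specimen table
CHARACTERS = ("host_species", "host_tissue", "region")

_MISSING = "unknown"


# ---------------------------------------------------------------------------
# Specimen records -> state frequencies -> coded matrices


@dataclass
class SpecimenTable:
    """Per-specimen records; thin wrapper over a pandas DataFrame with
    columns specimen_id, lineage_id and the character columns."""

    data: pd.DataFrame
    characters: tuple = CHARACTERS

    def __post_init__(self):
        required = {"specimen_id", "lineage_id", *self.characters}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"specimen table missing columns: {sorted(missing)}")
        for ch in self.characters:
            if (self.data[ch].astype(str).str.len() == 0).any():
                raise ValueError(
                    f"empty strings in column {ch!r}; code missing data as "
                    f"{_MISSING!r}"
                )

    @property
    def lineages(self) -> list:
        return sorted(self.data["lineage_id"].unique())


def read_specimen_table(path: str, characters: tuple = CHARACTERS) -> SpecimenTable:
    return SpecimenTable(pd.read_csv(path, sep="\t", dtype=str), characters)


@dataclass
class StateFrequencies:
    """Relative state frequencies per lineage and character.

    ``freqs[char][lineage]`` maps state -> frequency (sums to 1 over the
    states observed for that lineage, missing records dropped);
    ``counts[char][lineage]`` is the number of usable specimens.
    """

    characters: tuple
    freqs: dict
    counts: dict

    def alphabet(self, character: str) -> tuple:
        states = set()
        for d in self.freqs[character].values():
            states.update(d)
        return tuple(sorted(states))

    def vector(self, character: str, lineage: str, alphabet=None) -> np.ndarray:
        alphabet = alphabet or self.alphabet(character)
        d = self.freqs[character][lineage]
        return np.array([d.get(s, 0.0) for s in alphabet])

    def lineages(self, character: str) -> list:
        return sorted(self.freqs[character])


def summarize_frequencies(table: SpecimenTable) -> StateFrequencies:
    """Per-lineage relative frequencies of each character's states."""
    freqs: dict = {}
    counts: dict = {}
    for ch in table.characters:
        freqs[ch] = {}
        counts[ch] = {}
        sub = table.data[table.data[ch] != _MISSING]
        grouped = sub.groupby("lineage_id")[ch].value_counts()
        for lineage in table.lineages:
            if lineage not in grouped.index.get_level_values(0):
                raise ValueError(
                    f"lineage {lineage!r} has no usable records for {ch!r}"
                )
            vc = grouped[lineage]
            total = int(vc.sum())
            freqs[ch][lineage] = {s: c / total for s, c in vc.items()}
            counts[ch][lineage] = total
    return StateFrequencies(characters=table.characters, freqs=freqs,
                            counts=counts)


@dataclass
class CodedMatrix:
    """Per-lineage state sets for one character under one coding scheme."""

    character: str
    scheme: str                       # polymorphic | predominant | simplified
    states: dict                      # lineage -> frozenset of states

    def __post_init__(self):
        if any(not s for s in self.states.values()):
            raise ValueError("empty state set in coded matrix")
        self.alphabet = tuple(sorted({x for s in self.states.values() for x in s}))

    def is_singleton(self) -> bool:
        return all(len(s) == 1 for s in self.states.values())

    def single_states(self) -> dict:
        if not self.is_singleton():
            raise ValueError("matrix has polymorphic entries")
        return {l: next(iter(s)) for l, s in self.states.items()}


def code_matrix(f: StateFrequencies, character: str, scheme: str,
                min_freq: float = 0.05, window: float = 0.2) -> CodedMatrix:
    """Collapse within-lineage variation into a state set per lineage.

    polymorphic: all states at frequency >= ``min_freq``;
    predominant: the most frequent state plus any within ``window`` of it;
    simplified: the single most frequent state (ties lexicographic).
    """
    if scheme not in ("polymorphic", "predominant", "simplified"):
        raise ValueError(f"unknown coding scheme {scheme!r}")
    out = {}
    for lineage, d in f.freqs[character].items():
        # lexicographic tie-break: sort by (-freq, state)
        ranked = sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))
        top_state, top_freq = ranked[0]
        if scheme == "polymorphic":
            chosen = {s for s, fr in d.items() if fr >= min_freq}
            if not chosen:           # nothing reaches the floor: keep the mode
                chosen = {top_state}
        elif scheme == "predominant":
            chosen = {top_state} | {s for s, fr in d.items()
                                    if fr >= top_freq - window}
        else:
            chosen = {top_state}
        out[lineage] = frozenset(chosen)
    return CodedMatrix(character=character, scheme=scheme, states=out)


# ---------------------------------------------------------------------------
# Parsimony (exact unit-cost Sankoff)

_INF = np.inf


@dataclass
class ParsimonyReconstruction:
    """MPR state sets and ACCTRAN/DELTRAN resolutions, keyed by the node's
    preorder index in the tree that produced them (tips included)."""

    character: str
    alphabet: tuple
    length: int                      # total steps
    mpr: dict                        # preorder index -> frozenset of states
    acctran: dict                    # preorder index -> single state
    deltran: dict
    tip_states: dict                 # preorder index -> frozenset (as coded)


def _tip_costs(node: Node, matrix: CodedMatrix, alphabet: tuple) -> np.ndarray:
    if node.label not in matrix.states:
        raise TreeError(f"tip {node.label!r} missing from coded matrix")
    allowed = matrix.states[node.label]
    return np.array([0.0 if s in allowed else _INF for s in alphabet])


def parsimony_reconstruct(tree: TimeTree, matrix: CodedMatrix) -> ParsimonyReconstruction:
    """Fitch-style unordered parsimony with polymorphic tips.

    A polymorphic tip satisfies any member of its state set at no cost.
    MPR sets are exact: a state is included iff some minimum-length
    assignment places it at that node (computed from up- and down-pass
    Sankoff cost vectors, unit change cost).  ACCTRAN resolves ambiguity
    toward the root (a change on the entering branch whenever the minimum
    allows), DELTRAN away from it (no change whenever the minimum allows);
    both attain exactly the MPR tree length.
    """
    alphabet = matrix.alphabet
    k = len(alphabet)
    nodes = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    S = [None] * len(nodes)          # subtree cost vectors

    for n in reversed(nodes):        # postorder
        i = index[id(n)]
        if n.is_tip:
            S[i] = _tip_costs(n, matrix, alphabet)
        else:
            total = np.zeros(k)
            for c in n.children:
                Sc = S[index[id(c)]]
                total += np.minimum(Sc, Sc.min() + 1.0)
            S[i] = total
    length = int(round(S[0].min()))

    # down-pass: A[v][s] = optimal cost of everything outside v's subtree
    # when v is assigned s (including the change cost on v's stem branch)
    A = [None] * len(nodes)
    A[0] = np.zeros(k)
    for n in nodes:
        i = index[id(n)]
        if n.is_tip:
            continue
        child_M = {}
        for c in n.children:
            Sc = S[index[id(c)]]
            child_M[id(c)] = np.minimum(Sc, Sc.min() + 1.0)
        for c in n.children:
            B = A[i].copy()
            for c2 in n.children:
                if c2 is not c:
                    B = B + child_M[id(c2)]
            A[index[id(c)]] = np.minimum(B, B.min() + 1.0)

    mpr = {}
    for i, n in enumerate(nodes):
        total = S[i] + A[i]
        mpr[i] = frozenset(alphabet[s] for s in range(k)
                           if total[s] <= length + 1e-9)

    state_pos = {s: p for p, s in enumerate(alphabet)}

    def resolve(prefer_change: bool) -> dict:
        out = {}
        root_set = sorted(mpr[0])
        out[0] = root_set[0]
        for n in nodes:
            i = index[id(n)]
            for c in n.children:
                j = index[id(c)]
                Sc = S[j]
                sp = state_pos[out[i]]
                cond = Sc + 1.0
                cond[sp] = Sc[sp]
                m = cond.min()
                allowed = [alphabet[s] for s in range(k) if cond[s] <= m + 1e-9]
                parent_state = out[i]
                if prefer_change:
                    changed = [s for s in allowed if s != parent_state]
                    out[j] = sorted(changed)[0] if changed else parent_state
                else:
                    out[j] = parent_state if parent_state in allowed \
                        else sorted(allowed)[0]
        return out

    acctran = resolve(prefer_change=True)
    deltran = resolve(prefer_change=False)
    tip_states = {index[id(n)]: matrix.states[n.label]
                  for n in nodes if n.is_tip}
    return ParsimonyReconstruction(
        character=matrix.character, alphabet=alphabet, length=length,
        mpr=mpr, acctran=acctran, deltran=deltran, tip_states=tip_states,
    )


# ---------------------------------------------------------------------------
# Mk model likelihood and fitting


@dataclass
class MkFit:
    """Fitted Mk model: generator matrix Q (rows sum to zero), structure,
    maximized log-likelihood."""

    alphabet: tuple
    structure: str                   # ER | SYM | ARD
    rates: np.ndarray                # free rate parameters
    Q: np.ndarray
    lnL: float
    converged: bool = True

    @property
    def n_params(self) -> int:
        return len(self.rates)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.lnL


def _build_Q(alphabet: tuple, structure: str, rates: np.ndarray) -> np.ndarray:
    k = len(alphabet)
    Q = np.zeros((k, k))
    if structure == "ER":
        Q[:] = rates[0]
    elif structure == "SYM":
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                Q[i, j] = Q[j, i] = rates[idx]
                idx += 1
    elif structure == "ARD":
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    else:
        raise ValueError(f"unknown structure {structure!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _n_free_rates(k: int, structure: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[structure]


def _transition_fn(alphabet: tuple, structure: str, rates: np.ndarray):
    k = len(alphabet)
    if structure == "ER":
        q = float(rates[0])

        def P(t):
            e = math.exp(-k * q * t)
            return np.full((k, k), (1 - e) / k) + np.eye(k) * e

        return P
    Q = _build_Q(alphabet, structure, rates)
    cache: dict = {}

    def P(t):
        if t not in cache:
            cache[t] = expm(Q * t)
        return cache[t]

    return P


def _tip_vectors(matrix_or_priors, character: str | None, alphabet: tuple) -> dict:
    """label -> partial-likelihood vector at the tip."""
    out = {}
    if isinstance(matrix_or_priors, CodedMatrix):
        for lineage, states in matrix_or_priors.states.items():
            out[lineage] = np.array([1.0 if s in states else 0.0
                                     for s in alphabet])
    else:
        f: StateFrequencies = matrix_or_priors
        for lineage in f.freqs[character]:
            out[lineage] = f.vector(character, lineage, alphabet)
    return out


def mk_loglik(tree: TimeTree, tip_vectors: dict, alphabet: tuple,
              structure: str, rates: np.ndarray,
              branch_lengths: dict | None = None,
              return_partials: bool = False):
    """Pruning-algorithm log-likelihood of an Mk model.

    Tip partials come from ``tip_vectors`` (one-hot for fixed states, the
    observed frequency vector when priors are used).  The root state is
    weighted uniformly over the alphabet.  ``branch_lengths`` optionally
    overrides each node's branch length (keyed by preorder index), which is
    how branch-length transforms (early burst, delta) are applied.
    """
    k = len(alphabet)
    P = _transition_fn(alphabet, structure, rates)
    nodes = list(tree.preorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    partials = [None] * len(nodes)
    log_scale = 0.0
    for n in reversed(nodes):
        i = index[id(n)]
        if n.is_tip:
            if n.label not in tip_vectors:
                raise TreeError(f"tip {n.label!r} missing from data")
            partials[i] = tip_vectors[n.label].astype(float)
        else:
            v = np.ones(k)
            for c in n.children:
                j = index[id(c)]
                t = (branch_lengths[j] if branch_lengths is not None
                     else c.branch_length)
                v = v * (P(t) @ partials[j])
            s = v.sum()
            if s <= 0:
                return (-np.inf, partials) if return_partials else -np.inf
            if s < 1e-280:
                v = v / s
                log_scale += math.log(s)
            partials[i] = v
    pi = np.full(k, 1.0 / k)
    L = float(pi @ partials[0])
    lnL = (math.log(L) + log_scale) if L > 0 else -np.inf
    return (lnL, partials) if return_partials else lnL


def mk_fit(tree: TimeTree, data, character: str | None = None,
           structure: str = "ER",
           branch_lengths: dict | None = None) -> MkFit:
    """Maximum-likelihood Mk rate matrix.

    ``data`` is either a :class:`StateFrequencies` (with ``character``
    naming the column; tip partials = observed frequencies) or a
    :class:`CodedMatrix` (one-hot or polymorphic-uniform tips).
    Equal-rates (ER) has a single free rate found by bounded 1-D search on
    a log scale; SYM/ARD use multi-start L-BFGS-B.
    """
    if isinstance(data, CodedMatrix):
        alphabet = data.alphabet
    else:
        if character is None:
            raise ValueError("character name required with StateFrequencies")
        alphabet = data.alphabet(character)
    k = len(alphabet)
    if k < 2:
        return MkFit(alphabet=alphabet, structure=structure,
                     rates=np.zeros(1), Q=np.zeros((k, k)), lnL=0.0)
    tipv = _tip_vectors(data, character, alphabet)

    nrates = _n_free_rates(k, structure)

    def neg(log_rates):
        rates = np.exp(log_rates)
        return -mk_loglik(tree, tipv, alphabet, structure, rates,
                          branch_lengths=branch_lengths)

    # scale guess: one expected change per total tree length
    total_len = sum(c.branch_length for n in tree.preorder()
                    for c in n.children)
    q0 = max(1.0 / max(total_len, 1e-9), 1e-6)
    if structure == "ER":
        res = optimize.minimize_scalar(
            lambda x: neg(np.array([x])),
            bounds=(math.log(q0) - 14, math.log(q0) + 10), method="bounded",
            options={"xatol": 1e-10},
        )
        rates = np.exp([res.x])
        lnL = -res.fun
        ok = res.success
    else:
        best = None
        for mult in (0.2, 1.0, 5.0):
            x0 = np.full(nrates, math.log(q0 * mult))
            res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                    bounds=[(math.log(q0) - 14,
                                             math.log(q0) + 10)] * nrates)
            if best is None or res.fun < best.fun:
                best = res
        rates = np.exp(best.x)
        lnL = -best.fun
        ok = best.success
    if not ok:
        raise RuntimeError(
            f"Mk optimization failed to converge (structure={structure})"
        )
    return MkFit(alphabet=alphabet, structure=structure, rates=rates,
                 Q=_build_Q(alphabet, structure, rates), lnL=float(lnL),
                 converged=bool(ok))


# ---------------------------------------------------------------------------
# Stochastic character mapping


@dataclass
class SimmapHistory:
    """One sampled character history on one tree.

    ``node_states`` maps preorder index -> state (tips included: the state
    sampled from the tip prior).  ``segments`` maps a non-root node's
    preorder index to the ordered list of (older_age, younger_age, state)
    tiles of its stem branch, from the parent node down to the node.
    """

    tree_index: int
    sim_index: int
    character: str
    node_states: dict
    segments: dict

    @property
    def n_changes(self) -> int:
        return sum(len(segs) - 1 for segs in self.segments.values())


def _sample_path_rejection(rng, Q, a, b, t, cap=10_000):
    """CTMC path from state a to b over duration t by forward simulation,
    rejecting paths that miss the required endpoint."""
    k = Q.shape[0]
    rates = -np.diag(Q)
    for _ in range(cap):
        path = [(0.0, a)]
        s, now = a, 0.0
        while True:
            r = rates[s]
            if r <= 0:
                break
            now += rng.exponential(1.0 / r)
            if now >= t:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            s = int(rng.choice(k, p=probs))
            path.append((now, s))
        if s == b:
            return path
    return None


def _sample_path_uniformization(rng, Q, a, b, t, max_jumps=200):
    """Endpoint-conditioned path via uniformization (exact fallback)."""
    k = Q.shape[0]
    omega = float(np.max(-np.diag(Q)))
    if omega <= 0:
        return [(0.0, a)]
    R = np.eye(k) + Q / omega
    powers = [np.eye(k)]
    for _ in range(max_jumps):
        powers.append(powers[-1] @ R)
    Pab = expm(Q * t)[a, b]
    if Pab <= 0:
        raise RuntimeError("endpoint-conditioned path has zero probability")
    # P(N = m | endpoints) ∝ Poisson(omega t)(m) * [R^m]_ab
    log_pois = -omega * t
    weights = []
    for m in range(max_jumps + 1):
        w = math.exp(log_pois) * powers[m][a, b]
        weights.append(max(w, 0.0))
        log_pois += math.log(omega * t) - math.log(m + 1) if omega * t > 0 else -np.inf
    weights = np.array(weights)
    if weights.sum() <= 0:
        raise RuntimeError("uniformization failed: zero total weight")
    m = int(rng.choice(len(weights), p=weights / weights.sum()))
    times = np.sort(rng.uniform(0.0, t, size=m))
    path = [(0.0, a)]
    s = a
    for i, tau in enumerate(times):
        remaining = m - i - 1
        probs = R[s] * powers[remaining][:, b]
        total = probs.sum()
        if total <= 0:
            raise RuntimeError("uniformization failed mid-path")
        s_new = int(rng.choice(k, p=probs / total))
        if s_new != s:               # drop virtual (self) jumps
            path.append((float(tau), s_new))
            s = s_new
    return path


def stochastic_map(trees, priors: StateFrequencies, character: str,
                   n_sim_per_tree: int = 10, seed: int = 0,
                   structure: str = "ER") -> list[SimmapHistory]:
    """Sample complete character histories over a set of trees.

    For each tree an Mk rate matrix is fitted by ML (tip partials = the
    observed frequency priors), internal-node and tip states are drawn
    from their joint conditional distribution (backward filtering, forward
    sampling), and each branch's path is simulated conditional on its
    endpoint states.  Deterministic for a given seed.
    """
    if isinstance(trees, TimeTree):
        trees = [trees]
    rng = np.random.default_rng(seed)
    histories = []
    for ti, tree in enumerate(trees):
        fit = mk_fit(tree, priors, character=character, structure=structure)
        alphabet = fit.alphabet
        k = len(alphabet)
        Q = fit.Q
        tipv = _tip_vectors(priors, character, alphabet)
        _, partials = mk_loglik(tree, tipv, alphabet, structure, fit.rates,
                                return_partials=True)
        nodes = list(tree.preorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        P = _transition_fn(alphabet, structure, fit.rates)
        for si in range(n_sim_per_tree):
            node_states = {}
            root_w = partials[0] / k
            root_w = root_w / root_w.sum()
            node_states[0] = int(rng.choice(k, p=root_w))
            segments = {}
            for n in nodes:
                i = index[id(n)]
                sp = node_states[i]
                for c in n.children:
                    j = index[id(c)]
                    t = c.branch_length
                    w = P(t)[sp] * partials[j]
                    w = w / w.sum()
                    sc = int(rng.choice(k, p=w))
                    node_states[j] = sc
                    if t <= 0:
                        if sc != sp:
                            raise RuntimeError(
                                "state change on zero-length branch"
                            )
                        segments[j] = [(n.age, c.age, alphabet[sc])]
                        continue
                    path = _sample_path_rejection(rng, Q, sp, sc, t)
                    if path is None:
                        path = _sample_path_uniformization(rng, Q, sp, sc, t)
                    segs = []
                    for pi_, (start, st) in enumerate(path):
                        end = path[pi_ + 1][0] if pi_ + 1 < len(path) else t
                        segs.append((n.age - start, n.age - end, alphabet[st]))
                    segments[j] = segs
            histories.append(SimmapHistory(
                tree_index=ti, sim_index=si, character=character,
                node_states={i: alphabet[s] for i, s in node_states.items()},
                segments=segments,
            ))
    return histories


# ---------------------------------------------------------------------------
# Trait-model comparison (equal rates vs early burst vs delta)


@dataclass
class TraitModelFit:
    model: str                       # equal_rates | early_burst | delta
    params: dict
    lnL: float
    n_params: int

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.lnL


def _depths(tree: TimeTree) -> tuple[list, dict, float]:
    nodes = list(tree.preorder())
    crown = tree.crown_age
    index = {id(n): i for i, n in enumerate(nodes)}
    return nodes, index, crown


def _transformed_lengths(tree: TimeTree, transform, *args) -> dict:
    """Per-node branch lengths after a depth transform d -> f(d)."""
    nodes, index, crown = _depths(tree)
    out = {}
    for n in nodes:
        for c in n.children:
            d1 = crown - n.age       # depth of branch top (from root)
            d2 = crown - c.age
            out[index[id(c)]] = transform(d2, *args) - transform(d1, *args)
    return out


def _eb_depth(d: float, a: float) -> float:
    # integral of the decaying rate e^{a s} from the root to depth d
    if a == 0:
        return d
    return (math.exp(a * d) - 1.0) / a


def _delta_depth(d: float, delta: float, crown: float) -> float:
    # node depths raised to power delta, rescaled to the original height
    if crown <= 0:
        return d
    return crown * (d / crown) ** delta


def fit_trait_models(tree: TimeTree, matrix: CodedMatrix) -> dict:
    """Equal-rates Mk vs early-burst vs delta branch-length transforms.

    early burst: the evolutionary rate decays as e^{a*t} from the root
    (a <= 0), applied as a branch-length transform with joint ML over the
    exponent a and the Mk rate; delta: node depths are raised to the power
    delta in [1e-3, 3] (delta < 1 concentrates change early).  Reports AIC
    and each transform's AIC difference from the untransformed equal-rates
    fit (positive = the extra parameter is not worth it).
    """
    if not matrix.is_singleton():
        raise ValueError("trait models require simplified (single-state) tips")
    crown = tree.crown_age

    er = mk_fit(tree, matrix, structure="ER")
    fits = {"equal_rates": TraitModelFit(
        "equal_rates", {"q": float(er.rates[0])}, er.lnL, 1)}

    a_min = math.log(1e-5) / crown
    alphabet = matrix.alphabet
    tipv = _tip_vectors(matrix, None, alphabet)
    logq0 = math.log(max(float(er.rates[0]), 1e-8))
    q_bounds = (logq0 - 10, logq0 + 8)

    def fit_transform(name, transform_args, shape_bounds, shape0):
        # joint (shape parameter, log rate) maximization
        def neg(theta):
            shape, logq = theta
            bl = _transformed_lengths(tree, *transform_args(shape))
            return -mk_loglik(tree, tipv, alphabet, "ER",
                              np.exp([logq]), branch_lengths=bl)

        best = None
        for s0 in shape0:
            res = optimize.minimize(neg, np.array([s0, logq0]),
                                    method="L-BFGS-B",
                                    bounds=[shape_bounds, q_bounds])
            if best is None or res.fun < best.fun:
                best = res
        shape, logq = best.x
        # the untransformed tree is a boundary case; never fit worse than it
        lnL = max(-best.fun, er.lnL)
        if -best.fun < er.lnL:
            shape = shape_bounds[1] if name == "early_burst" else 1.0
            logq = logq0
        return float(shape), float(math.exp(logq)), float(lnL)

    a_hat, q_eb, lnl_eb = fit_transform(
        "early_burst", lambda a: (_eb_depth, a), (a_min, 0.0),
        (-0.5 / crown, a_min / 4))
    fits["early_burst"] = TraitModelFit(
        "early_burst", {"a": a_hat, "q": q_eb}, lnl_eb, 2)

    d_hat, q_dl, lnl_dl = fit_transform(
        "delta", lambda dl: (_delta_depth, dl, crown), (1e-3, 3.0),
        (0.5, 2.0))
    fits["delta"] = TraitModelFit(
        "delta", {"delta": d_hat, "q": q_dl}, lnl_dl, 2)

    base = fits["equal_rates"].aic
    delta_aic = {m: f.aic - base for m, f in fits.items()}
    return {"fits": fits, "delta_aic": delta_aic}
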