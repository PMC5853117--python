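"""Lineage-through-time diversification analysis.

Implements the Pybus–Harvey gamma statistic with normal-theory p-values,
maximum-likelihood fitting of four branching models to a set of branching
times (pure birth, birth–death, and the logistic and exponential
density-dependent models DDL/DDX) with AIC comparison, pure-birth tree
simulation conditioned on tip number, and a missing-taxon sensitivity
procedure that compares an observed statistic against nulls simulated with
a set fraction of tips randomly pruned.

Model likelihoods are functions of the internode intervals g_k (duration
with exactly k lineages) of an :class:`~radshift.tree_core.LTTProfile`:

    lnL = sum_{k=2}^{n-1} ln(k * lambda_k)  -  sum_{k=2}^{n} k * lambda_k * g_k

with per-lineage speciation rate lambda_k = lambda (pure birth),
r*(1 - k/K) (DDL) or r*k^-x (DDX).  The birth–death model uses the
crown-conditioned Nee et al. likelihood parameterised by net rate
r = lambda - mu and extinction fraction a = mu/lambda; at a = 0 it reduces
exactly to the pure-birth likelihood above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .tree_core import (
    LTTProfile,
    Node,
    TimeTree,
    TreeError,
    branching_profile,
    prune_random_tips,
)

__all__ = [
    "GammaResult",
    "DiversificationFit",
    "SensitivityResult",
    "gamma_stat",
    "gamma_pvalue",
    "gamma_test",
    "fit_pure_birth",
    "fit_birth_death",
    "fit_density_dependent",
    "compare_models",
    "simulate_yule",
    "sensitivity_missing",
]


# ---------------------------------------------------------------------------
# Gamma statistic


@dataclass(frozen=True)
class GammaResult:
    gamma: float
    n: int
    p_two_tailed: float
    p_one_tailed_lower: float
    source: str = "full"


def gamma_stat(profile: LTTProfile) -> float:
    """Pybus–Harvey gamma: standardized summary of internode intervals.

    gamma = [ mean(T_2..T_{n-1}) - T/2 ] / [ T * sqrt(1/(12(n-2))) ] where
    T_i = sum_{k=2}^{i} k*g_k and T = T_n.  Asymptotically standard normal
    under a constant-rate pure-birth process with complete sampling;
    negative values mean branching is concentrated early (slowdown).
    """
    n = profile.n
    if n < 3:
        raise TreeError("gamma requires at least 3 lineages")
    T = profile.total
    if not T > 0:
        raise TreeError("gamma requires positive total lineage-time")
    inner = profile.weighted_cumsum[:-1].sum() / (n - 2)
    return float((inner - T / 2.0) / (T * math.sqrt(1.0 / (12 * (n - 2)))))


def gamma_pvalue(gamma: float, tails: str = "two") -> float:
    """Standard-normal p-value for an observed gamma.

    ``tails="two"``: 2*(1 - Phi(|gamma|)); ``tails="one_lower"``: Phi(gamma),
    the probability of a slowdown at least this strong.
    """
    if not math.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if tails == "two":
        return float(2.0 * stats.norm.sf(abs(gamma)))
    if tails == "one_lower":
        return float(stats.norm.cdf(gamma))
    raise ValueError(f"unknown tails {tails!r}")


def gamma_test(tree_or_profile, cut_age: float = 0.0,
               source: str = "full") -> GammaResult:
    """Gamma with both p-values for a tree or a precomputed profile."""
    if isinstance(tree_or_profile, LTTProfile):
        prof = tree_or_profile
    else:
        prof = branching_profile(tree_or_profile, cut_age=cut_age)
    g = gamma_stat(prof)
    return GammaResult(
        gamma=g,
        n=prof.n,
        p_two_tailed=gamma_pvalue(g, "two"),
        p_one_tailed_lower=gamma_pvalue(g, "one_lower"),
        source=source,
    )


# ---------------------------------------------------------------------------
# Model fits


@dataclass(frozen=True)
class DiversificationFit:
    model: str                      # pure_birth | birth_death | DDL | DDX
    params: dict
    lnL: float
    n_params: int
    boundary: bool = False          # optimum pinned at a parameter bound

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.lnL


def _check_profile(profile: LTTProfile, min_n: int) -> None:
    if profile.n < min_n:
        raise TreeError(f"model fitting requires at least {min_n} lineages")


def fit_pure_birth(profile: LTTProfile) -> DiversificationFit:
    """Yule model; closed-form MLE lambda_hat = (n-2)/T."""
    _check_profile(profile, 3)
    n = profile.n
    T = profile.total
    if not T > 0:
        raise TreeError("total lineage-time must be positive")
    lam = (n - 2) / T
    k = np.arange(2, n)
    lnL = float(np.log(k * lam).sum() - lam * T)
    return DiversificationFit("pure_birth", {"lambda": lam}, lnL, 1)


def _bd_lnl(r: float, a: float, b: np.ndarray) -> float:
    """Crown-conditioned birth-death log-likelihood of branching-time ages
    ``b`` (descending, b[0] = crown age), net rate r, extinction fraction a."""
    n = len(b) + 1
    if r <= 0 or not 0 <= a < 1:
        return -np.inf
    # ln(e^{r b} - a) = r b + log1p(-a e^{-r b}), overflow-safe
    cross = np.log1p(-a * np.exp(-r * b)) if a > 0 else np.zeros_like(b)
    return float(
        math.lgamma(n)
        + (n - 2) * math.log(r)
        - r * (b[0] + b.sum())
        + n * math.log1p(-a)
        - 2.0 * cross.sum()
    )


def fit_birth_death(profile: LTTProfile) -> DiversificationFit:
    """Constant-rate birth-death fit by bounded 2-D optimization.

    Conditioned on the crown age and survival of both crown lineages
    (Nee et al. form).  Nested above pure birth: the a = 0 start guarantees
    lnL(BD) >= lnL(pure birth).
    """
    _check_profile(profile, 3)
    b = profile.branching_times
    n = profile.n
    pb = fit_pure_birth(profile)

    def neg(theta):
        logr, a = theta
        return -_bd_lnl(math.exp(logr), a, b)

    best = (pb.lnL, math.log(pb.params["lambda"]), 0.0)
    r0 = pb.params["lambda"]
    for a0 in (0.0, 0.3, 0.6, 0.9):
        # at extinction fraction a the net rate shrinks; rescale the start
        x0 = np.array([math.log(r0 * (1 - 0.5 * a0)), a0])
        res = optimize.minimize(
            neg, x0, method="L-BFGS-B",
            bounds=[(math.log(r0) - 12, math.log(r0) + 12), (0.0, 1 - 1e-9)],
        )
        if res.success and -res.fun > best[0] + 1e-12:
            best = (-res.fun, res.x[0], res.x[1])
    lnL, logr, a = best
    r = math.exp(logr)
    boundary = a > 1 - 1e-6
    return DiversificationFit(
        "birth_death", {"r": r, "a": a, "lambda": r / (1 - a) if a < 1 else np.inf,
                        "mu": r * a / (1 - a) if a < 1 else np.inf},
        lnL, 2, boundary=boundary,
    )


def _dd_profile_lnl(lam_k: np.ndarray, g: np.ndarray, n: int) -> tuple[float, float]:
    """Profile likelihood for a rate sequence lambda_k = r * shape_k.

    ``lam_k`` holds shape_k for k = 2..n; returns (r_hat, lnL at r_hat).
    """
    k = np.arange(2, n + 1, dtype=float)
    W = float((k * lam_k * g).sum())
    if W <= 0 or np.any(lam_k[:-1] <= 0):
        return np.nan, -np.inf
    r = (n - 2) / W
    lnL = float(np.log(k[:-1] * r * lam_k[:-1]).sum() - (n - 2))
    return r, lnL


def fit_density_dependent(profile: LTTProfile, form: str = "DDL") -> DiversificationFit:
    """Density-dependent diversification fit.

    DDL: lambda_k = r*(1 - k/K) with carrying capacity K > n, searched on a
    log scale up to 1e6.  DDX: lambda_k = r*k^-x with exponent x in [0, 5].
    The initial rate r is profiled out in closed form; the remaining
    parameter is optimized by bounded 1-D search.  Both models reduce to
    pure birth at their boundary (K -> inf, x = 0).
    """
    _check_profile(profile, 4)
    n = profile.n
    g = profile.intervals
    k = np.arange(2, n + 1, dtype=float)

    if form == "DDL":
        # K = n + exp(u); u spans slightly-above-n .. 1e6
        u_hi = math.log(1e6)

        def neg(u):
            K = n + math.exp(u)
            return -_dd_profile_lnl(1.0 - k / K, g, n)[1]

        res = optimize.minimize_scalar(neg, bounds=(-6.0, u_hi), method="bounded",
                                       options={"xatol": 1e-10})
        K = n + math.exp(res.x)
        r, lnL = _dd_profile_lnl(1.0 - k / K, g, n)
        boundary = res.x > u_hi - 1e-3
        # pure birth is the K -> inf boundary; never report a worse fit
        pb = fit_pure_birth(profile)
        if pb.lnL > lnL:
            r, K, lnL, boundary = pb.params["lambda"], np.inf, pb.lnL, True
        return DiversificationFit("DDL", {"r": r, "K": K}, lnL, 2, boundary=boundary)

    if form == "DDX":
        def neg(x):
            return -_dd_profile_lnl(k ** (-x), g, n)[1]

        res = optimize.minimize_scalar(neg, bounds=(0.0, 5.0), method="bounded",
                                       options={"xatol": 1e-10})
        x = float(res.x)
        r, lnL = _dd_profile_lnl(k ** (-x), g, n)
        # pure birth is the x=0 boundary; never report a worse-than-nested fit
        pb = fit_pure_birth(profile)
        if pb.lnL > lnL:
            x, r, lnL = 0.0, pb.params["lambda"], pb.lnL
        return DiversificationFit("DDX", {"r": r, "x": x}, lnL, 2,
                                  boundary=x < 1e-8 or x > 5 - 1e-6)

    raise ValueError(f"unknown density-dependent form {form!r}")


def compare_models(profile: LTTProfile) -> dict:
    """Fit all four models; report the AIC table and the constant-rate vs
    density-dependent contrast.

    ``delta_aic`` = AIC(best constant-rate) - AIC(best density-dependent);
    positive values favor density dependence.
    """
    fits = {
        "pure_birth": fit_pure_birth(profile),
        "birth_death": fit_birth_death(profile),
        "DDL": fit_density_dependent(profile, "DDL"),
        "DDX": fit_density_dependent(profile, "DDX"),
    }
    best = min(fits.values(), key=lambda f: f.aic)
    best_cr = min(fits["pure_birth"].aic, fits["birth_death"].aic)
    best_dd = min(fits["DDL"].aic, fits["DDX"].aic)
    return {
        "fits": fits,
        "best_model": best.model,
        "delta_aic": best_cr - best_dd,
    }


def delta_aic_statistic(profile: LTTProfile) -> float:
    """The sensitivity-procedure statistic: AIC(best constant-rate) minus
    AIC(best density-dependent)."""
    return compare_models(profile)["delta_aic"]


# ---------------------------------------------------------------------------
# Pure-birth simulation


def simulate_yule(n_tips: int, seed, lam: float = 1.0) -> TimeTree:
    """Pure-birth tree conditioned on tip number.

    Grows from 2 lineages with exponential waiting times at total rate
    k*lam; each event splits a uniformly chosen extant lineage.  The final
    interval (after the (n-1)th split, while n lineages exist) is also
    Exp(n*lam), so all internode intervals g_k ~ Exp(k*lam) independently —
    the regime in which the gamma statistic is standard normal.
    """
    if n_tips < 3:
        raise TreeError("simulate_yule requires n_tips >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ks = np.arange(2, n_tips + 1, dtype=float)
    g = rng.exponential(1.0 / (ks * lam))        # g_2 .. g_n
    split_times = np.cumsum(g[:-1])              # forward time of splits 3..n
    total = float(g.sum())

    root = Node(None, total)
    active = [root.add_child(Node()), root.add_child(Node())]
    for i in range(n_tips - 2):
        age = total - float(split_times[i])
        j = rng.integers(len(active))
        node = active[j]
        node.age = age
        left, right = node.add_child(Node()), node.add_child(Node())
        active[j] = left
        active.append(right)
    for tip in active:
        tip.age = 0.0
    # deterministic tip labels in preorder
    tree = TimeTree(root)
    for i, tip in enumerate(tree.tips()):
        tip.label = f"t{i + 1}"
    return tree


# ---------------------------------------------------------------------------
# Missing-taxon sensitivity


@dataclass(frozen=True)
class SensitivityResult:
    statistic: str                   # "gamma" or "dAIC"
    observed: float
    fractions: list
    critical_values: dict            # f -> (lo, hi) or (hi,) for one-tailed
    significant: dict                # f -> bool
    max_fraction_missing: float | None   # None => "ns"

    @property
    def label(self) -> str:
        if self.max_fraction_missing is None:
            return "ns"
        return f"{round(self.max_fraction_missing * 100)}%"


def sensitivity_missing(observed: float, statistic_fn, n_tips: int,
                        alpha: float = 0.05, tails: str = "two",
                        n_sim: int = 10000, f_step: float = 0.1,
                        f_max: float = 0.9, seed: int = 0,
                        statistic_name: str = "gamma") -> SensitivityResult:
    """How much incomplete sampling the observed statistic survives.

    For each missing fraction f (0, f_step, 2*f_step, ...): simulate
    ``n_sim`` pure-birth trees with round(n_tips/(1-f)) tips, prune
    round(f * that) random tips, evaluate ``statistic_fn`` on each, and take
    empirical critical values at level ``alpha`` (two-tailed for gamma,
    upper one-tailed for the ΔAIC statistic).  The fraction is increased
    until the observed value is no longer significant; the last significant
    fraction is reported, or None ("ns") if f = 0 already fails.
    """
    rng = np.random.default_rng(seed)
    fractions, crits, sig = [], {}, {}
    max_sig = None
    f = 0.0
    while f <= f_max + 1e-9:
        n_start = int(round(n_tips / (1.0 - f))) if f > 0 else n_tips
        n_prune = int(round(f * n_start))
        vals = np.empty(n_sim)
        for i in range(n_sim):
            t = simulate_yule(n_start, rng)
            if n_prune:
                t = prune_random_tips(t, n_prune, int(rng.integers(2 ** 31)))
            vals[i] = statistic_fn(t)
        if tails == "two":
            lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
            crits[f] = (float(lo), float(hi))
            is_sig = observed < lo or observed > hi
        elif tails == "one_upper":
            hi = float(np.quantile(vals, 1 - alpha))
            crits[f] = (hi,)
            is_sig = observed > hi
        elif tails == "one_lower":
            lo = float(np.quantile(vals, alpha))
            crits[f] = (lo,)
            is_sig = observed < lo
        else:
            raise ValueError(f"unknown tails {tails!r}")
        fractions.append(f)
        sig[f] = bool(is_sig)
        if is_sig:
            max_sig = f
        else:
            break
        f = round(f + f_step, 10)
    return SensitivityResult(
        statistic=statistic_name, observed=observed, fractions=fractions,
        critical_values=crits, significant=sig, max_fraction_missing=max_sig,
    )
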