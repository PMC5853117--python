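# Methods

This note documents the models, defaults and numerical choices behind
`radshift`, and what the synthetic-data tests do and do not demonstrate.

## Tree model

Trees are rooted and ultrametric with node *ages* (Ma before present) as
the primary quantity; branch lengths are derived as parent age minus own
age.  On input, ages are reconstructed from root-to-tip path lengths; tip
depths within 1e-6 Ma of the deepest tip are snapped to age 0, larger
deviations are an error unless forced alignment is requested (consensus
trees with median branch lengths are often slightly non-ultrametric).
Zero-length internal branches are allowed; simultaneous branching times
are ordered deterministically by preorder index.  Multifurcations are
read and written but rejected by operations that need a strictly binary
branching sequence (gamma, model fitting, split tallies).

**Truncation** at age *a* makes every branch crossing the age line a tip
on the line and re-zeroes ages so the line becomes the present (terminal
branches are shortened by *a*); a node whose age equals the cutoff is
kept.  Gamma is invariant to this shift, so truncating first or cutting
the profile at *a* gives the same statistic (tested as a two-route
invariant).  Branching profiles with a cut age ignore nodes younger than
the cut for the same reason.

## Lineage delimitation

Distances are raw counts of differing sites over columns where both
sequences have unambiguous A/C/G/T (gaps and IUPAC codes excluded
pairwise).  The guide tree is Saitou–Nei neighbor joining implemented
in-package so its tie-breaks are specified: Q-matrix ties go to the
smallest input-order index pair, and a negative branch estimate is
clamped to zero with the deficit moved to its sibling.  The tree is
rooted by splitting the outgroup's edge at its midpoint.

Delimitation finds the finest partition into guide-tree-monophyletic
groups whose between-group sequence pairs all differ by at least
`min_diff` substitutions (default 3): transitive closure of the
"closer than threshold" relation, then enlargement of each group to the
smallest containing clade until monophyletic.  A haplotype lying within
the threshold of two or more groups that are themselves mutually
divergent is treated as a sampled ancestral haplotype: excluded if rare
(≤ 3 specimens), otherwise left to chain its neighbors into one combined
lineage.  This deterministic rule replaces case-by-case inspection of
haplotype networks; it is validated against a brute-force search for the
finest valid monophyletic partition on small simulated cases.  Species
clusters use single linkage at proportional distance < 0.04 — the
chaining behavior matches divergence-threshold species assignment.
Exemplars are medoids (minimum mean within-lineage distance, lexicographic
ties); the delimitation criterion guarantees exemplar pairs differ by at
least `min_diff`.

## Character coding and ancestral states

Specimen records give per-lineage state frequencies (records coded
"unknown" are dropped).  Three codings: *polymorphic* keeps states at
frequency ≥ 0.05; *predominant* keeps the modal state plus any within
0.2 of it; *simplified* keeps the modal state only (ties lexicographic).
Use on both flower sexes appears as specimen-level variation and hence
tip polymorphism; there is no dedicated "both" state.

Parsimony is unordered with unit costs, computed by exact Sankoff dynamic
programming (up- and down-pass cost vectors).  MPR sets are exact: a
state belongs to a node's set iff its up+down cost equals the global
minimum — this is guaranteed correct for polymorphic tips (any member
state satisfiable at no cost) and multifurcations, unlike the classic
Fitch final-pass heuristic.  ACCTRAN/DELTRAN resolve ambiguity in
preorder under the constraint that the child's state keep the total
length minimal given the parent's resolved state; ACCTRAN prefers a
change on the entering branch whenever the minimum allows, DELTRAN
prefers none.  Both resolutions attain exactly the MPR length (tested).

The Mk model uses an equal-rates generator by default (symmetric and
all-rates-different structures are available); the rate is fitted by
bounded 1-D search on a log scale via the pruning algorithm, with tip
partial likelihoods initialized to the observed frequency vector rather
than one-hot — within-lineage variation enters as a tip prior.  The root
is weighted uniformly over observed states.  Stochastic mapping fits the
rate matrix per source tree (mirroring per-tree handling of a posterior
sample), samples node states by backward filtering / forward sampling,
and draws branch paths conditional on endpoints by rejection sampling
(cap 10,000 attempts) with an exact uniformization fallback.  Ten maps
per tree is the default.

Trait-model comparison fits equal-rates Mk on the untransformed tree and
on early-burst (rate ∝ e^{a·t} from the root, a ≤ 0, lower bound
log(1e-5)/crown) and delta (node depths ↦ crown·(depth/crown)^δ,
δ ∈ [1e-3, 3]) transforms, jointly optimizing the shape parameter and
rate by L-BFGS-B from two starts.  Because the transforms nest the
untransformed tree at their boundary, fits are floored at the equal-rates
likelihood.  Note that with the truth on the a = 0 boundary, the expected
AIC penalty for the wasted exponent is 1.5, not 2 (the likelihood-ratio
improvement is a ½·0 + ½·(χ²₁/2) mixture).

## Split tallies and the permutation test

A split is *old* iff its age ≥ the breakpoint (default 3 Ma; the boundary
counts as old — measure-zero in practice).  A shift is counted when the
two immediate descendants' state sets are disjoint: resolved single
states for internal descendants, coded state sets for tips.  A shift in
host species *or* host tissue constitutes the composite host shift.
Simmap tallies compare the sampled states at the two descendant nodes —
the states immediately before each descendant's own terminal event —
regardless of how many transitions occurred along the branches.

The permutation statistic D = P(shift | old) − P(shift | young) uses MPR
sets (a shift only when descendant MPR sets are disjoint — no
ACCTRAN/DELTRAN split), the composite host∨tissue shift when both host
characters are supplied, and whole-row shuffles: one permutation of the
tip-to-row assignment applied to all characters, preserving their
correlation under the null.  Both the raw b/m p-value (which can be
exactly 0) and the (b+1)/(m+1) correction are reported.  The MPR-
disjointness rule is conservative at nested ambiguous nodes: with many
equally parsimonious histories a deep node's MPR set can absorb states
from both sides, so "every old split shifts" is attainable only when old
splits are not nested — the planted-signal test is built accordingly.

## Diversification

The likelihood of a branching profile with internode intervals g_k
(duration with exactly k lineages, k = 2..n; the final interval down to
the present/cut line is included in all survival terms) is
Σ ln(k·λ_k) − Σ k·λ_k·g_k with λ_k constant (pure birth, MLE
λ̂ = (n−2)/T), logistic (DDL, λ_k = r(1−k/K), K > n searched on a log
scale up to 1e6) or power-law (DDX, λ_k = r·k⁻ˣ, x ∈ [0, 5]); for DDL and
DDX the initial rate is profiled out in closed form and the remaining
parameter optimized by bounded 1-D search (tolerance 1e-10).  The
birth–death model uses the Nee-style likelihood conditioned on the crown
age and survival of both crown lineages, parameterized by net rate r and
extinction fraction a ∈ [0, 1), optimized by multi-start L-BFGS-B with
log-rate parameterization; at a = 0 it equals the pure-birth likelihood
exactly (the lfact(n−1) constant equals Σ ln k), so nesting inequalities
hold to machine precision.  DDL/DDX fits are floored at the pure-birth
likelihood, their K→∞ / x = 0 boundary.  The model comparison reports
ΔAIC = AIC(best constant-rate) − AIC(best density-dependent), positive
favoring density dependence.

Gamma p-values are two-tailed 2(1−Φ(|γ|)) and one-tailed lower Φ(γ);
both are always emitted because truncated-tree analyses are naturally
one-tailed (does the truncated tree still show a slowdown?) even where a
two-tailed convention is used for full trees.

Pure-birth simulation conditions on tip number by drawing all internode
intervals g_k ~ Exp(kλ) — including the final hanging interval — which is
precisely the regime in which gamma is standard normal; topology grows by
splitting a uniformly chosen extant lineage.  The missing-taxon
sensitivity procedure simulates, for each missing fraction f, trees with
round(n/(1−f)) tips, prunes round(f·that) random tips, recomputes the
statistic, takes empirical critical values at α = 0.05 (two-tailed for
gamma, upper one-tailed for the density-dependence ΔAIC) and raises f in
0.1 steps until the observed value stops being significant, reporting the
last significant fraction.

## Synthetic data

The generator emulates the study conditions: a pure-birth tree rescaled
to a 13 Ma crown with 115 lineages (birth–death and DDL growth
available); characters evolved as equal-rates Markov chains whose total
leave-rate switches at the 3 Ma breakpoint (host 0.30→0.04 events/Ma,
tissue 0.12→0.03, region constant 0.15 in the study-shaped fixture — an
old-era concentration of host shifts against constant geographic
turnover); ~33 specimens per lineage drawn Dirichlet-multinomially with
concentration 40 on the true state (≈ 93% of specimens on the modal
host, the "predominantly one host" regime); and 504-bp Jukes–Cantor
sequences at 0.01 substitutions/site/Ma (~2% divergence per Ma of
separation, barcode-typical).  An optional minimum-split-age filter keeps
one exemplar per young clade with branch lengths intact, emulating
sampling of well-separated lineages only.  Every character transition is
logged with its branch and age, so tallies can be checked against truth.

What the generator does *not* emulate: phylogenetic uncertainty (a
posterior tree sample), host–region correlation (off by default; a
coupling knob exists), substitution rate heterogeneity, saturation, or
missing data.  Passing recovery tests therefore show the pipeline is
correct under its own assumptions, not that those assumptions hold for
any particular empirical dataset.

## Problem sizes in the test suite

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the asserted tolerance: 10,000 trees for the gamma null
critical value (±0.07 around 1.96), 1,000 replicates for permutation
type-I error (±2 MC SE around 0.05, on a 60-tip tree where the discrete
statistic has few ties), 100 replicates for rate-recovery medians and
DDL power, 50 for delimitation and era-contrast recovery, and exhaustive
enumeration oracles at ≤ 7 tips / ≤ 3 states for parsimony and 5 tips for
the Mk likelihood.

## Known limitations

- The ancestral-haplotype exclusion rule is an explicit formalization of
  a procedure that was originally partly manual; other reasonable rules
  exist for deeply paraphyletic cases.
- ACCTRAN/DELTRAN are preorder greedy resolutions; they attain the MPR
  length but, like all such resolutions, are not unique labelings.
- The birth–death extinction fraction is weakly identified from
  branching times alone; boundary solutions (a → 1) are flagged rather
  than prevented.
- Stochastic-map rejection sampling can be slow at very high rates on
  long branches before the uniformization fallback engages.
- Ordered/weighted parsimony, covarion models and correlated-character
  tests are out of scope.
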