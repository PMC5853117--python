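# radshift

Tools for asking *when* a rapid radiation diversified and *what accompanied
each divergence*: host shifts, changes of host tissue, or geographic
movement.  The package was built around the analysis style used for
species-rich Neotropical insect radiations sampled by DNA barcodes —
hundreds of mtCOI haplotypes, a time-calibrated phylogeny, and thousands of
specimen records of host plant, host tissue and collecting region — but
every stage works on any ultrametric tree plus tabular metadata.

It provides, as a library and a CLI:

1. **Haplotype-lineage delimitation** (`lineage_delim`) — raw pairwise
   difference counts, a neighbor-joining guide tree rooted on an outgroup,
   the finest monophyletic partition whose between-lineage pairs differ by
   ≥ 3 substitutions (~0.5% of a 504-bp barcode), single-linkage "species"
   clusters below 4% divergence, and medoid exemplars.
2. **Ancestral states** (`ancestral_states`) — per-lineage state
   frequencies from specimen records; polymorphic / predominant /
   simplified codings; exact unit-cost parsimony (MPR sets, ACCTRAN and
   DELTRAN); Mk-model stochastic character mapping with frequency priors
   at the tips; equal-rates vs early-burst vs delta trait models by AIC.
3. **Split-shift tallies** (`shift_analysis`) — lineage-splitting events
   cross-classified by age (older/younger than a 3 Ma breakpoint) and by
   character shift (descendants with different states or non-overlapping
   state sets; host **or** tissue counts as a host shift), with a
   row-shuffle permutation test of the old-vs-young contrast.
4. **Diversification** (`diversification`) — lineage-through-time
   profiles; the Pybus–Harvey gamma statistic
   γ = [ (n−2)⁻¹ Σᵢ Tᵢ − T/2 ] / [ T √(1/(12(n−2))) ] with normal-theory
   p-values; ML fits of pure-birth, birth–death (Nee crown-conditioned),
   DDL (λₖ = r(1−k/K)) and DDX (λₖ = r·k⁻ˣ) models compared by AIC; tree
   truncation at 1 Ma; and a missing-taxon sensitivity procedure built on
   pure-birth simulation with random pruning.
5. **Synthetic data** (`synthetic_data`) — fully seeded generator of
   trees, era-dependent character histories (with every true shift
   logged), polymorphic specimen tables and Jukes–Cantor barcode
   alignments, so the whole pipeline is testable against known truth.

## Worked example

Simulate a study-shaped dataset (115 lineages, 13 Ma crown, host shifts
concentrated before 3 Ma) and analyze it:

```bash
radshift simulate --study-shaped --seed 7 --out demo
radshift gamma demo/tree.nwk
radshift permtest demo/tree.nwk demo/specimens.tsv --m 1000 --seed 7
```

The gamma command prints

```json
{
 "gamma": -1.0948924159986793,
 "n": 115,
 "p_one_tailed_lower": 0.13678188600422841,
 "p_two_tailed": 0.27356377200845683
}
```

— a mildly negative but non-significant gamma, i.e. no detectable
departure from a constant branching rate in this replicate.  The
permutation test prints

```json
{
 "characters": ["host_species", "host_tissue"],
 "m": 1000,
 "observed_D": 0.4503766786767114,
 "p_corrected": 0.000999000999000999,
 "p_raw": 0.0
}
```

`observed_D` is the difference in the proportion of splits accompanied by
a host-or-tissue shift between old (> 3 Ma) and young splits; none of the
1000 row-shuffled matrices reached it (raw p = 0), correctly detecting the
old-era concentration of host shifts that this scenario was generated
with.  `radshift fitdiv demo/tree.nwk` reports pure birth as the
best-fitting of the four diversification models on the same tree, with
the density-dependent models gaining no AIC advantage
(`delta_aic_dd` = −0.42).

A full bundle — delimitation, codings, parsimony and stochastic-map
tallies, permutation test, and gamma/model-fit rows for the full tree,
the 1 Ma-truncated tree and any configured clades — comes from:

```bash
radshift run-all demo/tree.nwk --specimens demo/specimens.tsv \
    --alignment demo/alignment.fasta --outgroup OUTGROUP --out demo/results
```

Reruns with the same seed are byte-identical; every result carries the
seed and config hash that produced it.

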