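# parknest

Taxonomic and functional nestedness analysis of species-by-site community
matrices, built for habitat-island settings such as bird assemblages in
urban parks.

A community is *nested* when the species found at species-poor sites are
subsets of those at species-rich sites; it is *anti-nested* when composition
turns over between sites instead. `parknest` implements the full inferential
workflow around this question:

* **NODF / WNODF** — nestedness based on overlap and decreasing fill, for
  presence–absence and abundance matrices, with separate species-incidence
  (rows) and site-composition (columns) components. For an ordered row pair
  (i above j) with strictly decreasing marginal totals, NODF scores
  `100 · |overlap| / MT_j`; WNODF counts cells of the poorer row that are
  non-zero and strictly smaller than the richer row's matching cell,
  normalised by the poorer row's fill.
* **Null models** — Monte-Carlo significance under four randomizations of
  the abundance matrix: `pp` (cell probabilities proportional to row×column
  totals), `rc` (fixed row and column sums, Patefield sampling), `aa`
  (equiprobable placement, fixed grand total N) and `ss` (fixed fill F and
  N). Verdicts (nested / anti-nested / not significant) come from the 95%
  percentile interval of 1000 null matrices.
* **Random placement** — Coleman's passive-sampling model: with relative
  area `a_j` and pooled abundance `n_i`, expected richness is
  `E_j = S − Σ_i (1 − a_j)^{n_i}`; the passive-sampling hypothesis is
  rejected when more than 1/3 of sites fall outside `E_j ± 1 SD`.
* **Sample coverage** — Chao–Jost abundance-based coverage
  `Ĉ = 1 − (f1/n)·[(n−1)f1 / ((n−1)f1 + 2 f2)]` with hypergeometric
  rarefaction and Chao1-style extrapolation of richness.
* **Functional nestedness** — Gower distances on continuous traits, a UPGMA
  dendrogram, and **treeNODF**: the NODF idea applied to the branch length a
  site's assemblage spans on the tree, with the additive decomposition
  `treeNODF = S.Fraction + topoNODF` (shared-species branch length vs shared
  topology beyond shared species) and the *permRows* permutation test for
  the decreasing-area ordering.
* **Synthetic communities** — a generator with a nestedness dial θ ∈ [0, 1]
  (area-threshold incidence mixed with area-independent occupancy),
  overdispersed abundances, group flags and correlated traits, emulating a
  17-park / 95-species survey so the whole pipeline is testable without
  field data.

## Worked example

Simulate a strongly area-structured community of 30 species on 8 sites and
score it:

```sh
$ parknest simulate -o demo --seed 42 --n-species 30 --n-sites 8 --theta 0.8
$ parknest metrics demo/matrix.csv --metric nodf
NODF = 86.12 (rows 85.70, cols 91.83)
$ parknest metrics demo/matrix.csv --metric wnodf
WNODF = 42.49 (rows 41.21, cols 59.71)
$ parknest metrics demo/matrix.csv --metric treenodf \
      --areas demo/areas.csv --traits demo/traits.csv --n-perm 99 --seed 1
treeNODF = 93.77 (S.Fraction 93.32 + topoNODF 0.45)
  treeNODF: z = 3.33, p = 0.01
  S.Fraction: z = 3.34, p = 0.01
  topoNODF: z = 0.87, p = 0.27
```

A NODF of 86 says that, after packing rows and columns by decreasing totals,
the average poorer row/column re-occurs to 86% inside richer ones — a highly
nested incidence structure (θ = 0.8 by construction). WNODF is lower because
it additionally requires abundances to decrease into poorer sites. The
treeNODF of 93.8 with permutation p = 0.01 (the floor at 99 permutations)
says small sites carry nested subsets of the *functional branch length* of
large sites, and the split shows this is driven almost entirely by shared
species (S.Fraction) rather than tree topology (topoNODF, p = 0.27).

The full study workflow — five bird groups (all, passerines, residents,
insectivores, omnivores; waterbirds always excluded), two metrics, three
components, four null models, coverage, random placement and functional
nestedness — runs from a YAML config:

```sh
parknest run -c config.yaml     # writes coverage.csv, taxonomic_nestedness.csv,
                                # random_placement_*.csv, functional_nestedness.csv
```

All randomness flows from one seed; re-running a config reproduces every
table byte for byte.

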