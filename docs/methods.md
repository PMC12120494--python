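# Methods

## The question and the data model

The package analyses a labelled species × sites abundance matrix (the
community matrix), a site-area table (hectares), a species group table
(passerine / resident / diet guild / waterbird flags) and a continuous trait
table. Species are held in rows internally; readers accept either
orientation. Cells are non-negative integers; validation rejects duplicate
labels and negative or non-numeric cells, naming the offending entity.
Waterbirds are removed before any analysis (they are surveyed incidentally
in park transects), and only five groups are considered large enough to
analyse: all birds, passerines, residents, insectivores and omnivores.
All-zero species rows are dropped with a warning before any metric — a
species observed nowhere carries no information — while all-zero sites are
kept, because zero richness is a meaningful observation; such sites simply
contribute zero-valued paired terms through the metrics' own fill guards.

## NODF and WNODF

Both metrics first *pack* the matrix: rows and columns are sorted by
decreasing marginal totals (stable sort, ties keep input order), presence
counts for NODF and abundance sums for WNODF. Fills enter WNODF only as
paired-term denominators. For each ordered row pair (i above j):

* NODF: if `MT_i > MT_j > 0`, term `= 100 · |overlap| / MT_j`, else 0;
* WNODF: if `total_i > total_j` and `fill_j > 0`, term
  `= 100 · #{c : x_jc > 0, x_ic > x_jc} / fill_j`, else 0.

Columns are scored symmetrically. The row component averages row-pair
terms, the column component column-pair terms, and the overall value is the
mean over the union of both pair sets, so all values live in [0, 100].
Equal marginal totals deliberately contribute 0: no nested subset relation
exists between equally-filled rows. A strictly binary matrix makes every
WNODF term 0 by construction; the function warns and returns 0. Both
implementations are verified against independent literal pair-enumeration
oracles on hundreds of random small matrices.

## Null models and Monte-Carlo inference

The four randomizations are defined by their conservation contracts, which
are asserted on every generated matrix:

| model | construction | conserves |
|-------|-------------|-----------|
| pp | N individuals, cell probability `r_i c_j / N²` | N (margins in expectation) |
| rc | uniform integer table with the observed margins (Patefield, via `scipy.stats.random_table`) | all row and column sums |
| aa | N individuals placed equiprobably | N |
| ss | F cells drawn without replacement, seeded with 1, remaining N − F placed equiprobably on them | N and F |

Each test recomputes the metric (with internal re-packing) on `n_sim = 1000`
null matrices; the three components share the same nulls. Reported per
component: null mean and SD, `z = (obs − mean)/sd` (NaN sentinel when
sd = 0), the 2.5th/97.5th percentile interval, and a two-sided add-one
corrected p-value `min(1, 2·min(#{null ≥ obs}+1, #{null ≤ obs}+1)/(n_sim+1))`.
Two-sided logic is used because both nestedness and anti-nestedness are
meaningful outcomes of the same test; the verdict is *nested* above the
97.5th percentile, *anti-nested* below the 2.5th, *not significant*
otherwise. Reproducibility is bitwise: one seed per test, per-replicate
streams derived by counter through `numpy.random.SeedSequence([seed, k])`.

A calibration note: rc, aa and ss condition on statistics that data
generated under the same model preserve exactly, so model-generated data are
exchangeable with their nulls and the type-I error is nominal (asserted at
5% ± 3 pp in the calibration suite). pp conditions on the *observed*
margins, while pp generation randomises them; like all such conditional
tests its finite-sample type-I error is only approximately nominal, so it is
exercised but not held to the same tolerance.

## Random placement (passive sampling)

With relative areas `a_j = A_j / ΣA` and pooled species abundances `n_i`,
the probability species i misses site j is `(1 − a_j)^{n_i}`, giving
`E_j = S − Σ_i (1 − a_j)^{n_i}` and
`Var_j = Σ_i (1 − a_j)^{n_i} (1 − (1 − a_j)^{n_i})`. The decision rule is
taken verbatim from the field's practice: reject passive sampling when more
than 1/3 of sites fall outside `E_j ± 1 SD`; boundary sites count as within
("not within" read strictly). Species with zero pooled abundance are dropped
with a warning. Each bird group gets its own curve from its own subsetted
matrix.

A known statistical limitation, documented rather than hidden: per-site
richness under the model is a Poisson-binomial sum, so a site lies outside
the ±1 SD band with probability ≈ 0.32 whenever several species have
intermediate presence probabilities. The expected fraction outside therefore
sits almost exactly at the 1/3 threshold, and the rule rejects
model-generated data roughly half the time. The rule is a lenient screening
heuristic for detecting *gross* departures (real structured communities
produce fractions far above 1/3), not a calibrated test; the unit tests
assert the true behaviour (fraction outside concentrating near 1/3 under the
model) rather than a nominal error rate the rule does not possess.

## Coverage and rarefaction/extrapolation

Sample coverage uses the abundance-based estimator
`Ĉ = 1 − (f1/n)[(n−1)f1 / ((n−1)f1 + 2f2)]`, returning 1 when there are no
singletons and 0 in the degenerate all-singleton case; coverage > 0.90 flags
an adequate inventory. Interpolated richness uses exact hypergeometric
rarefaction, `E[S(m)] = Σ_i [1 − C(n−x_i, m)/C(n, m)]`, computed stably via
`scipy.stats.hypergeom.pmf(0, n, x_i, m)` and verified against an exhaustive
subsample-enumeration oracle at tiny n. Extrapolation beyond n adds
`f̂0 [1 − (1 − f1/(n f̂0 + f1))^{m*}]` undetected species with the Chao1
`f̂0 = ((n−1)/n) f1²/(2f2)` (or the bias-corrected `f1(f1−1)/2` form when
f2 = 0). The default endpoint is 2n with 40 knots, the reference point m = n
always included (the curve equals observed richness there exactly). Curves
are computed per group on abundances pooled across sites.

## Functional nestedness

Gower distance between species is the range-normalised mean absolute trait
difference; zero-range traits are dropped with a warning and missing values
are excluded pairwise with renormalisation. UPGMA is delegated to
`scipy.cluster.hierarchy.linkage(method="average")`; node heights are half
the merge distance, so the tree is ultrametric and cophenetic distances
equal the UPGMA distances (half-height branch convention). Tie-breaking
among equidistant merges follows scipy's deterministic nearest-neighbor
chain; with continuous trait distances exact ties have measure zero, and
determinism — the property that matters for reproducibility — is preserved.

treeNODF maps each site to its branch set — every branch on a path from a
present tip to the root; the root itself carries no branch. For sites
ordered by decreasing area (u above v) with summed branch lengths
`BL_u > BL_v > 0`, the paired term is
`100 · length(branches(u) ∩ branches(v)) / BL_v`. The S.Fraction term
replaces the intersection with the branch length spanned by the species
present at *both* sites; since every branch on a shared tip's path to the
root lies in both branch sets, S.Fraction ≤ treepaired and the topoNODF
remainder is non-negative, giving the additive identity
`treeNODF = S.Fraction + topoNODF` to machine precision on every input.
On a star tree (every tip attached directly to the root with equal lengths)
branch sets reduce to species sets and treeNODF equals the row component of
binary NODF in the same site order, with topoNODF = 0 — an exact reduction
used as an oracle in the tests. Presence–absence is used throughout, and
only the site (row) direction is scored, as the ordering gradient is park
area. Significance comes from permRows: `n_perm = 99` uniformly random site
orders, one-sided (greater) add-one p-values per component — the attainable
floor is exactly 1/100 — and z-scores from the permutation mean and SD.

## Synthetic communities

The generator emulates the scale of the motivating survey: 17 sites with
log-uniform areas on (2, 300) ha, 95 species. Species i (rank-ordered from
common to rare) has target occupancy
`k_i = max(1, round(J · ((S − i + 1)/S)^γ))` sites; with the default decay
γ = 1 the occupancies span all of 1..J. Incidence mixes a deterministic
area-threshold rule with area-independent noise:
`P(present at j) = θ·[site j among the k_i largest] + (1 − θ)·k_i/J`. At
θ = 1 the binary matrix is perfectly nested by area (NODF = 100 when
occupancies are distinct); at θ = 0 composition is independent of area; mean
NODF is monotone in θ (asserted over a 50-seed grid). Present cells get
abundance `1 + NegBin(1, mean ∝ a_j)` — overdispersed, area-scaled, never
zero. Default mean abundance per present cell is 4, a typical transect count
for a detected species. Traits are two correlated log-normals calibrated to
passerine body mass (~25 g median) and wing length (~80 mm); group flags use
fixed proportions (62% passerine, 68% resident, 42% insectivorous, 30%
omnivorous, 5% waterbird).

What the generator does *not* emulate: spatial autocorrelation between
parks, seasonal turnover, detection error, and realistic rare-species
abundance structure — because present cells have abundance ≥ 1 and means
scale with area, pooled singletons are rare and estimated coverage is
typically ≈ 1.0 rather than the 0.9–0.99 of real surveys. Passing
coverage checks on synthetic data therefore demonstrates the estimator and
plumbing, not survey-completeness behaviour under realistic rarity.

## Pipeline, sizes and numerical choices

The pipeline runs subset → coverage → (metric × null model) → random
placement → functional nestedness per group, 120 null-test rows in the
default design (5 groups × 2 metrics × 3 components × 4 models). The
top-level seed is split per stage/group/metric/model by CRC32 of the stage
tag, keeping all derived seeds below 2³¹; identical configs reproduce
identical report bytes. Defaults follow the study design: 1000 null
matrices, 95% percentile intervals, 99 permutations.

Problem sizes in the test and acceptance runs are chosen for single-CPU
work: type-I calibration uses 16 species × 8 sites with 200 replicates of
200 null matrices; θ-monotonicity uses 50 seeds per grid point at full study
scale; the acceptance script runs the complete study-scale pipeline at the
full 1000/99 settings (≈ 1 minute).

Degenerate inputs: matrices need ≥ 2 species and ≥ 2 sites for any
nestedness metric; a null SD of zero yields a NaN z with the verdict decided
by the percentile interval alone; a single-site area table gives E = S and
SD = 0 in the Coleman curve; ties everywhere break by stable input order.
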