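# Methods

This note documents the models implemented in `museumdiv`, the conventions
and numerical choices behind them, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Overview

The package reproduces, as a reusable pipeline, the post-tree-inference
analyses used to ask whether a Neotropical clade diversified under a
"museum" (steady accumulation, constant rates, low extinction) or a
"cradle" (recent, rapid accumulation) dynamic:

1. **Relative-time dating** of a single-locus phylogram by mean path
   lengths (`museumdiv.mpl`).
2. **DNA-based species delimitation** with the single-threshold general
   mixed Yule coalescent (GMYC) model plus consensus reduction of the
   alignment to one sequence per delimited entity (`museumdiv.gmyc`).
3. **Time-stratified dispersal–extinction–cladogenesis (DEC)** estimation
   of ancestral geographic ranges over six Neotropical areas
   (`museumdiv.dec`).
4. A **diversification-rate battery**: the γ statistic and its Monte Carlo
   constant-rates (MCCR) correction for incomplete sampling, rate-constant
   versus rate-variable model selection by AIC, fixed-time shift tests at
   named geological events, the relative cladogenesis test, and whole-clade
   net-diversification estimators (`museumdiv.divrate`).

Ages are always measured backward from the present (tips at age 0). A
chronogram must be ultrametric within a relative tolerance of 1e-6 of tree
height; trees off by at most 1e-3 (dating-software rounding) can be snapped
back via terminal-branch adjustment behind an explicit `snap=True` flag.
Binary trees are required by every likelihood; polytomies raise immediately.

## Mean-path-length dating

The MPL age of an internal node is the mean path length from the node to
its descendant tips. Raw MPL ages need not be monotone under rate
heterogeneity, so ages are repaired tips-to-root
(`age(parent) = max(age(parent), age(child) + 1e-9)`) and rescaled so the
root equals a requested age — default 1, i.e. relative time, the
convention the GMYC stage expects. The output is exactly ultrametric by
construction and invariant to rescaling the input branch lengths.

The per-node clock test compares the two daughter subtrees' MPLs with a z
statistic. Under a Poisson model of substitutions the variance of a
subtree MPL is `sum over branches of (tips_below / n)^2 * length`, which
accounts for the covariance induced by shared branches; the daughters
share no branches below the tested node, so the variance of the difference
is the sum of the two subtree variances. Branch lengths are interpreted as
substitution counts; pass `sites=L` for per-site lengths. Nodes with a
single-tip daughter are reported NA, and a tree-wide verdict applies a
Bonferroni correction at α = 0.05. Under a simulated strict clock with
Poisson noise the per-node rejection rate is ≈ 5% (calibration is part of
the test suite).

## GMYC species delimitation

A threshold age T splits branching events into an interspecific
diversification (Yule-like) process (events older than T) and intraspecific
coalescent processes within the clusters founded by the branches crossing
T. Branching events partition the tree depth into intervals; interval i of
duration x_i carries the total rate

    b_i = λ1 · n_d,i^p1 + λ2 · Σ_j [n_j,i (n_j,i − 1)]^p2

with n_d,i diversification lineages and n_j,i lineages of cluster j, all
counted during the interval. The log-likelihood is the waiting-time form
Σ (log b_i − b_i x_i) over event-terminated intervals plus the survival
terms −b_i x_i of the interval cut at T and the final interval to the
present. The null model is a single process with rate λ1 [n(n−1)]^p1; it
nests exactly in the threshold model at the crown cut, so the scan maximum
can never fall below the null optimum. The five threshold-model parameters
(λ1, λ2, p1, p2, T) against the null's two give a likelihood-ratio test
with 3 degrees of freedom. On 500 simulated single-process coalescent
trees the test's empirical size at α = 0.05 is ≈ 0.046, so the χ²(3)
reference is adequate.

Candidate thresholds are midpoints between consecutive distinct node ages
plus the two boundary cuts. For each T the rates (λ1, λ2) are profiled by
a damped Newton solve of the 2-D concave subproblem, nested in a coarse
grid plus Nelder–Mead refinement over the scaling exponents
(p1, p2 ∈ [0, 5]; λ ∈ [1e-8, 1e6]; logL tolerance 1e-8). Ties in
likelihood break toward the fewest entities — conservative splitting.
Entities are the branches crossing the ML threshold (singletons included,
typed as such), and the confidence set collects every scanned threshold
within 2 log-likelihood units, with its entity-count range.

Two properties are worth noting. First, the absolute log-likelihood is not
invariant under joint rescaling of ages and rates (it shifts by
(n−2)·log c); the LRT, the p-value, the ML threshold (in rescaled units)
and the entity count are exactly invariant, and those are what the tests
pin. Second, the event terms use the total rate b_i, not the rate of the
component in which an event occurred: the unmarked waiting-time form is
the one whose threshold scan concentrates likelihood at the true
Yule/coalescent boundary in simulation; a marked variant was evaluated and
discards the mixture structure in practice (the scan degenerates toward a
single flexible process).

Consensus reduction collapses an aligned FASTA to one sequence per
cluster: per column, the unanimous base (gaps and N ignored), otherwise
the IUPAC ambiguity code of the observed base set; all-gap columns yield a
gap.

## Time-stratified DEC

Ranges are non-empty subsets of a fixed area list, capped at `maxareas`
(default 2; 22 states over six areas including the absorbing null range,
42 at `maxareas` 3) minus explicitly excluded, biologically implausible
combinations. Along a branch, dispersal adds area b at rate
`d · Σ_{a∈R} m_s[a][b]` — source contributions are additive and the slice
matrix m_s ∈ [0,1] encodes paleogeographic connectivity — and extinction
removes each occupied area at rate e. Slice boundaries default to the
five-slice paleogeographic model (root–32, 32–23, 23–10, 10–7, 7–0 Ma);
times older than the first boundary use the first slice's matrix. Branch
transition probabilities multiply dense matrix exponentials
(scipy's scaling-and-squaring; the space is at most 42×42) over the pieces
of the branch, oldest first.

At a node, a single-area range is inherited identically; a widespread
range R splits by vicariance ({a}, R∖{a}) or subset sympatry ({a}, R),
enumerating ordered daughter assignments, deduplicated, with uniform
weights per ancestral range. The likelihood is computed by post-order
pruning with per-node rescaling; it matches exhaustive enumeration to
1e-9 on every ≤ 4-tip, 2-area case (tested). The root is either fixed to
a constrained range — the conventional reading of "origin in area A";
a flat average over permitted ranges is the alternative — and
`dec_optimize` fits (d, e) by bounded direction-set search
(bounds [1e-9, 10], tolerance 1e-7), flagging boundary estimates on flat
likelihoods. The per-node table re-evaluates the global likelihood with
each candidate (range, split) fixed at that node and reports every
candidate within 2 log-likelihood units of the node's best — the
conventional significance rule for ancestral-range alternatives.

Note that the likelihood is not monotone in `maxareas`: capping the range
size truncates the generator, so raising the cap opens new exit paths from
small ranges and can lower the optimized likelihood. The two caps are
alternatives to compare, not nested models.

## Diversification-rate battery

All Yule-family likelihoods share one convention: condition on the crown
event, count the n−2 subsequent branching events, and use the total
exposure `Σ_{k=2..n} k·g_k` (g_k the time with exactly k lineages,
including the final interval to the present). The pure-birth MLE is then
`λ̂ = (n−2) / Σ k g_k`. The birth–death model uses the Nee-style form in
(r = λ−μ, a = μ/λ), which reduces to the pure-birth likelihood exactly at
a = 0. Rate-variable models: density-dependent linear
(λ(N) = λ0(1 − N/K), K profiled with K > n), density-dependent exponential
(λ(N) = λ0 N^−x), and two- and three-rate Yule models whose shift times
are profiled over the observed branching times (the continuous profile is
monotone between events, so the grid is exact) with closed-form
per-segment rates. AIC = −2 lnL + 2k with k = 1, 2, 2, 2, 3, 5;
ΔAIC_RC = best rate-constant AIC − best rate-variable AIC, negative values
favouring rate constancy, with the 4.0 (n ≈ 30) and 5.5 (n ≈ 100)
guide thresholds reported alongside. The LR between the two selected
models is referred to χ²(1), reproducing the published convention even where
the parameter-count difference is larger.

The γ statistic uses the published closed form; its one-tailed p is
Φ(γ) (small when branching concentrates early). The MCCR test simulates
complete pure-birth trees with the present placed at the moment the
(n+1)-th lineage would arise — under this conditioning every internode
interval is exponential and γ is exactly the standard constant-rates null,
converging to the −1.645 cut-off under complete sampling — then prunes
uniformly at random to the sampled size and takes the 5th percentile. The
speciation rate is immaterial (γ is scale-invariant) and fixed at 1.
For 47 total / 30 sampled species this null's critical value is ≈ −2.2
(cross-checked against an independent R/ape simulation), noticeably more
negative than the published value of −1.78; the published p-value (0.659)
is, however, consistent with this null and inconsistent with that
critical value, so we regard the published critical value as anomalous
and report the recomputed one.

Fixed-time shift tests fit one Yule rate older and one younger than a
given event age (the straddling interval split at the cut; the default
event ages EOGM 34, LOWE 25, MMCO 15, PPG 2.6 Ma are configuration values)
against the constant-rate fit, with χ²(1). The relative cladogenesis test
evaluates, for each non-root internal node, the probability that one of
the k lineages alive just after its parent's split leaves at least the
observed number of the N total tips, under the uniform-composition
(equal-rates Markov) null — `P(≥r) = Σ_m C(N−m−1, k−2)/C(N−1, k−1)` —
with Bonferroni correction over tested nodes. Net-diversification
estimators use the survival-conditioned moment forms
`r_stem = ln(n(1−ε)+ε)/t` and `r_crown = ln(n(1−ε)/2+ε)/t`, chosen so the
ε = 0 limits are exactly ln(n)/t and ln(n/2)/t; they are strictly
decreasing in the relative extinction ε ∈ {0, 0.5, 0.9}.

## Synthetic data

Generators draw from one seeded `numpy` Generator each; identical
parameters and seed give byte-identical output, and each emits its ground
truth (species map, true node ranges, true rates).

* `sim_yule` / `sim_bd`: constant-rate chronograms conditioned on n extant
  tips. The pure-birth present sits at the would-be (n+1)-th event, the
  conditioning under which γ is exactly standard normal. The birth–death
  simulator uses forward first-passage conditioning (present at the first
  moment the extant count would reach n+1; extinction triggers a retry,
  cap 10,000) — an approximation to uniform-present conditioning that is
  adequate for recovery/calibration testing but not a sampler of the exact
  conditioned distribution.
* `sim_gmyc`: Yule species tree rescaled to crown age 1 (configurable),
  each tip replaced by an m-sample within-species coalescent whose
  pairwise rate is scaled so the expected TMRCA equals θ. A coalescent
  deeper than the species' subtending branch would break ultrametricity;
  such subtrees are rescaled to 90% of the available depth and the tree is
  flagged (clusters may then be unidentifiable). The generator emulates
  complete, balanced sampling with equal θ across species — real barcode
  data have uneven sampling, variable population sizes, and gene-tree
  discordance, so passing recovery tests here demonstrates correctness of
  the estimator, not field performance.
* `sim_coalescent`: single-population Kingman tree, the null for the
  delimitation LRT.
* `perturb_rates`: independent lognormal branch-rate noise with mean
  exactly 1 (μ = −σ²/2), emulating a non-clocklike gene tree.
* `sim_dec_ranges`: Gillespie simulation of the per-slice rate matrices
  along branches with uniform cladogenetic scenario draws; branches ending
  in the null range are redrawn (tips must be observable) with the
  rejection count reported, and the run aborts if the rejection rate
  exceeds 0.99. The rejection step conditions each branch on survival,
  which slightly biases tip ranges toward persistence at high e.
* `sim_seqs`: Jukes–Cantor sequences (uniform base frequencies, no rate
  variation across sites), sufficient to exercise consensus reduction and
  distance sanity checks.

## Test conditions and problem sizes

The heavier checks run at these sizes, chosen to finish comfortably on a
single CPU while leaving the statistical criteria sharp: GMYC recovery
uses 100 replicates of 5 species × 4 samples at θ = 0.0005 (crown 1) —
well-separated scales; with θ within an order of magnitude of the
shallowest species split, lumping/oversplitting errors appear, as expected
for threshold-based delimitation. LRT calibration uses 500 replicates of
20-tip coalescent trees. DEC recovery uses 50 replicates of 100-tip trees
over 2 areas (d = 0.05, e = 0.01, d × height ≈ 0.25). The MCCR null uses
the full 10,000 replicates. MPL accuracy uses 50 replicates of 100-tip
chronograms at σ = 0.2.

## Known limitations

* Single-threshold GMYC only; no multiple-threshold or Bayesian variants.
* The GMYC rate forms follow the threshold-model family conventions but
  the exact reference implementation's formulas are not published; validation is by simulation recovery and calibration, not
  by matching published raw log-likelihoods (which are internally
  inconsistent with model nesting as printed).
* DEC has no founder-event (jump) speciation parameter and no
  Bayesian range inference.
* MPL dating provides relative time only; no fossil/secondary
  calibrations (external Bayesian dating is a pass-through stage in the
  pipeline).
* The birth–death simulator's conditioning is approximate (see above).
* Shift-test event ages are user configuration, not estimates; the
  three-rate Yule grid search is O(n²) over branching-time pairs.
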