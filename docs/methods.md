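# Methods

## The model

`resic` infers the temporal order in which genetic or pathway alterations
arise during tumorigenesis from *cross-sectional* genotype counts — one
sample per patient, all taken after diagnosis — without observable
precursor stages.

Each patient is modeled as a compartment of `N` self-renewing cells
evolving by a Moran process: at every division a cell is chosen to divide
in proportion to its relative fitness `r`, one daughter replaces the
parent, the other replaces a uniformly chosen cell, and a daughter may
acquire the next hit of one of the 2–3 alteration events under study.  In
the step-by-step regime (each arising mutant lineage fixes or is lost
before the next one appears) the compartment occupies a single
*mutational state* — the tuple of current hit levels, one entry per event
— and moves through a finite DAG of states.  The per-division rate along
an edge is

    rate = u · φ(r_target / r_source, N),
    φ(r, N) = (1 − 1/r) / (1 − 1/r^N),  φ(1, N) = 1/N,

where `φ` is the Moran fixation probability of a single mutant and `u`
is the mutation supply: `(2 − level) · μ · N` for a gene-level event
(diploid alleles depleting with each hit) and `M · μ_g · N` for a
collapsed pathway event with `M` member genes.  Gene-level events default
to two allelic levels so that low-level and high-level amplification can
be ordered as sequential hits; pathway events are binary.

At the patient-population level a constant influx `φ_in` of newly
diagnosed, unmutated patients enters the origin state and an equal
outflux (per-patient rate `δ`) leaves the fully mutated state.  Because
the state graph is a DAG, the steady-state balance system is triangular
in any topological order and is solved exactly by a single sweep (the
residual of the full balance system is checked in the tests at 1e-10).
Steady-state frequencies are compared with observed cohort counts; the
origin→terminal through-flux is decomposed over ordered paths, each
path's share being the product over its edges of the edge's fraction of
its source state's outflow.  The share of paths in which event A's first
hit precedes event B's is the *ordering flux* — the frequency reported
for the temporal sequence "A before B".

## Parameters

| parameter | default | meaning |
|---|---|---|
| `N` | 100 | cells at risk per patient compartment; neutral fluxes are provably independent of `N` and fitted results are robust to order-of-magnitude changes (tested) |
| `μ` | 1.0e-7 | per-allele alteration rate per cell division, the simplified value derived from the germline focal copy-number rate (4.2e-5 per locus per generation over 191 spermatogenesis divisions → 2.2e-7 per locus, 1.1e-7 per allele) |
| `μ_g` | 2.0e-7 | per-gene rate used for pathway events (both alleles of one locus) |
| `δ` | `μ·N` | per-patient exit rate from the terminal state; only the terminal state's relative occupancy depends on it |
| `φ_in` | 1 | influx; cancels on normalization |
| fitness bounds | [1.0, 5.0] | per-state relative fitness box (no deleterious states, no implausibly large single-step effects), log-parameterized |
| Fisher screen | p ≤ 0.05, frequencies > 5% | uncorrected one-sided co-occurrence screen; a Bonferroni option divides the cutoff by the number of pairs |
| bootstrap | B = 10,000 (full), 1,000 (scaled-down) | multinomial patient resampling; an order is significant at ≥ 80% support |
| stability | flux ≥ 0.58 | dominant-path flux at which pairwise orders are empirically stable under addition of a third event (inclusive) |

The division-count formula for spermatogenesis, `36 + 23·(x − x_p)`,
gives 197 divisions for age 20 and puberty at 13, while the conventional
average used for the rate derivation is 191; `sperm_divisions` returns
the formula value and `cna_rate_per_division` reproduces the 2.2e-7 rate
only when given 191.  The two values are deliberately not reconciled —
callers choose which convention to feed the rate arithmetic.

## Fitting and bootstrap

Fitness values of non-origin states are the only fitted parameters
(population size, mutation rates and in/outflux are held fixed, a choice
justified by the robustness of the flux decomposition to them).  The
objective is the sum of squared differences between predicted and
observed state frequencies; a multinomial negative log-likelihood is
available behind the `objective="multinomial"` flag.  Optimization is
L-BFGS-B on log-fitness with 20 stratified random starts drawn from the
seed; ties go to the first-found optimum, making results bit-reproducible
for a fixed seed.

Bootstrap iterations resample `n` patients multinomially from the
observed state counts and refit warm-started at the full-data optimum
plus one random restart.  Warm starting keeps 1,000-iteration bootstraps
tractable on one CPU without materially changing support fractions (the
full-data multi-start already locates the global basin; each resample
perturbs it only slightly).  Support for an ordering is the fraction of
iterations in which it is dominant; displayed flux is the mean over all
iterations.  Failed refits are counted and reported, never dropped
silently.

Comparisons across data modalities (e.g. copy-number-only versus
copy-number plus point mutations) classify a pair's ordering as
consistent (same dominant order, flux moved ≤ 3 percentage points),
weakened (same dominant order but flux dropped by more than 3 points, or
fewer alleles / a lost pair), or inconsistent (dominant order changed).

## Pathway collapse

A pathway alteration event is binary and directional: a sample carries
the event if at least one member gene is altered so as to move pathway
signaling in the pathway's oncogenic direction.  Member genes carry
signed effects (a positive-effect gene raises the pathway product when
amplified; deletion reverses the sign; negative-effect genes are
mirrored).  Design choices made where the collapse rule was open:

* mixed signals within one sample (one hit up, another down) resolve to
  the oncogenic direction, with a logged warning — a single qualifying
  hit suffices, and there is no anti-oncogenic state to order;
* counter-oncogenic statuses (−1) map to level 0 in the binary event;
* point mutations default to loss of gene function (deletion-like), with
  a per-gene override set for activating oncogene mutations;
* when a pathway source lacks effect signs, the more frequent alteration
  of each gene in the cohort is assumed pro-tumorigenic
  (`infer_effect_signs`).

The shipped GBM pathway table (TP53, PIK3C1/AKT, PIK3C2, RAS, RB) is a
curator-reviewed encoding of the standard TCGA/Pathway Commons GBM
definitions, with each member's effect sign recorded explicitly.

## Subtyping

Consensus clustering: 1,000 iterations of average-linkage hierarchical
clustering on 1 − Pearson distance over 80% subsamples; consensus(i, j)
counts co-clustering among iterations co-sampling both i and j (pairs
never co-sampled get 0); final labels cluster 1 − consensus the same
way.  The number of clusters is scanned over k = 2..10 by the
area-under-CDF increment; the built-in heuristic suggests the largest k
before increments drop below 0.03 (chosen by simulation on planted-block
data so that the true k is recovered while pure noise yields no
recommendation) and abstains otherwise — the choice of k remains the
caller's.  Silhouette widths use the standard (b − a)/max(a, b)
definition on the same distance; only samples with strictly positive
widths ("core" samples) are retained for subtype-stratified ordering
runs, and singleton-cluster samples get width 0 and are excluded.

## Synthetic data

Two generator fidelities separate optimizer validation from model
validation:

* **exact steady-state sampling** — a multinomial cohort draw from the
  analytic steady-state frequencies, with the generating landscape, path
  fluxes and dominant order recorded as truth.  The default planted pair
  (`planted_pair_config`) uses fitness 1.05 for the first hit of A, 1.0
  for B and 1.1 for the double mutant at N = 100, giving an A-before-B
  flux of ≈ 0.83, and cohorts of 400 patients — scales at which a
  single-CPU bootstrap study is comfortable;
* **cell-level Moran simulation** — explicit divisions with geometric
  waiting times between arising lineages and cell-by-cell lineage
  tracking to absorption, recording each lineage's fixation or loss.
  Mutations arising during a sweep are neglected (the step-by-step
  regime the rate formulas assume).

Planted expression blocks add a block-mean shift on Gaussian noise and
median-center per gene.  What these generators deliberately do **not**
emulate: measurement noise in copy-number calling, inter-patient
variation in N or μ, overlapping pathway membership, linked loci within
one CNA, or non-block expression covariance.  Passing tests therefore
demonstrate correctness of the machinery under the model's own
assumptions, not robustness to real-data artifacts.

## Numerical notes

* `φ(r, N)` is computed via `expm1` in log space for stability near
  r = 1; ratios within 1e-12 of 1 use the exact neutral limit 1/N, and
  underflowing deleterious cases return 0.
* The steady state is solved by topological sweep — exact, with no
  iterative tolerance; flow conservation is asserted in tests at 1e-10.
* Exact ordering-flux ties break lexicographically with a logged
  warning.
* Degenerate inputs fail loudly: zero-rate networks, all-zero
  contingency tables, empty pathway lists, constant-expression samples
  and pre-puberty ages all raise with the offending item named.

## Known limitations

* Networks are limited to 2–3 events by design; the state space (and
  the cohort size needed to populate it) grows combinatorially.
* Absolute calendar time is not modeled; only rate ratios matter, so
  orders, not dates, are inferred.
* The optimizer returns a point estimate; uncertainty comes only from
  the bootstrap, not from the fit itself.
* Pathway collapse assumes the first hit in each member gene is
  independent; co-amplified neighboring genes violate this.
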