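# resic

Infer the temporal order in which genetic and pathway alterations arise
during tumorigenesis from **cross-sectional** genotype data — cohorts of
tumors sampled once, at their fully transformed stage, with no observable
precursor lesions.

`resic` is aimed at cancer genomics groups working with thresholded
copy-number call matrices (GISTIC-style, genes × samples, calls in
−2..+2), optional MAF-like mutation tables, and optional expression
matrices for molecular subtyping.

## The method

Each patient harbors `N` self-renewing cells evolving by a Moran process;
in the step-by-step regime the compartment occupies a single *mutational
state* (the tuple of hit levels across 2–3 alteration events) and moves
along a DAG of single-hit transitions at rate

    q = u · φ(r_target / r_source, N),    φ(r, N) = (1 − 1/r) / (1 − 1/r^N)

— mutation supply `u` times the Moran fixation probability `φ` of the
arising lineage (`φ(1, N) = 1/N`).  Imposing a constant influx of newly
diagnosed unmutated patients and an equal outflux from the fully mutated
state yields a steady-state distribution of patients over states, which
is fitted to the observed cohort counts by optimizing the per-state
fitness values `r`.  The origin→terminal through-flux of the fitted
network is decomposed over ordered paths; the fraction of flux in which
event A's first hit precedes event B's is the reported frequency of the
order "A before B".  Stability is assessed by a multinomial bootstrap
over patients (an order is significant at ≥ 80% support), pairwise orders
are composed into an event-order network, three-way analyses confirm or
extend it, and expression-based consensus clustering with silhouette
filtering enables subtype-stratified runs.

Around the core sit the standard pre-processing steps: pathway collapse
(directional, one qualifying hit suffices, event rate `M·μ_g` for `M`
member genes — a curator-reviewed GBM pathway table for TP53, PIK3C1/AKT,
PIK3C2, RAS and RB signaling ships with the package), and a one-sided
Fisher co-occurrence screen (p ≤ 0.05, marginal and joint alteration
frequencies > 5%).

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Generate a synthetic cohort of 400 patients from a planted fitness
landscape in which event A's first hit is advantageous (r = 1.05) and
B's is neutral, then recover the order:

```python
from resic import bootstrap_orderings, fit_fitness
from resic.simulate import planted_pair_config, sample_cohort_from_steady_state

cfg = planted_pair_config(cohort_size=400, seed=7)
cohort = sample_cohort_from_steady_state(cfg)
print("cohort state counts:", {"/".join(map(str, s)): c
                               for s, c in sorted(cohort.observed.counts.items())})

net = cfg.network()
fit = fit_fitness(net, cohort.observed, seed=7)
print("fitted fitness:", {"/".join(map(str, s)): round(v, 3)
                          for s, v in sorted(fit.landscape.r.items())})
print("ordering flux A before B: %.3f" % fit.ordering_fluxes[("A", "B")])

summary = bootstrap_orderings(net, cohort.observed, B=1000, seed=7)
print("bootstrap support A->B: %.3f (significant: %s)"
      % (summary.support[("A", "B")], summary.significant))
```

Output:

```
cohort state counts: {'0/0': 162, '0/1': 15, '1/0': 178, '1/1': 45}
fitted fitness: {'0/0': 1.0, '0/1': 1.0, '1/0': 1.041, '1/1': 1.08}
ordering flux A before B: 0.802
bootstrap support A->B: 1.000 (significant: True)
```

Read: 178 patients carry only A versus 15 carrying only B, which the
model explains by a fitness advantage of the A-first intermediate
(1.041); 80.2% of the steady-state flux takes the A-before-B path, and
that order is dominant in 100% of 1,000 bootstrap resamples — a
significant temporal sequence A → B, matching the planted truth (82.8%
true flux).

The same pipeline is scriptable from the shell:

```sh
resic simulate --cohort-size 400 --seed 7 --out sim
resic screen --matrix sim.levels.tsv --events sim.events.json --out screen.tsv
resic bootstrap --matrix sim.levels.tsv --events sim.events.json \
      --pair A --pair B -B 1000 --seed 7 --out boot.json
resic assemble boot.json --out order
resic subtype --expr sim.expression.tsv -k 4 --out subtypes.tsv
resic rates
```

`resic collapse` turns a GISTIC-style matrix (plus an optional MAF) into
pathway-event levels using the shipped or a user-supplied pathway table.

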