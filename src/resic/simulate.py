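"""Synthetic cohorts and expression matrices with known ground truth.

Two generator fidelities are provided for genotype data:

* exact steady-state sampling -- a multinomial draw of a cohort from the
  analytic steady-state patient frequencies of a configured network and
  fitness landscape (fast; exercises the fitting machinery); and
* explicit cell-level Moran simulation -- cells divide in proportion to
  fitness, a daughter replaces a uniformly chosen cell and may mutate at
  the per-division supply rate (slow; validates the fixation-probability
  and transition-rate machinery against the closed forms).

Expression matrices with planted subtype blocks (block mean shift plus
Gaussian noise, median-centered per gene) exercise consensus clustering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    FitnessLandscape,
    MutationNetwork,
    PathFlux,
    State,
    build_network,
    path_fluxes,
    pairwise_ordering_fluxes,
    steady_state,
)
from .inference import ObservedCounts, dominant_order  # noqa: F401 (re-export convenience)
from .io_model import AlterationEvent, EventKind, EventMatrix, OncogenicDirection

__all__ = [
    "ExpressionBlockSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "MoranTrajectory",
    "binary_events",
    "planted_pair_config",
    "sample_cohort_from_steady_state",
    "simulate_moran_patient",
    "moran_fixation_fraction",
    "simulate_expression_blocks",
]


@dataclass(frozen=True)
class ExpressionBlockSpec:
    """Planted-subtype expression layout: k blocks of samples, each with an
    elevated marker-gene module of strength ``effect`` over N(0, noise_sd)."""

    k: int = 4
    n_genes: int = 200
    samples_per_block: int = 30
    effect: float = 2.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_genes < self.k:
            raise ValueError("need at least one gene per block")


@dataclass
class SimulationConfig:
    """Everything needed to regenerate a synthetic study."""

    events: list[AlterationEvent]
    fitness: dict[State, float]
    N: int = 100
    mu: float = 1.0e-7
    cohort_size: int = 400
    B: int = 1000
    seed: int = 0
    allele_supply_mode: str = "remaining_alleles"
    expression: ExpressionBlockSpec | None = None

    def network(self) -> MutationNetwork:
        return build_network(
            self.events, N=self.N, mu=self.mu,
            allele_supply_mode=self.allele_supply_mode,
        )

    def landscape(self) -> FitnessLandscape:
        return FitnessLandscape(dict(self.fitness))

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "events": [
                {
                    "id": e.id, "kind": e.kind.value, "genes": list(e.genes),
                    "oncogenic_direction": e.oncogenic_direction.value,
                    "allelic_levels": e.allelic_levels,
                    "mutation_rate": e.mutation_rate,
                }
                for e in self.events
            ],
            "fitness": {"/".join(map(str, s)): r for s, r in self.fitness.items()},
            "N": self.N, "mu": self.mu, "cohort_size": self.cohort_size,
            "B": self.B, "seed": self.seed,
            "allele_supply_mode": self.allele_supply_mode,
            "expression": (
                None if self.expression is None else vars(self.expression)
            ),
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc


@dataclass
class SyntheticCohort:
    """A sampled cohort plus the generating truth."""

    config: SimulationConfig
    observed: ObservedCounts
    true_landscape: FitnessLandscape
    true_fluxes: list[PathFlux]
    true_ordering_fluxes: dict[tuple[str, str], float]
    true_dominant: tuple[tuple[str, str], ...]

    def event_matrix(self) -> EventMatrix:
        """Expand the state counts into an explicit sample-by-event matrix."""
        net = self.config.network()
        ids = net.event_ids()
        rows, names = [], []
        i = 0
        for s in net.states:
            for _ in range(self.observed.counts.get(s, 0)):
                i += 1
                names.append(f"S{i:05d}")
                rows.append(list(s))
        df = pd.DataFrame(rows, columns=ids, index=names)
        return EventMatrix(df, net.events)


def binary_events(ids: Sequence[str], M: int = 3,
                  per_gene_rate: float = 2.0e-7) -> list[AlterationEvent]:
    """Convenience: binary pathway-style events with equal rates M*mu_g."""
    return [
        AlterationEvent(
            id=i,
            kind=EventKind.pathway,
            genes=tuple(f"{i}_G{j}" for j in range(M)),
            oncogenic_direction=OncogenicDirection.gain_of_signal,
            allelic_levels=1,
            mutation_rate=M * per_gene_rate,
        )
        for i in ids
    ]


def planted_pair_config(
    r_first: float = 1.05,
    r_second: float = 1.0,
    r_both: float = 1.1,
    cohort_size: int = 400,
    N: int = 100,
    seed: int = 0,
) -> SimulationConfig:
    """Two binary events A, B with A favored first (asymmetric landscape).

    With the defaults the A-before-B path carries roughly 80% of the
    through-flux (the fixation probability of the first A hit dwarfs the
    neutral first B hit), giving a planted dominant order A -> B.
    """
    events = binary_events(["A", "B"])
    fitness = {
        (0, 0): 1.0,
        (1, 0): r_first,
        (0, 1): r_second,
        (1, 1): r_both,
    }
    return SimulationConfig(
        events=events, fitness=fitness, N=N, cohort_size=cohort_size, seed=seed
    )


def sample_cohort_from_steady_state(config: SimulationConfig) -> SyntheticCohort:
    """Multinomial cohort draw from the exact steady-state frequencies."""
    if config.cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    net = config.network()
    landscape = config.landscape()
    sol = steady_state(net, landscape)
    fluxes = path_fluxes(sol)
    ofl = pairwise_ordering_fluxes(fluxes, net)
    rng = np.random.default_rng(config.seed)
    draw = rng.multinomial(config.cohort_size, sol.freq)
    counts = {s: int(c) for s, c in zip(net.states, draw) if c > 0}
    observed = ObservedCounts(counts=counts, total=config.cohort_size)

    import itertools as _it

    ids = sorted(net.event_ids())
    dominant = []
    for a, b in _it.combinations(ids, 2):
        dominant.append((a, b) if ofl[(a, b)] >= ofl[(b, a)] else (b, a))
    return SyntheticCohort(
        config=config,
        observed=observed,
        true_landscape=landscape,
        true_fluxes=fluxes,
        true_ordering_fluxes=ofl,
        true_dominant=tuple(dominant),
    )


def moran_fixation_fraction(
    r_ratio: float, N: int, trials: int = 10000, seed: int = 0
) -> float:
    """Empirical fixation fraction of a single mutant lineage.

    Simulates the two-type Moran process division by division (divider
    chosen in proportion to fitness, daughter replaces a uniformly chosen
    cell) for ``trials`` independent lineages, vectorized across trials.
    """
    if r_ratio <= 0 or N < 1 or trials < 1:
        raise ValueError("require r_ratio > 0, N >= 1, trials >= 1")
    if N == 1:
        return 1.0
    rng = np.random.default_rng(seed)
    i = np.ones(trials, dtype=np.int64)  # mutant counts per active trial
    fixed = 0
    while i.size:
        w_mut = r_ratio * i
        p_divider_mut = w_mut / (w_mut + (N - i))
        up = rng.random(i.size) < p_divider_mut          # daughter is mutant
        down = rng.random(i.size) < i / N                # replaced cell is mutant
        i = i + up.astype(np.int64) - down.astype(np.int64)
        hit_top = i == N
        fixed += int(hit_top.sum())
        i = i[(i > 0) & ~hit_top]
    return fixed / trials


@dataclass
class MoranTrajectory:
    """Cell-level trajectory of one patient's compartment.

    ``states`` lists (division index, monomorphic state) at each sweep;
    ``lineages`` records every arising mutant lineage as
    (division index, target state, fixed?).
    """

    states: list[tuple[int, State]]
    lineages: list[tuple[int, State, bool]] = field(default_factory=list)

    @property
    def final_state(self) -> State:
        return self.states[-1][1]


def simulate_moran_patient(
    config: SimulationConfig,
    max_divisions: int = 10**12,
    seed: int | None = None,
) -> MoranTrajectory:
    """Explicit Moran simulation of one patient in the step-by-step regime.

    While the compartment is monomorphic in a state, the waiting time (in
    divisions) to the next arising mutant is geometric with the state's
    total per-division mutation supply; each arising lineage is then
    followed cell by cell until fixation or loss.  Mutations arising
    during a sweep are neglected (the step-by-step regime the rate
    formulas assume).  With mu = 0 the state never changes.
    """
    net = config.network()
    if net.N > 1000:
        raise ValueError("cell-level simulation supports N <= 1000")
    r = config.landscape().to_array(net)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    div = 0
    state = net.origin
    traj = MoranTrajectory(states=[(0, net.states[net.origin])])
    while state != net.terminal and div < max_divisions:
        out = net._out_edges[state]
        us = np.array([net.edges[j].u for j in out]) / net.N  # per-division prob
        p_total = us.sum()
        if p_total <= 0:
            break
        wait = rng.geometric(min(p_total, 1.0))
        if div + wait > max_divisions:
            div = max_divisions
            break
        div += int(wait)
        j = out[rng.choice(len(out), p=us / p_total)]
        dst = net.edges[j].dst
        ratio = r[dst] / r[state]
        # follow the arising lineage cell by cell until absorption
        i = 1
        while 0 < i < net.N:
            w_mut = ratio * i
            up = rng.random() < w_mut / (w_mut + (net.N - i))
            down = rng.random() < i / net.N
            i += int(up) - int(down)
            div += 1
        fixed = i == net.N
        traj.lineages.append((div, net.states[dst], fixed))
        if fixed:
            state = dst
            traj.states.append((div, net.states[dst]))
    return traj


def simulate_expression_blocks(
    spec: ExpressionBlockSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Block-structured expression matrix (genes x samples) plus true labels.

    Each subtype block elevates its own marker-gene module by ``effect``
    on a N(0, noise_sd) background; rows are median-centered, emulating
    preprocessed log-scale expression data.
    """
    rng = np.random.default_rng(seed)
    n_samples = spec.k * spec.samples_per_block
    genes_per_block = spec.n_genes // spec.k
    mean = np.zeros((spec.n_genes, n_samples))
    labels = np.repeat(np.arange(1, spec.k + 1), spec.samples_per_block)
    for b in range(spec.k):
        g0, g1 = b * genes_per_block, (b + 1) * genes_per_block
        cols = labels == b + 1
        mean[g0:g1, cols] = spec.effect
    noise = (
        rng.normal(0.0, spec.noise_sd, size=mean.shape)
        if spec.noise_sd > 0
        else 0.0
    )
    x = mean + noise
    x = x - np.median(x, axis=1, keepdims=True)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    expr = pd.DataFrame(x, index=genes, columns=samples)
    return expr, pd.Series(labels, index=samples, name="subtype")
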