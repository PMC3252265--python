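"""Mutational-state networks, Moran transition rates, steady-state patient
flow, and its decomposition into ordered paths.

The model
---------
Each patient harbors a compartment of N self-renewing cells evolving by a
Moran process: at each division a cell is chosen to divide in proportion to
its relative fitness r, one daughter replaces the parent and the other
replaces a uniformly chosen cell, and a daughter may acquire the next hit
of one of the events under study.  In the step-by-step regime (each
arising mutant lineage fixes or dies out before the next appears) the
patient's compartment occupies a single *mutational state* -- the tuple of
current hit levels, one per event -- and moves along the edges of a finite
DAG.  The per-division rate of the state transition along an edge is

    rate = u * phi_fix(r_target / r_source, N)

where u is the mutation supply (number of at-risk target alleles x
per-allele rate x N cells, or M*mu_g*N for a collapsed pathway event) and
phi_fix is the Moran fixation probability of a single mutant,
(1 - 1/r)/(1 - 1/r^N), with the neutral limit 1/N.

At the population-of-patients level we impose a constant influx phi of
newly diagnosed, unmutated patients and an equal outflux (rate delta per
patient) from the fully mutated state.  The resulting steady-state patient
frequencies over states are compared with observed cohort genotype counts,
and the through-flux from origin to terminal is decomposed over ordered
paths; the share of each path is the frequency of its temporal order of
events.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_model import AlterationEvent, EventKind

__all__ = [
    "State",
    "Edge",
    "MutationNetwork",
    "FitnessLandscape",
    "SteadyStateSolution",
    "PathFlux",
    "fixation_probability",
    "build_network",
    "transition_rate",
    "steady_state",
    "path_fluxes",
    "ordering_flux",
    "pairwise_ordering_fluxes",
]

State = tuple[int, ...]

DEFAULT_N = 100        # cells at risk per patient compartment
DEFAULT_MU = 1.0e-7    # per-allele alteration rate per cell division


def fixation_probability(r_ratio: float, N: int) -> float:
    """Moran fixation probability of a single mutant with relative fitness r.

    Returns (1 - 1/r) / (1 - 1/r**N); the neutral case r = 1 is the
    continuous limit 1/N.
    """
    if r_ratio <= 0:
        raise ValueError(f"fitness ratio must be positive, got {r_ratio}")
    if N < 1:
        raise ValueError(f"population size must be >= 1, got {N}")
    if N == 1:
        return 1.0
    if abs(r_ratio - 1.0) < 1e-12:
        return 1.0 / N
    inv = 1.0 / r_ratio
    denom = -math.expm1(N * math.log(inv))  # 1 - r^-N, stable for r near 1
    if math.isinf(denom) or denom == 0.0:
        # deleterious r << 1 at large N: fixation probability underflows
        return 0.0 if r_ratio < 1 else 1.0 - inv
    return (1.0 - inv) / denom


def _fixation_vec(ratios: np.ndarray, N: int) -> np.ndarray:
    """Vectorized fixation probability (used in rate computations)."""
    ratios = np.asarray(ratios, dtype=float)
    out = np.empty_like(ratios)
    neutral = np.abs(ratios - 1.0) < 1e-12
    out[neutral] = 1.0 / N
    nz = ~neutral
    if nz.any():
        inv = 1.0 / ratios[nz]
        with np.errstate(over="ignore"):
            denom = -np.expm1(N * np.log(inv))
        val = np.where(np.isinf(denom), np.where(inv > 1, 0.0, 1.0 - inv),
                       (1.0 - inv) / denom)
        out[nz] = val
    return out


@dataclass(frozen=True)
class Edge:
    """A single-hit transition: increments one event's level by 1."""

    src: int           # source state index
    dst: int           # target state index
    event_index: int   # which event is incremented
    u: float           # mutation supply (per patient per division, x N)


class MutationNetwork:
    """DAG of mutational states for 2-3 events with Moran rate machinery.

    States are all combinations of per-event levels; edges increment one
    event's level by one.  States are ordered by total hit count then
    lexicographically, which is a topological order of the DAG.
    """

    def __init__(
        self,
        events: Sequence[AlterationEvent],
        N: int = DEFAULT_N,
        mu: float = DEFAULT_MU,
        allele_supply_mode: str = "remaining_alleles",
    ):
        if not 2 <= len(events) <= 3:
            raise ValueError(
                f"networks support 2 or 3 events (state space grows "
                f"combinatorially); got {len(events)}"
            )
        if allele_supply_mode not in ("remaining_alleles", "constant"):
            raise ValueError(f"unknown allele_supply_mode {allele_supply_mode!r}")
        if N < 1 or mu < 0:
            raise ValueError("require N >= 1 and mu >= 0")
        self.events = list(events)
        self.N = int(N)
        self.mu = float(mu)
        self.allele_supply_mode = allele_supply_mode

        levels = [range(e.allelic_levels + 1) for e in self.events]
        states = sorted(itertools.product(*levels), key=lambda s: (sum(s), s))
        self.states: list[State] = states
        self.state_index: dict[State, int] = {s: i for i, s in enumerate(states)}
        self.origin = self.state_index[tuple(0 for _ in self.events)]
        self.terminal = self.state_index[
            tuple(e.allelic_levels for e in self.events)
        ]

        edges: list[Edge] = []
        for i, s in enumerate(states):
            for k, ev in enumerate(self.events):
                if s[k] < ev.allelic_levels:
                    t = list(s)
                    t[k] += 1
                    edges.append(
                        Edge(i, self.state_index[tuple(t)], k,
                             self._supply(ev, s[k]))
                    )
        self.edges = edges
        self._edge_src = np.array([e.src for e in edges], dtype=np.intp)
        self._edge_dst = np.array([e.dst for e in edges], dtype=np.intp)
        self._edge_u = np.array([e.u for e in edges], dtype=float)
        self._out_edges: list[list[int]] = [[] for _ in states]
        for j, e in enumerate(edges):
            self._out_edges[e.src].append(j)
        self._paths_cache: list[tuple[tuple[int, ...], tuple[int, ...]]] | None = None

    def _supply(self, ev: AlterationEvent, level: int) -> float:
        """Mutation supply u for the next hit of ``ev`` from ``level``."""
        if ev.kind is EventKind.pathway:
            rate = ev.mutation_rate
            if rate is None:
                rate = len(ev.genes) * 2.0 * self.mu  # M * per-gene rate
            return rate * self.N
        if ev.mutation_rate is not None and level == 0:
            return ev.mutation_rate * self.N
        if self.allele_supply_mode == "constant":
            return 2.0 * self.mu * self.N
        return (2.0 - level) * self.mu * self.N

    # -- structure ---------------------------------------------------------

    def enumerate_paths(self) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
        """All origin->terminal paths as (edge indices, event sequence)."""
        if self._paths_cache is None:
            paths = []

            def walk(state: int, eidx: list[int], seq: list[int]) -> None:
                if state == self.terminal:
                    paths.append((tuple(eidx), tuple(seq)))
                    return
                for j in self._out_edges[state]:
                    e = self.edges[j]
                    walk(e.dst, eidx + [j], seq + [e.event_index])

            walk(self.origin, [], [])
            self._paths_cache = paths
        return self._paths_cache

    def event_ids(self) -> list[str]:
        return [e.id for e in self.events]

    def rates(self, r: np.ndarray) -> np.ndarray:
        """Per-edge transition rates for a per-state fitness vector."""
        ratios = r[self._edge_dst] / r[self._edge_src]
        return self._edge_u * _fixation_vec(ratios, self.N)

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "events": [e.id for e in self.events],
            "N": self.N,
            "mu": self.mu,
            "allele_supply_mode": self.allele_supply_mode,
            "states": [list(s) for s in self.states],
            "edges": [
                {"src": list(self.states[e.src]), "dst": list(self.states[e.dst]),
                 "event": self.events[e.event_index].id, "u": e.u}
                for e in self.edges
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc


def build_network(
    events: Sequence[AlterationEvent],
    N: int = DEFAULT_N,
    mu: float = DEFAULT_MU,
    allele_supply_mode: str = "remaining_alleles",
) -> MutationNetwork:
    """Build the full mutational-state lattice for 2 or 3 events."""
    return MutationNetwork(events, N=N, mu=mu,
                           allele_supply_mode=allele_supply_mode)


@dataclass
class FitnessLandscape:
    """Relative fitness per mutational state; the origin is fixed at 1."""

    r: dict[State, float]

    def __post_init__(self) -> None:
        for s, v in self.r.items():
            if v <= 0:
                raise ValueError(f"fitness must be positive, state {s}: {v}")

    @classmethod
    def neutral(cls, network: MutationNetwork) -> "FitnessLandscape":
        return cls({s: 1.0 for s in network.states})

    @classmethod
    def from_array(
        cls, network: MutationNetwork, values: np.ndarray
    ) -> "FitnessLandscape":
        return cls({s: float(v) for s, v in zip(network.states, values)})

    def to_array(self, network: MutationNetwork) -> np.ndarray:
        arr = np.empty(len(network.states))
        for i, s in enumerate(network.states):
            arr[i] = self.r[s]
        origin = network.states[network.origin]
        if not math.isclose(self.r[origin], 1.0, rel_tol=1e-9):
            raise ValueError("origin fitness must be 1")
        return arr


@dataclass
class SteadyStateSolution:
    """Steady-state patient distribution and edge fluxes on a network."""

    network: MutationNetwork
    freq: np.ndarray          # normalized patient frequency per state
    occupancy: np.ndarray     # unnormalized occupancy (phi x mean dwell)
    rates: np.ndarray         # per-edge transition rates
    edge_flux: np.ndarray     # rate x occupancy per edge
    influx: float             # phi into the origin state
    outflux_rate: float       # delta, per-patient exit rate from terminal

    @property
    def freq_by_state(self) -> dict[State, float]:
        return dict(zip(self.network.states, map(float, self.freq)))

    def balance_residual(self) -> float:
        """Max |inflow - outflow| over states (0 at exact steady state)."""
        net = self.network
        inflow = np.zeros(len(net.states))
        outflow = np.zeros(len(net.states))
        np.add.at(inflow, net._edge_dst, self.edge_flux)
        np.add.at(outflow, net._edge_src, self.edge_flux)
        inflow[net.origin] += self.influx
        outflow[net.terminal] += self.outflux_rate * self.occupancy[net.terminal]
        return float(np.max(np.abs(inflow - outflow)))


def _occupancies(
    network: MutationNetwork, rates: np.ndarray, phi: float, delta: float
) -> np.ndarray:
    """Exact steady-state occupancies by a topological sweep.

    The balance system (inflow = outflow at every state, phi injected at
    the origin, delta per patient removed at the terminal) is triangular in
    any topological order of the DAG, so it is solved state by state.
    """
    n = len(network.states)
    inflow = np.zeros(n)
    x = np.zeros(n)
    inflow[network.origin] = phi
    for i in range(n):  # states are stored in topological order
        if i == network.terminal:
            x[i] = inflow[i] / delta
            continue
        out = network._out_edges[i]
        total = 0.0
        for j in out:
            total += rates[j]
        xi = inflow[i] / total
        x[i] = xi
        for j in out:
            inflow[network._edge_dst[j]] += rates[j] * xi
    return x


def steady_state(
    network: MutationNetwork,
    landscape: FitnessLandscape | np.ndarray,
    influx: float = 1.0,
    delta: float | None = None,
) -> SteadyStateSolution:
    """Solve the patient-population steady state.

    ``influx`` (phi) only scales occupancies and cancels on normalization;
    ``delta`` defaults to mu*N, the scale of the slowest transitions, and
    only affects the relative occupancy of the terminal state.
    """
    r = (
        landscape.to_array(network)
        if isinstance(landscape, FitnessLandscape)
        else np.asarray(landscape, dtype=float)
    )
    if delta is None:
        delta = network.mu * network.N
    if influx <= 0 or delta <= 0:
        raise ValueError("influx and delta must be positive")
    rates = network.rates(r)
    if not np.all(np.isfinite(rates)) or np.any(rates <= 0):
        raise ValueError("transition rates must be finite and positive")
    x = _occupancies(network, rates, influx, delta)
    total = x.sum()
    return SteadyStateSolution(
        network=network,
        freq=x / total,
        occupancy=x,
        rates=rates,
        edge_flux=rates * x[network._edge_src],
        influx=influx,
        outflux_rate=delta,
    )


@dataclass(frozen=True)
class PathFlux:
    """One origin->terminal path and its share of the through-flux."""

    edge_indices: tuple[int, ...]
    event_sequence: tuple[int, ...]   # event index incremented at each step
    event_ids: tuple[str, ...]
    probability: float


def path_fluxes(
    solution: SteadyStateSolution, network: MutationNetwork | None = None
) -> list[PathFlux]:
    """Decompose the origin->terminal through-flux over ordered paths.

    Each path's probability is the product over its edges of the edge's
    share of its source state's total outflow; probabilities sum to 1.
    """
    net = network or solution.network
    out_total = np.zeros(len(net.states))
    np.add.at(out_total, net._edge_src, solution.edge_flux)
    probs = solution.edge_flux / out_total[net._edge_src]
    fluxes = []
    for eidx, seq in net.enumerate_paths():
        p = 1.0
        for j in eidx:
            p *= probs[j]
        fluxes.append(
            PathFlux(
                edge_indices=eidx,
                event_sequence=seq,
                event_ids=tuple(net.events[k].id for k in seq),
                probability=float(p),
            )
        )
    return fluxes


def ordering_flux(
    fluxes: Iterable[PathFlux],
    network: MutationNetwork,
    event_a: str,
    event_b: str,
) -> float:
    """Fraction of through-flux in which event_a's first hit precedes event_b's.

    ordering_flux(a, b) + ordering_flux(b, a) = 1: transitions are single
    hits, so no path increments two events simultaneously.
    """
    ids = network.event_ids()
    try:
        ia, ib = ids.index(event_a), ids.index(event_b)
    except ValueError as err:
        raise ValueError(f"event not in network: {err}") from None
    total = 0.0
    for pf in fluxes:
        if pf.event_sequence.index(ia) < pf.event_sequence.index(ib):
            total += pf.probability
    return total


def pairwise_ordering_fluxes(
    fluxes: list[PathFlux], network: MutationNetwork
) -> dict[tuple[str, str], float]:
    """Ordering flux for every ordered pair of events in the network."""
    ids = network.event_ids()
    out = {}
    for a, b in itertools.permutations(ids, 2):
        out[(a, b)] = ordering_flux(fluxes, network, a, b)
    return out


def solution_to_json(
    solution: SteadyStateSolution, path: str | Path | None = None
) -> dict:
    net = solution.network
    fluxes = path_fluxes(solution)
    doc = {
        "freq": {"/".join(map(str, s)): f
                 for s, f in solution.freq_by_state.items()},
        "influx": solution.influx,
        "outflux_rate": solution.outflux_rate,
        "edge_flux": [
            {"src": list(net.states[e.src]), "dst": list(net.states[e.dst]),
             "flux": float(fl)}
            for e, fl in zip(net.edges, solution.edge_flux)
        ],
        "path_fluxes": [
            {"order": list(pf.event_ids), "probability": pf.probability}
            for pf in fluxes
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def network_to_dot(
    network: MutationNetwork,
    solution: SteadyStateSolution | None = None,
) -> str:
    """Graphviz DOT rendering of the state network (optionally with fluxes)."""
    lines = ["digraph mutational_network {", "  rankdir=LR;"]
    for i, s in enumerate(network.states):
        label = ",".join(map(str, s))
        extra = ""
        if solution is not None:
            extra = f"\\nfreq={solution.freq[i]:.3g}"
        lines.append(f'  s{i} [label="{label}{extra}"];')
    for j, e in enumerate(network.edges):
        label = network.events[e.event_index].id
        if solution is not None:
            label += f" ({solution.edge_flux[j]:.3g})"
        lines.append(f'  s{e.src} -> s{e.dst} [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)


def transition_rate(
    edge: Edge,
    landscape: FitnessLandscape,
    network: MutationNetwork,
) -> float:
    """Rate of one state transition: mutation supply x fixation probability."""
    r = landscape.to_array(network)
    ratio = r[edge.dst] / r[edge.src]
    return edge.u * fixation_probability(ratio, network.N)
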