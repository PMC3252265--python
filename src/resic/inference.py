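"""Fitting fitness landscapes to observed genotype counts and bootstrapping
the dominant temporal sequence.

The observed data are cross-sectional: counts of patients in each
mutational state at diagnosis.  The fitted quantities are the relative
fitness values of the non-origin states, chosen to minimize the distance
between the model's steady-state patient frequencies and the observed
frequencies.  Ordering statements are then read off the fitted network as
ordering fluxes, and their stability is assessed by a multinomial
bootstrap over patients: an ordering is called significant when it is the
dominant sequence in at least 80% of bootstrap refits.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .core import (
    FitnessLandscape,
    MutationNetwork,
    PathFlux,
    SteadyStateSolution,
    State,
    _occupancies,
    path_fluxes,
    pairwise_ordering_fluxes,
    steady_state,
)
from .io_model import EventMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ObservedCounts",
    "FitResult",
    "BootstrapSummary",
    "Consistency",
    "OrderingComparison",
    "fit_fitness",
    "bootstrap_orderings",
    "dominant_order",
    "compare_orderings",
    "counts_from_matrix",
]

SUPPORT_THRESHOLD = 0.80   # bootstrap support needed to call an order significant
DEFAULT_BOUNDS = (1.0, 5.0)


@dataclass(frozen=True)
class ObservedCounts:
    """Patient counts per mutational state of a network."""

    counts: dict[State, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of state counts")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.total <= 0:
            raise ValueError("need at least one patient")

    def frequencies(self, network: MutationNetwork) -> np.ndarray:
        unknown = set(self.counts) - set(network.states)
        if unknown:
            raise ValueError(f"counts for states not in network: {unknown}")
        arr = np.array(
            [self.counts.get(s, 0) for s in network.states], dtype=float
        )
        return arr / self.total


def counts_from_matrix(
    matrix: EventMatrix, network: MutationNetwork
) -> ObservedCounts:
    """Tabulate cohort samples into network-state counts."""
    ids = network.event_ids()
    sub = matrix.levels[ids].to_numpy()
    counts: dict[State, int] = {}
    for row in sub:
        s = tuple(int(v) for v in row)
        if s not in network.state_index:
            raise ValueError(f"sample level combination {s} not a network state")
        counts[s] = counts.get(s, 0) + 1
    return ObservedCounts(counts=counts, total=int(sub.shape[0]))


@dataclass
class FitResult:
    """Best fitted landscape with its steady state and flux decomposition."""

    landscape: FitnessLandscape
    objective: float
    predicted: np.ndarray
    solution: SteadyStateSolution
    fluxes: list[PathFlux]
    ordering_fluxes: dict[tuple[str, str], float]
    dominant: tuple[tuple[str, str], ...]
    n_starts: int
    n_converged: int


class _Problem:
    """Precompiled objective over log-fitness of non-origin states."""

    def __init__(
        self,
        network: MutationNetwork,
        obs_freq: np.ndarray,
        influx: float,
        delta: float,
        objective: str,
    ):
        self.net = network
        self.obs = obs_freq
        self.influx = influx
        self.delta = delta
        n = len(network.states)
        self.free = np.array(
            [i for i in range(n) if i != network.origin], dtype=np.intp
        )
        self.n = n
        if objective not in ("least_squares", "multinomial"):
            raise ValueError(f"unknown objective {objective!r}")
        self.kind = objective

    def r_full(self, theta: np.ndarray) -> np.ndarray:
        r = np.ones(self.n)
        r[self.free] = np.exp(theta)
        return r

    def __call__(self, theta: np.ndarray) -> float:
        r = self.r_full(theta)
        rates = self.net.rates(r)
        x = _occupancies(self.net, rates, self.influx, self.delta)
        f = x / x.sum()
        if self.kind == "least_squares":
            d = f - self.obs
            return float(d @ d)
        # multinomial negative log-likelihood (up to a constant)
        mask = self.obs > 0
        return float(-(self.obs[mask] * np.log(f[mask])).sum())


def fit_fitness(
    network: MutationNetwork,
    observed: ObservedCounts,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    n_starts: int = 20,
    seed: int = 0,
    influx: float = 1.0,
    delta: float | None = None,
    objective: str = "least_squares",
    warm_starts: Sequence[np.ndarray] = (),
) -> FitResult:
    """Fit per-state fitness values to observed state counts.

    Runs ``n_starts`` bounded local optimizations (L-BFGS-B on
    log-fitness) from stratified random initial landscapes drawn from
    ``seed``, plus any ``warm_starts`` (log-fitness vectors over non-origin
    states).  The objective is the sum of squared differences between
    predicted and observed state frequencies ("least_squares", default) or
    a multinomial negative log-likelihood ("multinomial").  Deterministic
    given the seed; the best objective wins, ties going to the first found.
    """
    lo, hi = bounds
    if not (0 < lo <= hi):
        raise ValueError(f"bounds must satisfy 0 < lo <= hi, got {bounds}")
    if delta is None:
        delta = network.mu * network.N
    obs_freq = observed.frequencies(network)
    prob = _Problem(network, obs_freq, influx, delta, objective)
    k = len(prob.free)
    log_lo, log_hi = np.log(lo), np.log(hi)
    box = [(log_lo, log_hi)] * k

    rng = np.random.default_rng(seed)
    starts = [np.asarray(w, dtype=float) for w in warm_starts]
    if n_starts > 0:
        # stratified (latin-hypercube style) starts across the log-box
        strata = (np.arange(n_starts)[:, None] + rng.random((n_starts, k))) / n_starts
        for col in range(k):
            rng.shuffle(strata[:, col])
        starts.extend(log_lo + strata * (log_hi - log_lo))
    if not starts:
        raise ValueError("need n_starts > 0 or at least one warm start")

    best = None
    n_conv = 0
    for x0 in starts:
        res = optimize.minimize(
            prob, np.clip(x0, log_lo, log_hi), method="L-BFGS-B", bounds=box
        )
        if not np.isfinite(res.fun):
            continue
        n_conv += int(bool(res.success))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or n_conv == 0:
        raise RuntimeError(
            f"optimizer failed to converge on all {len(starts)} starts "
            f"(last status: {res.message if starts else 'n/a'})"
        )

    r = prob.r_full(best.x)
    landscape = FitnessLandscape.from_array(network, r)
    solution = steady_state(network, r, influx=influx, delta=delta)
    fluxes = path_fluxes(solution)
    ofl = pairwise_ordering_fluxes(fluxes, network)
    fit = FitResult(
        landscape=landscape,
        objective=float(best.fun),
        predicted=solution.freq,
        solution=solution,
        fluxes=fluxes,
        ordering_fluxes=ofl,
        dominant=(),
        n_starts=len(starts),
        n_converged=n_conv,
    )
    fit.dominant = dominant_order(fit)
    return fit


def dominant_order(fit: FitResult) -> tuple[tuple[str, str], ...]:
    """The pairwise first-hit precedence relations with maximal flux.

    For every unordered event pair the direction with the larger ordering
    flux is returned as (earlier, later); exact ties break lexicographically
    with a logged warning.
    """
    ids = sorted({e for pair in fit.ordering_fluxes for e in pair})
    relations = []
    for a, b in itertools.combinations(ids, 2):
        fab = fit.ordering_fluxes[(a, b)]
        fba = fit.ordering_fluxes[(b, a)]
        if fab == fba:
            log.warning("ordering flux tie for (%s, %s); lexicographic break", a, b)
            relations.append((a, b))
        else:
            relations.append((a, b) if fab > fba else (b, a))
    return tuple(relations)


@dataclass
class BootstrapSummary:
    """Dominant-order support and mean fluxes across bootstrap resamples.

    ``support[(a, b)]`` is the fraction of iterations in which a-before-b
    was the dominant direction for that pair; ``mean_flux[(a, b)]`` is the
    ordering flux averaged over all (successful) iterations.  An ordering
    is significant when its support reaches 80%.
    """

    events: tuple[str, ...]
    B: int
    seed: int
    support: dict[tuple[str, str], float]
    mean_flux: dict[tuple[str, str], float]
    n_failed: int = 0

    @property
    def significant(self) -> bool:
        return max(self.support.values()) >= SUPPORT_THRESHOLD

    def dominant_ordering(self, a: str, b: str) -> tuple[str, str]:
        """Direction with larger support for the unordered pair {a, b}."""
        return (a, b) if self.support[(a, b)] >= self.support[(b, a)] else (b, a)

    def pair_significant(self, a: str, b: str) -> bool:
        return max(self.support[(a, b)], self.support[(b, a)]) >= SUPPORT_THRESHOLD

    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(sorted(self.events), 2))

    def dominant_mean_flux(self, a: str, b: str) -> float:
        d = self.dominant_ordering(a, b)
        return self.mean_flux[d]


def bootstrap_orderings(
    network: MutationNetwork,
    observed: ObservedCounts,
    B: int = 1000,
    seed: int = 0,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    base_n_starts: int = 20,
    refit_n_starts: int = 2,
    influx: float = 1.0,
    delta: float | None = None,
    objective: str = "least_squares",
) -> BootstrapSummary:
    """Multinomial bootstrap of the dominant temporal sequence.

    Each iteration resamples ``observed.total`` patients with replacement
    from the observed state counts, refits the fitness landscape (warm
    started at the full-data fit plus ``refit_n_starts - 1`` random
    restarts), and records each pair's dominant direction and ordering
    flux.  Failed refits are counted in ``n_failed``, never silently
    dropped.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    base = fit_fitness(
        network, observed, bounds=bounds, n_starts=base_n_starts,
        seed=int(rng.integers(2**31)), influx=influx, delta=delta,
        objective=objective,
    )
    warm = np.log(base.landscape.to_array(network)[
        [i for i in range(len(network.states)) if i != network.origin]
    ])
    probs = observed.frequencies(network)
    ids = sorted(network.event_ids())
    pairs = list(itertools.permutations(ids, 2))
    n_dom = {p: 0 for p in pairs}
    flux_sum = {p: 0.0 for p in pairs}
    n_failed = 0
    for _ in range(B):
        draw = rng.multinomial(observed.total, probs)
        counts = {
            s: int(c) for s, c in zip(network.states, draw) if c > 0
        }
        boot = ObservedCounts(counts=counts, total=observed.total)
        try:
            fit = fit_fitness(
                network, boot, bounds=bounds,
                n_starts=max(refit_n_starts - 1, 0),
                seed=int(rng.integers(2**31)),
                influx=influx, delta=delta, objective=objective,
                warm_starts=[warm],
            )
        except RuntimeError:
            n_failed += 1
            continue
        for a, b in itertools.combinations(ids, 2):
            fab = fit.ordering_fluxes[(a, b)]
            flux_sum[(a, b)] += fab
            flux_sum[(b, a)] += 1.0 - fab
            dom = (a, b) if fab >= 0.5 else (b, a)
            n_dom[dom] += 1
    n_ok = B - n_failed
    if n_failed:
        log.warning("bootstrap: %d/%d refits failed", n_failed, B)
    return BootstrapSummary(
        events=tuple(ids),
        B=B,
        seed=seed,
        support={p: n_dom[p] / B for p in pairs},
        mean_flux={p: (flux_sum[p] / n_ok if n_ok else float("nan"))
                   for p in pairs},
        n_failed=n_failed,
    )


class Consistency(str, enum.Enum):
    consistent = "consistent"
    weakened = "weakened"
    inconsistent = "inconsistent"


@dataclass(frozen=True)
class OrderingComparison:
    """Comparison of one event pair's ordering across two data modalities."""

    classification: Consistency
    flux_delta: float          # percentage points, for the reference dominant order
    dominant_changed: bool


def compare_orderings(
    a: BootstrapSummary,
    b: BootstrapSummary,
    fewer_alleles: bool = False,
    pair_lost: bool = False,
) -> OrderingComparison:
    """Classify agreement of a pair's ordering between two analyses.

    The order is consistent when the dominant sequence is unchanged and
    the percent flux moved by no more than three points; it is weakened if
    the dominant sequence held but the flux dropped by more than three
    points (or fewer alleles / a lost pair are flagged by the caller), and
    inconsistent if the dominant order changed.
    """
    if set(a.events) != set(b.events) or len(a.events) != 2:
        raise ValueError("comparisons require two summaries of the same pair")
    ea, eb = sorted(a.events)
    dom_a = a.dominant_ordering(ea, eb)
    dom_b = b.dominant_ordering(ea, eb)
    delta = abs(a.mean_flux[dom_a] - b.mean_flux[dom_a]) * 100.0
    changed = dom_a != dom_b
    if changed:
        cls = Consistency.inconsistent
    elif delta > 3.0 or fewer_alleles or pair_lost:
        cls = Consistency.weakened
    else:
        cls = Consistency.consistent
    return OrderingComparison(
        classification=cls, flux_delta=delta, dominant_changed=changed
    )
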