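"""Combine pairwise ordering results into an event-order network and
overlay three-way analyses for stability annotation.

Pairwise analyses yield directed earlier->later relations; composing them
transitively yields chains (A before B and C before A gives C->A->B).
Three-way analyses re-test each pair in the presence of a third event:
pairwise edges re-confirmed there are stable, orderings appearing only in
triples are annotated separately ("gold" edges), and any reversal is
surfaced as an explicit conflict rather than resolved automatically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .inference import BootstrapSummary, SUPPORT_THRESHOLD

__all__ = [
    "OrderGraph",
    "assemble_pairwise",
    "overlay_threeway",
    "stability_flag",
    "STABILITY_FLUX_THRESHOLD",
]

#: Minimum dominant-path flux for an ordering to be expected stable under
#: the addition of further events (inclusive).
STABILITY_FLUX_THRESHOLD = 0.58


@dataclass
class OrderGraph:
    """Directed earlier->later event graph with provenance annotations."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    conflicts: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def cycles(self) -> list[list[str]]:
        """All simple cycles (contradictory ordering evidence)."""
        return sorted(nx.simple_cycles(self.graph))

    def chains(self) -> list[list[str]]:
        """Maximal linear chains by transitive composition of edges.

        Only meaningful when the graph is acyclic; on cyclic graphs an
        empty list is returned (the cycles are reported separately).
        """
        if not nx.is_directed_acyclic_graph(self.graph):
            return []
        roots = [n for n in self.graph if self.graph.in_degree(n) == 0]
        chains = []

        def walk(node: str, acc: list[str]) -> None:
            succ = sorted(self.graph.successors(node))
            if not succ:
                if len(acc) > 1:
                    chains.append(acc)
                return
            for s in succ:
                walk(s, acc + [s])

        for r in sorted(roots):
            walk(r, [r])
        return chains

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "nodes": self.nodes,
            "edges": [
                {"from": u, "to": v, **self.graph.edges[u, v]}
                for u, v in self.edges
            ],
            "conflicts": [
                {"edge": list(e), "reason": r} for e, r in self.conflicts
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc

    @classmethod
    def from_json(cls, doc: dict | str | Path) -> "OrderGraph":
        if not isinstance(doc, dict):
            doc = json.loads(Path(doc).read_text())
        g = nx.DiGraph()
        g.add_nodes_from(doc["nodes"])
        for e in doc["edges"]:
            attrs = {k: v for k, v in e.items() if k not in ("from", "to")}
            g.add_edge(e["from"], e["to"], **attrs)
        og = cls(graph=g)
        og.conflicts = [
            (tuple(c["edge"]), c["reason"]) for c in doc.get("conflicts", [])
        ]
        return og

    def to_dot(self) -> str:
        """DOT export; pairwise-significant edges black, triple-only gold,
        line weight the number of confirming three-way analyses."""
        lines = ["digraph event_order {", "  rankdir=LR;"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for u, v in self.edges:
            d = self.graph.edges[u, v]
            color = "gold" if d.get("provenance") == "threeway_only" else "black"
            penwidth = 1 + d.get("n_confirming_triples", 0)
            label = f"{d.get('mean_flux', float('nan')) * 100:.1f}%"
            lines.append(
                f'  "{u}" -> "{v}" [color={color}, penwidth={penwidth}, '
                f'label="{label}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def assemble_pairwise(summaries: Iterable[BootstrapSummary]) -> OrderGraph:
    """Build the order graph from significant pairwise bootstrap summaries.

    One edge per significant pair, in its dominant direction.  Chains
    follow by transitive composition (see :meth:`OrderGraph.chains`);
    cycles are detected and reported, never silently broken.
    """
    g = nx.DiGraph()
    for s in summaries:
        if len(s.events) != 2:
            raise ValueError("assemble_pairwise expects two-event summaries")
        a, b = sorted(s.events)
        if not s.pair_significant(a, b):
            raise ValueError(
                f"pair ({a}, {b}) not significant (support < "
                f"{SUPPORT_THRESHOLD:.0%}); filter before assembly"
            )
        u, v = s.dominant_ordering(a, b)
        g.add_edge(
            u, v,
            support=max(s.support[(u, v)], 0.0),
            mean_flux=s.mean_flux[(u, v)],
            provenance="pairwise",
            n_confirming_triples=0,
        )
    og = OrderGraph(graph=g)
    for cyc in og.cycles():
        og.conflicts.append((tuple(cyc[:2]), f"cycle: {'->'.join(cyc + cyc[:1])}"))
    return og


def overlay_threeway(
    graph: OrderGraph, threeway_results: Iterable[BootstrapSummary]
) -> OrderGraph:
    """Overlay three-event bootstrap summaries onto a pairwise order graph.

    For each pair significant within a triple: an existing same-direction
    pairwise edge gains a confirmation (edge weight = number of confirming
    triples); a new ordering is added flagged "threeway_only"; a reversal
    of an existing edge is recorded as a conflict.
    """
    g = graph.graph
    for s in threeway_results:
        if len(s.events) != 3:
            raise ValueError("overlay_threeway expects three-event summaries")
        for a, b in s.pairs():
            if not s.pair_significant(a, b):
                continue
            u, v = s.dominant_ordering(a, b)
            if g.has_edge(u, v):
                d = g.edges[u, v]
                d["n_confirming_triples"] = d.get("n_confirming_triples", 0) + 1
                if d.get("provenance") == "pairwise":
                    d["provenance"] = "threeway_confirmed"
            elif g.has_edge(v, u):
                graph.conflicts.append(
                    ((v, u), f"three-way analysis of {s.events} reverses "
                             f"pairwise edge {v}->{u}")
                )
            else:
                g.add_edge(
                    u, v,
                    support=s.support[(u, v)],
                    mean_flux=s.mean_flux[(u, v)],
                    provenance="threeway_only",
                    n_confirming_triples=1,
                )
    return graph


def stability_flag(
    summary: BootstrapSummary, threshold: float = STABILITY_FLUX_THRESHOLD
) -> bool:
    """Whether the dominant path's mean flux reaches the stability threshold.

    Orderings whose most likely path carries at least 58% of the
    through-flux are empirically stable when further events are added to
    the analysis; the threshold is inclusive.
    """
    a, b = sorted(summary.events)[:2]
    best = max(
        summary.dominant_mean_flux(x, y) for x, y in summary.pairs()
    ) if len(summary.events) > 2 else summary.dominant_mean_flux(a, b)
    return best >= threshold
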