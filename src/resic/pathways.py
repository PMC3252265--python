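"""Collapse gene-level alterations into directional pathway alteration events.

A pathway alteration event is binary: a sample carries the event if at
least one member gene is altered in a way that moves pathway signaling in
the pathway's oncogenic direction (e.g. "TP53 inactivation" via MDM2/4
amplification or TP53/CDKN2A deletion).  Because the member genes sit on
different loci, first hits are treated as independent and the collapsed
event mutates at rate M*mu_g, with M the member count and mu_g the per-gene
rate per cell division.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_model import (
    AlterationEvent,
    EventKind,
    EventMatrix,
    OncogenicDirection,
    SampleGenotype,
)

log = logging.getLogger(__name__)

__all__ = [
    "Effect",
    "GeneCall",
    "SignalChange",
    "PathwayDefinition",
    "PathwayStatus",
    "load_gbm_pathways",
    "read_pathway_table",
    "gene_call_effect",
    "collapse_sample",
    "pathway_event_matrix",
    "infer_effect_signs",
]

#: Per-gene mutation rate per cell division used for pathway events
#: (both alleles of one locus, i.e. twice the per-allele rate of 1.0e-7).
DEFAULT_PER_GENE_RATE = 2.0e-7


class Effect(str, enum.Enum):
    """Sign of a member gene's contribution to the pathway product."""

    positive = "+"
    negative = "-"


class GeneCall(str, enum.Enum):
    amplified = "amplified"
    deleted = "deleted"
    point_mutated = "point_mutated"


class SignalChange(str, enum.Enum):
    up = "up"
    down = "down"
    none = "none"


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway with signed member genes and an oncogenic direction.

    ``members`` maps gene symbol -> Effect.  A positive-effect gene
    increases production of the pathway's signaling product when amplified;
    deletion has the reverse effect; negative-effect genes are mirrored.
    ``oncogenic_direction`` is "activation" (signaling up promotes the
    tumor) or "inactivation" (signaling down promotes it).
    """

    name: str
    members: tuple[tuple[str, Effect], ...]
    oncogenic_direction: str  # "activation" | "inactivation"

    def __post_init__(self) -> None:
        if self.oncogenic_direction not in ("activation", "inactivation"):
            raise ValueError(
                f"pathway {self.name!r}: bad direction {self.oncogenic_direction!r}"
            )
        genes = [g for g, _ in self.members]
        if not genes:
            raise ValueError(f"pathway {self.name!r}: empty member list")
        if len(set(genes)) != len(genes):
            raise ValueError(f"pathway {self.name!r}: duplicate member genes")

    @property
    def M(self) -> int:
        """Member gene count (the mutation-rate multiplier)."""
        return len(self.members)

    @property
    def gene_effects(self) -> dict[str, Effect]:
        return dict(self.members)

    @property
    def oncogenic_change(self) -> SignalChange:
        return (
            SignalChange.up
            if self.oncogenic_direction == "activation"
            else SignalChange.down
        )


@dataclass(frozen=True)
class PathwayStatus:
    sample_id: str
    pathway: str
    status: int  # +1 oncogenic-direction alteration, -1 opposite, 0 neutral

    def __post_init__(self) -> None:
        if self.status not in (-1, 0, 1):
            raise ValueError(f"status must be -1/0/+1, got {self.status}")


def read_pathway_table(path: str | Path) -> list[PathwayDefinition]:
    """Read a pathway table (TSV columns: pathway, gene, effect, oncogenic_direction)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("pathway", "gene", "effect", "oncogenic_direction"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for name, grp in df.groupby("pathway", sort=True):
        directions = set(grp["oncogenic_direction"])
        if len(directions) != 1:
            raise ValueError(f"pathway {name!r}: inconsistent oncogenic_direction")
        members = tuple(
            (g, Effect(e)) for g, e in zip(grp["gene"], grp["effect"])
        )
        out.append(
            PathwayDefinition(
                name=str(name),
                members=members,
                oncogenic_direction=directions.pop(),
            )
        )
    return out


def load_gbm_pathways() -> list[PathwayDefinition]:
    """Load the shipped, curator-reviewed GBM pathway definitions
    (TP53, PIK3C1/AKT, PIK3C2, RAS, RB)."""
    with resources.as_file(
        resources.files("resic.data").joinpath("gbm_pathways.tsv")
    ) as p:
        return read_pathway_table(p)


def gene_call_effect(
    gene: str, call: GeneCall, pathway: PathwayDefinition,
    point_mutation_gain: frozenset[str] | set[str] = frozenset(),
) -> SignalChange:
    """Signaling change of the pathway product caused by one gene call.

    Positive-effect gene: amplified -> up, deleted -> down; negative-effect
    gene mirrored.  Point mutations default to loss of gene function (same
    change as deletion); genes listed in ``point_mutation_gain`` (activating
    oncogene mutations) behave like amplification instead.
    """
    call = GeneCall(call)
    eff = pathway.gene_effects.get(gene)
    if eff is None:
        return SignalChange.none
    if call is GeneCall.point_mutated:
        call = (
            GeneCall.amplified if gene in point_mutation_gain else GeneCall.deleted
        )
    up = (eff is Effect.positive) == (call is GeneCall.amplified)
    return SignalChange.up if up else SignalChange.down


def _sample_calls(
    sample: SampleGenotype, mutations: Mapping[str, set[str]] | None
) -> list[tuple[str, GeneCall]]:
    calls = []
    for gene, c in sample.cna_call.items():
        if c > 0:
            calls.append((gene, GeneCall.amplified))
        elif c < 0:
            calls.append((gene, GeneCall.deleted))
    mutated = set()
    if mutations is not None:
        mutated |= mutations.get(sample.sample_id, set())
    mutated |= {g for g, m in sample.point_mutated.items() if m}
    for gene in sorted(mutated):
        calls.append((gene, GeneCall.point_mutated))
    return calls


def collapse_sample(
    sample: SampleGenotype,
    pathway: PathwayDefinition,
    mutations: Mapping[str, set[str]] | None = None,
    point_mutation_gain: frozenset[str] | set[str] = frozenset(),
) -> PathwayStatus:
    """Collapse one sample's gene calls into a pathway alteration status.

    A single qualifying hit suffices.  Status is +1 if any member
    alteration moves signaling in the oncogenic direction (oncogenic hits
    dominate mixed signals, with a logged warning), -1 if hits exist but
    all move signaling the other way, 0 if no member is altered.
    """
    onco = pathway.oncogenic_change
    n_with = n_against = 0
    for gene, call in _sample_calls(sample, mutations):
        change = gene_call_effect(gene, call, pathway, point_mutation_gain)
        if change is SignalChange.none:
            continue
        if change is onco:
            n_with += 1
        else:
            n_against += 1
    if n_with and n_against:
        log.warning(
            "sample %s: mixed signals in pathway %s (%d oncogenic, %d opposite); "
            "oncogenic direction dominates",
            sample.sample_id, pathway.name, n_with, n_against,
        )
    if n_with:
        status = 1
    elif n_against:
        status = -1
    else:
        status = 0
    return PathwayStatus(sample.sample_id, pathway.name, status)


def pathway_event_matrix(
    samples: Iterable[SampleGenotype],
    pathways: Sequence[PathwayDefinition],
    per_gene_rate: float = DEFAULT_PER_GENE_RATE,
    mutations: Mapping[str, set[str]] | None = None,
    point_mutation_gain: frozenset[str] | set[str] = frozenset(),
) -> EventMatrix:
    """Binary EventMatrix of pathway events, each annotated with rate M*mu_g.

    Level 1 iff the sample's status matches the oncogenic direction;
    counter-oncogenic (-1) statuses map to level 0 because the ordered
    events are accumulations in the oncogenic direction.
    """
    if per_gene_rate <= 0:
        raise ValueError("per_gene_rate must be positive")
    pathways = list(pathways)
    if not pathways:
        raise ValueError("empty pathway list")
    samples = list(samples)
    events = [
        AlterationEvent(
            id=p.name,
            kind=EventKind.pathway,
            genes=tuple(g for g, _ in p.members),
            oncogenic_direction=(
                OncogenicDirection.gain_of_signal
                if p.oncogenic_direction == "activation"
                else OncogenicDirection.loss_of_signal
            ),
            allelic_levels=1,
            mutation_rate=p.M * per_gene_rate,
        )
        for p in pathways
    ]
    data = {}
    for p in pathways:
        col = [
            1
            if collapse_sample(s, p, mutations, point_mutation_gain).status == 1
            else 0
            for s in samples
        ]
        data[p.name] = col
    df = pd.DataFrame(data, index=[s.sample_id for s in samples])
    return EventMatrix(df, events)


def infer_effect_signs(
    genotypes: Iterable[SampleGenotype],
    members: Sequence[str],
    name: str,
    oncogenic_direction: str,
) -> PathwayDefinition:
    """Build a PathwayDefinition when no effect signs are available.

    Fallback for undirected pathway sources: the more frequent alteration
    of each gene across the cohort (amplification vs deletion) is assumed
    pro-tumorigenic, and the effect sign is set so that this alteration
    moves signaling in the oncogenic direction.  Ties default to
    amplification-as-oncogenic.
    """
    genotypes = list(genotypes)
    members_signed = []
    for gene in members:
        n_amp = sum(1 for g in genotypes if g.cna_call.get(gene, 0) > 0)
        n_del = sum(1 for g in genotypes if g.cna_call.get(gene, 0) < 0)
        amp_is_onco = n_amp >= n_del
        if oncogenic_direction == "activation":
            eff = Effect.positive if amp_is_onco else Effect.negative
        else:
            eff = Effect.negative if amp_is_onco else Effect.positive
        members_signed.append((gene, eff))
    return PathwayDefinition(
        name=name,
        members=tuple(members_signed),
        oncogenic_direction=oncogenic_direction,
    )
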