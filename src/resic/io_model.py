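"""Domain types, file readers/writers, and copy-number mutation-rate arithmetic.

Input conventions follow the common post-processing formats of tumor
copy-number pipelines: a GISTIC-style thresholded gene-by-sample matrix of
integer calls in {-2, -1, 0, +1, +2} (deep deletion .. high-level
amplification) and a MAF-like tab-delimited variant table.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "EventKind",
    "OncogenicDirection",
    "AlterationEvent",
    "SampleGenotype",
    "EventMatrix",
    "CNARateParams",
    "read_gistic_matrix",
    "read_maf",
    "sperm_divisions",
    "cna_rate_per_division",
    "gene_event_matrix",
]

GISTIC_LEVELS = {-2, -1, 0, 1, 2}

#: MAF variant classes retained as functional hits: non-synonymous point
#: mutations and small insertions/deletions.  Silent/non-coding classes drop.
NONSYNONYMOUS_CLASSES = {
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Splice_Site",
    "Translation_Start_Site",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    # short synonyms seen in older exports
    "Missense",
    "Nonsense",
    "Indel",
    "Frameshift",
}


class EventKind(str, enum.Enum):
    focal_amplification = "focal_amplification"
    focal_deletion = "focal_deletion"
    point_mutation = "point_mutation"
    pathway = "pathway"


class OncogenicDirection(str, enum.Enum):
    gain_of_signal = "gain_of_signal"
    loss_of_signal = "loss_of_signal"


@dataclass(frozen=True)
class AlterationEvent:
    """One orderable alteration event.

    Either a gene-level event (focal amplification/deletion or point
    mutation of a single gene, up to ``allelic_levels`` sequential hits) or
    a collapsed pathway event (binary, one hit in any member gene).

    Parameters
    ----------
    id : unique label within an analysis.
    kind : the event class.
    genes : member gene symbols (singleton for gene-level events).
    oncogenic_direction : signaling change treated as tumor-promoting.
    allelic_levels : maximum number of sequential hits, 1 or 2.
    mutation_rate : optional per-cell per-division rate of the first hit;
        set to M*mu_g for pathway events (M member genes, mu_g per-gene
        rate).  When None, the network builder uses the per-allele supply.
    """

    id: str
    kind: EventKind
    genes: tuple[str, ...]
    oncogenic_direction: OncogenicDirection
    allelic_levels: int = 2
    mutation_rate: float | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"event {self.id!r}: genes must be non-empty")
        if self.allelic_levels not in (1, 2):
            raise ValueError(
                f"event {self.id!r}: allelic_levels must be 1 or 2, "
                f"got {self.allelic_levels}"
            )
        if self.kind is EventKind.pathway and self.allelic_levels != 1:
            raise ValueError(f"pathway event {self.id!r} must have allelic_levels=1")
        object.__setattr__(self, "genes", tuple(self.genes))


@dataclass
class SampleGenotype:
    """Per-sample thresholded copy-number calls and optional point mutations."""

    sample_id: str
    cna_call: dict[str, int] = field(default_factory=dict)
    point_mutated: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.cna_call.items() if c not in GISTIC_LEVELS}
        if bad:
            raise ValueError(
                f"sample {self.sample_id!r}: calls outside GISTIC levels: {bad}"
            )


class EventMatrix:
    """Samples x events matrix of integer alteration levels.

    Levels are in ``[0, L_e]`` per event; ordering of both axes is
    lexicographic so downstream output is deterministic.
    """

    def __init__(self, levels: pd.DataFrame, events: Sequence[AlterationEvent]):
        events = sorted(events, key=lambda e: e.id)
        ids = [e.id for e in events]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate event ids")
        if set(levels.columns) != set(ids):
            raise ValueError("levels columns must match event ids")
        levels = levels.loc[sorted(levels.index), ids].astype(int)
        for ev in events:
            col = levels[ev.id]
            if (col < 0).any() or (col > ev.allelic_levels).any():
                raise ValueError(
                    f"event {ev.id!r}: levels outside [0, {ev.allelic_levels}]"
                )
        self.levels = levels
        self.events = list(events)
        self._by_id = {e.id: e for e in events}

    @property
    def samples(self) -> list[str]:
        return list(self.levels.index)

    @property
    def event_ids(self) -> list[str]:
        return [e.id for e in self.events]

    def event(self, event_id: str) -> AlterationEvent:
        return self._by_id[event_id]

    def altered(self, event_id: str) -> pd.Series:
        """Boolean per sample: any hit (level >= 1) for the event."""
        return self.levels[event_id] >= 1

    def marginal_frequency(self, event_id: str) -> float:
        return float(self.altered(event_id).mean())

    def to_tsv(self, path: str | Path) -> None:
        self.levels.to_csv(path, sep="\t", index_label="sample")

    def events_to_json(self, path: str | Path) -> None:
        recs = [
            {
                "id": e.id,
                "kind": e.kind.value,
                "genes": list(e.genes),
                "oncogenic_direction": e.oncogenic_direction.value,
                "allelic_levels": e.allelic_levels,
                "mutation_rate": e.mutation_rate,
            }
            for e in self.events
        ]
        Path(path).write_text(json.dumps(recs, indent=1))

    @classmethod
    def from_tsv(
        cls, path: str | Path, events: Sequence[AlterationEvent]
    ) -> "EventMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        return cls(df, events)

    @classmethod
    def events_from_json(cls, path: str | Path) -> list[AlterationEvent]:
        recs = json.loads(Path(path).read_text())
        return [
            AlterationEvent(
                id=r["id"],
                kind=EventKind(r["kind"]),
                genes=tuple(r["genes"]),
                oncogenic_direction=OncogenicDirection(r["oncogenic_direction"]),
                allelic_levels=r["allelic_levels"],
                mutation_rate=r.get("mutation_rate"),
            )
            for r in recs
        ]

    def subset(self, event_ids: Sequence[str]) -> "EventMatrix":
        return EventMatrix(
            self.levels[list(event_ids)].copy(),
            [self._by_id[i] for i in event_ids],
        )


@dataclass(frozen=True)
class CNARateParams:
    """Copy-number alteration rate bookkeeping.

    ``per_generation_rate_per_locus`` is the germline-measured rate of focal
    copy-number changes per locus per generation; dividing by the number of
    cell divisions per generation gives the per-division rate, and halving
    that gives the per-allele rate.
    """

    per_generation_rate_per_locus: float
    divisions_per_generation: int
    per_division_per_locus: float
    per_allele: float
    generation_age: float | None = None
    puberty_age: float | None = None

    def __post_init__(self) -> None:
        if not math.isclose(
            self.per_division_per_locus,
            self.per_generation_rate_per_locus / self.divisions_per_generation,
            rel_tol=1e-12,
        ):
            raise ValueError("per_division_per_locus inconsistent with inputs")
        if not math.isclose(
            self.per_allele, self.per_division_per_locus / 2.0, rel_tol=1e-12
        ):
            raise ValueError("per_allele must be half of per_division_per_locus")


def sperm_divisions(x: float, x_p: float) -> int:
    """Number of cell divisions a sperm germ cell has undergone by age ``x``.

    Uses the standard spermatogenesis division count 36 + 23*(x - x_p),
    where ``x_p`` is age at puberty.
    """
    if x < x_p:
        raise ValueError(f"age x={x} must be >= puberty age x_p={x_p}")
    return int(round(36 + 23 * (x - x_p)))


def cna_rate_per_division(
    per_generation_rate: float,
    divisions: int,
    generation_age: float | None = None,
    puberty_age: float | None = None,
) -> CNARateParams:
    """Convert a per-generation per-locus CNA rate to per-division rates."""
    if per_generation_rate <= 0:
        raise ValueError("per_generation_rate must be positive")
    if divisions <= 0:
        raise ValueError("divisions must be a positive integer")
    per_div = per_generation_rate / divisions
    return CNARateParams(
        per_generation_rate_per_locus=per_generation_rate,
        divisions_per_generation=int(divisions),
        per_division_per_locus=per_div,
        per_allele=per_div / 2.0,
        generation_age=generation_age,
        puberty_age=puberty_age,
    )


def read_gistic_matrix(
    path: str | Path, threshold_mode: str = "high_only"
) -> list[SampleGenotype]:
    """Read a GISTIC-style thresholded calls matrix into genotypes.

    The file is tab-delimited: first column gene symbols, one column per
    sample, integer entries in {-2..2}.  Patients represented by multiple
    columns are deduplicated if all their columns agree and excluded
    entirely if any two columns disagree.

    ``threshold_mode`` ("high_only" or "any") is a downstream convention for
    turning calls into event levels (see :func:`gene_event_matrix`); calls
    are stored unmodified here.
    """
    if threshold_mode not in ("high_only", "any"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        columns = header.split("\t")[1:]
        if not columns:
            raise ValueError(f"{path}: no sample columns")
        rows: dict[str, list[int]] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            gene, cells = parts[0], parts[1:]
            if gene in rows:
                raise ValueError(f"{path}: duplicate gene row {gene!r}")
            if len(cells) != len(columns):
                raise ValueError(f"{path} line {lineno}: ragged row for {gene!r}")
            vals = []
            for col, cell in zip(columns, cells):
                try:
                    v = int(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-integer call {cell!r} "
                        f"(gene {gene!r}, sample {col!r})"
                    ) from None
                if v not in GISTIC_LEVELS:
                    raise ValueError(
                        f"{path}: call {v} outside GISTIC levels "
                        f"(gene {gene!r}, sample {col!r})"
                    )
                vals.append(v)
            rows[gene] = vals
    if not rows:
        raise ValueError(f"{path}: no gene rows")

    # group columns by patient id; drop patients with conflicting replicates
    by_patient: dict[str, list[int]] = {}
    for j, col in enumerate(columns):
        by_patient.setdefault(col, []).append(j)
    genotypes = []
    for patient in sorted(by_patient):
        idxs = by_patient[patient]
        calls = [{g: vals[j] for g, vals in rows.items()} for j in idxs]
        if any(c != calls[0] for c in calls[1:]):
            continue  # conflicting replicate columns: exclude the patient
        genotypes.append(SampleGenotype(sample_id=patient, cna_call=calls[0]))
    return genotypes


def read_maf(path: str | Path) -> dict[str, set[str]]:
    """Read a MAF-like variant table into sample -> mutated-gene sets.

    Keeps only non-synonymous point mutations and small indels.  Requires
    columns Hugo_Symbol, Tumor_Sample_Barcode and Variant_Classification.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    keep = df[df["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)]
    out: dict[str, set[str]] = {}
    for sample, gene in zip(keep["Tumor_Sample_Barcode"], keep["Hugo_Symbol"]):
        out.setdefault(sample, set()).add(gene)
    return out


def _call_to_level(call: int, direction: OncogenicDirection, mode: str) -> int:
    """Map a GISTIC call to an event level for a gene-level event."""
    if direction is OncogenicDirection.gain_of_signal:
        signed = call
    else:
        signed = -call
    if signed <= 0:
        return 0
    if mode == "high_only":
        return 1 if signed == 2 else 0
    return min(signed, 2)  # "any": +/-1 -> level 1, +/-2 -> level 2


def gene_event_matrix(
    genotypes: Iterable[SampleGenotype],
    events: Sequence[AlterationEvent],
    threshold_mode: str = "high_only",
    mutations: Mapping[str, set[str]] | None = None,
) -> EventMatrix:
    """Build a gene-level EventMatrix from thresholded calls.

    In "high_only" mode only |call| = 2 counts (one level); in "any" mode
    +/-1 maps to level 1 and +/-2 to level 2, letting low- and high-level
    amplification be ordered as sequential hits.  Point mutations, when
    supplied, add one level (capped at the event's allelic_levels).
    """
    if threshold_mode not in ("high_only", "any"):
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    genotypes = list(genotypes)
    data = {}
    for ev in events:
        if ev.kind is EventKind.pathway:
            raise ValueError("gene_event_matrix handles gene-level events only")
        gene = ev.genes[0]
        col = []
        for gt in genotypes:
            lvl = _call_to_level(
                gt.cna_call.get(gene, 0), ev.oncogenic_direction, threshold_mode
            )
            if mutations is not None and gene in mutations.get(gt.sample_id, set()):
                lvl += 1
            col.append(min(lvl, ev.allelic_levels))
        data[ev.id] = col
    df = pd.DataFrame(data, index=[g.sample_id for g in genotypes])
    return EventMatrix(df, events)
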