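"""Founder-cohort mutation summaries.

A cohort is a fish x gene matrix of called alleles (or a no-mutation
marker). Two denominators coexist in founder screens and both are reported
explicitly:

* mutation *events* — every mutated cell of the matrix (a label occurring in
  two fish counts twice); the deletion/insertion/complex split uses this.
* distinct mutation *types* — unique (gene, label) pairs; the frameshift
  fraction uses this.

Per-gene mutation efficiency is the fraction of fish carrying a mutation in
that gene; the cohort mean efficiency is the unweighted mean over genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .indels import MutationEvent, build_event, parse_label

__all__ = [
    "CohortTable",
    "CohortSummary",
    "event_from_label",
    "per_gene_efficiency",
    "summarize",
]

EVENT_CLASSES = ("deletion", "insertion", "complex")

#: Markers accepted in label tables for "no mutation in this gene".
NO_MUTATION_MARKERS = {"", "x", "X", "×", "wt", "WT", "0", None}


def event_from_label(gene: str, label: str) -> MutationEvent:
    """Build a MutationEvent from a printed genotype label such as
    "-8" or "+2 (-2, +4)". Component positions are unknown from a label and
    set to 0; sizes, class and frameshift are fully determined."""
    net, components = parse_label(label)
    if components is None:
        if net == 0:
            raise ValueError("label '0' denotes no mutation, not an event")
        if net < 0:
            return build_event(gene, deletions=((0, -net),))
        return build_event(gene, insertions=((0, "N" * net),))
    total_del, total_ins = components
    if total_ins - total_del != net:
        raise ValueError(f"label {label!r}: components do not sum to the net change")
    return build_event(
        gene, deletions=((0, total_del),), insertions=((0, "N" * total_ins),)
    )


@dataclass(frozen=True)
class CohortTable:
    """Rectangular fish x gene matrix of MutationEvents (None = no mutation)."""

    fish_ids: tuple[str, ...]
    genes: tuple[str, ...]
    cells: Mapping[tuple[str, str], Optional[MutationEvent]]

    def __post_init__(self) -> None:
        if len(set(self.fish_ids)) != len(self.fish_ids):
            raise ValueError("duplicate fish ids")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes")
        valid = {(f, g) for f in self.fish_ids for g in self.genes}
        for (fish, gene), ev in self.cells.items():
            if (fish, gene) not in valid:
                raise ValueError(f"cell ({fish!r}, {gene!r}) outside the matrix")
            if ev is not None and ev.gene and ev.gene != gene:
                raise ValueError(
                    f"event gene {ev.gene!r} does not match column {gene!r}"
                )

    def cell(self, fish: str, gene: str) -> Optional[MutationEvent]:
        return self.cells.get((fish, gene))

    def events(self) -> list[tuple[str, str, MutationEvent]]:
        """All mutation events in fish-then-gene order."""
        out = []
        for fish in self.fish_ids:
            for gene in self.genes:
                ev = self.cell(fish, gene)
                if ev is not None and ev.is_mutation:
                    out.append((fish, gene, ev))
        return out

    @classmethod
    def from_labels(
        cls,
        labels: Mapping[str, Mapping[str, Optional[str]]],
        fish_ids: Optional[Sequence[str]] = None,
    ) -> "CohortTable":
        """Build from nested {gene: {fish: label-or-marker}} mappings."""
        genes = tuple(labels)
        if fish_ids is None:
            seen: dict[str, None] = {}
            for per_gene in labels.values():
                for fish in per_gene:
                    seen.setdefault(fish)
            fish_ids = tuple(seen)
        cells: dict[tuple[str, str], Optional[MutationEvent]] = {}
        for gene, per_gene in labels.items():
            for fish in fish_ids:
                label = per_gene.get(fish)
                if label in NO_MUTATION_MARKERS:
                    cells[(fish, gene)] = None
                else:
                    cells[(fish, gene)] = event_from_label(gene, label)
        return cls(fish_ids=tuple(fish_ids), genes=genes, cells=cells)

    @classmethod
    def from_events(
        cls,
        events: Iterable[tuple[str, str, MutationEvent]],
        n_fish: Optional[int] = None,
        genes: Optional[Sequence[str]] = None,
    ) -> "CohortTable":
        """Build from (fish, gene, event) triples.

        ``n_fish`` supplies the denominator when screened fish without any
        mutation are absent from the event list; placeholder rows are added.
        """
        events = list(events)
        fish_ids = list(dict.fromkeys(f for f, _, _ in events))
        gene_list = list(genes) if genes is not None else list(
            dict.fromkeys(g for _, g, _ in events)
        )
        if n_fish is not None:
            if n_fish < len(fish_ids):
                raise ValueError(
                    f"n_fish={n_fish} smaller than the {len(fish_ids)} fish observed"
                )
            k = 0
            while len(fish_ids) < n_fish:
                k += 1
                candidate = f"unmutated_{k}"
                if candidate not in fish_ids:
                    fish_ids.append(candidate)
        cells: dict[tuple[str, str], Optional[MutationEvent]] = {
            (f, g): None for f in fish_ids for g in gene_list
        }
        for fish, gene, ev in events:
            cells[(fish, gene)] = ev
        return cls(fish_ids=tuple(fish_ids), genes=tuple(gene_list), cells=cells)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level statistics, with both denominators spelled out."""

    per_gene_efficiency: dict[str, float]  # percent, 2 decimals
    mean_efficiency: float  # percent, 2 decimals
    mean_efficiency_int: int  # integer-rounded percent
    positive_rate: float  # percent of fish with >= 1 mutation
    event_class_distribution: dict[str, float]  # percent over events
    n_events: int
    frameshift_fraction: float  # percent over distinct (gene, label) types
    n_types: int
    n_fish: int

    def to_dict(self) -> dict:
        return {
            "n_fish": self.n_fish,
            "per_gene_efficiency_pct": dict(self.per_gene_efficiency),
            "mean_efficiency_pct": self.mean_efficiency,
            "mean_efficiency_pct_rounded": self.mean_efficiency_int,
            "positive_rate_pct": self.positive_rate,
            "event_class_distribution_pct_of_events": dict(
                self.event_class_distribution
            ),
            "n_mutation_events": self.n_events,
            "frameshift_pct_of_distinct_types": self.frameshift_fraction,
            "n_distinct_mutation_types": self.n_types,
        }


def per_gene_efficiency(cohort: CohortTable, gene: str) -> float:
    """Percent of fish with a mutation in ``gene``, rounded to 2 decimals."""
    if gene not in cohort.genes:
        raise KeyError(f"unknown gene {gene!r}")
    mutated = sum(
        1
        for fish in cohort.fish_ids
        if (ev := cohort.cell(fish, gene)) is not None and ev.is_mutation
    )
    return round(100.0 * mutated / len(cohort.fish_ids), 2)


def summarize(cohort: CohortTable) -> CohortSummary:
    """Compute the full cohort summary."""
    if not cohort.fish_ids or not cohort.genes:
        raise ValueError("cohort must have at least one fish and one gene")
    per_gene = {g: per_gene_efficiency(cohort, g) for g in cohort.genes}
    exact = [
        100.0
        * sum(
            1
            for f in cohort.fish_ids
            if (ev := cohort.cell(f, g)) is not None and ev.is_mutation
        )
        / len(cohort.fish_ids)
        for g in cohort.genes
    ]
    mean_eff = sum(exact) / len(exact)

    events = cohort.events()
    n_events = len(events)
    class_counts = {c: 0 for c in EVENT_CLASSES}
    for _, _, ev in events:
        class_counts[ev.mutation_class] += 1
    if n_events:
        distribution = {
            c: round(100.0 * class_counts[c] / n_events, 2) for c in EVENT_CLASSES
        }
    else:
        distribution = {c: 0.0 for c in EVENT_CLASSES}

    types: dict[tuple[str, str], bool] = {}
    for _, gene, ev in events:
        types[(gene, ev.label)] = ev.frameshift
    n_types = len(types)
    fs_fraction = (
        round(100.0 * sum(types.values()) / n_types, 2) if n_types else 0.0
    )

    positive = sum(
        1
        for f in cohort.fish_ids
        if any(
            (ev := cohort.cell(f, g)) is not None and ev.is_mutation
            for g in cohort.genes
        )
    )
    return CohortSummary(
        per_gene_efficiency=per_gene,
        mean_efficiency=round(mean_eff, 2),
        mean_efficiency_int=int(round(mean_eff)),
        positive_rate=round(100.0 * positive / len(cohort.fish_ids), 2),
        event_class_distribution=distribution,
        n_events=n_events,
        frameshift_fraction=fs_fraction,
        n_types=n_types,
        n_fish=len(cohort.fish_ids),
    )
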