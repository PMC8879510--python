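"""Allele-vs-wild-type alignment, indel calling and classification.

One resolved allele sequence per fish-gene (Sanger-level genotyping) is
globally aligned to the wild-type amplicon; contiguous gap runs in the
allele row are deletions, runs in the wild-type row insertions. An allele is
then labelled the way founder-screen genotype tables are written: the net
length change first ("-8", "+1"), with the component breakdown in
parentheses only when the allele carries both a deletion and an insertion
("+1 (-3, +4)"). A frameshift is any non-zero-class event whose net change
is not a multiple of 3.

Alignment goes through Bio.Align.PairwiseAligner with affine gap penalties;
among co-optimal placements every gap run is left-shifted to a canonical
position (placement inside a repeat is degenerate and does not affect the
call).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import re
from typing import Optional

from Bio import Align

__all__ = [
    "ALIGN_SCORES",
    "PairwiseAlignment",
    "MutationEvent",
    "align_allele",
    "call_event",
    "classify_net",
    "build_event",
    "format_label",
    "parse_label",
]

#: Affine alignment constants. A gap of length k costs
#: |gap_open| + k * |gap_extend|. Chosen so that the published founder-table
#: alignments are optimal for their sequence pairs.
ALIGN_SCORES = {
    "match": 1,
    "mismatch": -2,
    "gap_open": -5,
    "gap_extend": -1,
}

GAP = "-"


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = ALIGN_SCORES["match"]
    a.mismatch_score = ALIGN_SCORES["mismatch"]
    # Biopython charges open_gap_score for the first gap position
    a.open_gap_score = ALIGN_SCORES["gap_open"] + ALIGN_SCORES["gap_extend"]
    a.extend_gap_score = ALIGN_SCORES["gap_extend"]
    return a


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment: wild-type row, allele row, score."""

    wt_row: str
    allele_row: str
    score: float

    def __post_init__(self) -> None:
        if len(self.wt_row) != len(self.allele_row):
            raise ValueError("alignment rows must have equal length")

    @property
    def wt(self) -> str:
        return self.wt_row.replace(GAP, "")

    @property
    def allele(self) -> str:
        return self.allele_row.replace(GAP, "")


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Column intervals [a, b) of '-' runs in one alignment row."""
    return [(m.start(), m.end()) for m in re.finditer(f"{GAP}+", row)]


def _left_shift(wt_row: str, allele_row: str) -> tuple[str, str]:
    """Left-shift every gap run while preserving the alignment score.

    A run [a, b) in one row may move one column left when column a-1 is
    aligned in both rows and the fixed row has the same base at columns a-1
    and b-1 (the letter slides across an identical letter, so match status
    is unchanged). Iterates to a fixpoint.
    """
    wt = list(wt_row)
    al = list(allele_row)
    changed = True
    while changed:
        changed = False
        for gap_row, fix_row in ((al, wt), (wt, al)):
            runs = _gap_runs("".join(gap_row))
            for a, b in runs:
                while (
                    a > 0
                    and gap_row[a - 1] != GAP
                    and fix_row[a - 1] != GAP
                    and fix_row[a - 1] == fix_row[b - 1]
                ):
                    gap_row[b - 1] = gap_row[a - 1]
                    gap_row[a - 1] = GAP
                    a -= 1
                    b -= 1
                    changed = True
    return "".join(wt), "".join(al)


def align_allele(wt_seq: str, allele_seq: str) -> PairwiseAlignment:
    """Globally align an allele to the wild type.

    Scoring: match +1, mismatch -2, gap open -5, gap extend -1 (affine).
    Among co-optimal alignments, gaps are left-shifted to canonical form.
    """
    if not wt_seq or not allele_seq:
        raise ValueError("sequences must be non-empty")
    wt_seq, allele_seq = wt_seq.upper(), allele_seq.upper()
    aln = next(iter(_aligner().align(wt_seq, allele_seq)))
    wt_row, allele_row = str(aln[0]), str(aln[1])
    wt_row, allele_row = _left_shift(wt_row, allele_row)
    return PairwiseAlignment(wt_row=wt_row, allele_row=allele_row,
                             score=float(aln.score))


def classify_net(net_change: int, has_del: bool, has_ins: bool) -> tuple[str, bool]:
    """(mutation_class, frameshift) from the net change and component flags.

    complex = at least one deletion and at least one insertion; frameshift =
    net change not divisible by 3, and never for the null event.
    """
    if not has_del and not has_ins:
        if net_change != 0:
            raise ValueError("null event must have net_change 0")
        return "none", False
    if has_del and has_ins:
        cls = "complex"
    elif has_del:
        cls = "deletion"
    else:
        cls = "insertion"
    return cls, net_change % 3 != 0


def format_label(
    net_change: int, total_del: int, total_ins: int, mutation_class: str
) -> str:
    """Canonical allele label: net first, components only for complex."""
    if mutation_class == "none":
        return "0"
    label = f"{net_change:+d}"
    if mutation_class == "complex":
        label += f" (-{total_del}, +{total_ins})"
    return label


_LABEL_RE = re.compile(
    r"^\s*([+−-]?\d+)\s*(?:\(\s*[−-](\d+)\s*,\s*\+(\d+)\s*\))?\s*$"
)


def parse_label(label: str) -> tuple[int, Optional[tuple[int, int]]]:
    """Parse a label back to (net_change, (total_del, total_ins) or None).

    Accepts ASCII '-' and typographic minus. "0" parses to (0, None).
    """
    m = _LABEL_RE.match(label.replace("−", "-"))
    if not m:
        raise ValueError(f"unparseable allele label: {label!r}")
    net = int(m.group(1).replace("−", "-"))
    if m.group(2) is None:
        return net, None
    return net, (int(m.group(2)), int(m.group(3)))


@dataclass(frozen=True)
class MutationEvent:
    """One called allele.

    ``deletions`` are (wild-type position, length); ``insertions`` are
    (wild-type position, inserted bases). ``substitutions`` (position,
    wt base, allele base) are a side channel: they never contribute to the
    class or the label, which record indels only.
    """

    gene: str
    deletions: tuple[tuple[int, int], ...]
    insertions: tuple[tuple[int, str], ...]
    net_change: int
    mutation_class: str
    frameshift: bool
    label: str
    substitutions: tuple[tuple[int, str, str], ...] = ()

    @property
    def total_deleted(self) -> int:
        return sum(ln for _, ln in self.deletions)

    @property
    def total_inserted(self) -> int:
        return sum(len(b) for _, b in self.insertions)

    @property
    def is_mutation(self) -> bool:
        return self.mutation_class != "none"


def build_event(
    gene: str,
    deletions: tuple[tuple[int, int], ...] = (),
    insertions: tuple[tuple[int, str], ...] = (),
    substitutions: tuple[tuple[int, str, str], ...] = (),
) -> MutationEvent:
    """Construct a consistent MutationEvent from its components."""
    total_del = sum(ln for _, ln in deletions)
    total_ins = sum(len(b) for _, b in insertions)
    net = total_ins - total_del
    cls, fs = classify_net(net, bool(deletions), bool(insertions))
    return MutationEvent(
        gene=gene,
        deletions=tuple(deletions),
        insertions=tuple(insertions),
        net_change=net,
        mutation_class=cls,
        frameshift=fs,
        label=format_label(net, total_del, total_ins, cls),
        substitutions=tuple(substitutions),
    )


def call_event(wt_seq: str, allele_seq: str, gene: str = "") -> MutationEvent:
    """Align an allele to wild type and call its mutation event.

    Gap runs in the allele row become deletions, runs in the wild-type row
    insertions; aligned mismatches go to the substitution side channel.
    """
    aln = align_allele(wt_seq, allele_seq)
    deletions: list[tuple[int, int]] = []
    insertions: list[tuple[int, str]] = []
    substitutions: list[tuple[int, str, str]] = []
    wt_pos = 0
    col = 0
    n = len(aln.wt_row)
    while col < n:
        w, a = aln.wt_row[col], aln.allele_row[col]
        if a == GAP:  # deletion run
            start = wt_pos
            length = 0
            while col < n and aln.allele_row[col] == GAP:
                length += 1
                wt_pos += 1
                col += 1
            deletions.append((start, length))
        elif w == GAP:  # insertion run
            start = wt_pos
            bases = []
            while col < n and aln.wt_row[col] == GAP:
                bases.append(aln.allele_row[col])
                col += 1
            insertions.append((start, "".join(bases)))
        else:
            if w != a:
                substitutions.append((wt_pos, w, a))
            wt_pos += 1
            col += 1
    return build_event(
        gene=gene,
        deletions=tuple(deletions),
        insertions=tuple(insertions),
        substitutions=tuple(substitutions),
    )
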