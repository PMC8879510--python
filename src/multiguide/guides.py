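"""Protospacer selection under the GG...NGG rule.

A usable target here is a 23-nt window whose first two bases are GG (so the
T7 polymerase initiates transcription on the guide's own 5' GG) and whose
last three bases form the SpCas9 PAM (NGG, i.e. the final two bases are GG).
Both strands of an exon are scanned; minus-strand hits are reported in their
own orientation with forward-strand coordinates. Candidates are ranked by
proximity to the start of the coding sequence, where indels are most likely
to truncate the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .seqio import SeqRecord, revcomp

__all__ = [
    "GuideTarget",
    "TargetValidation",
    "TARGET_LENGTH",
    "validate_target",
    "find_targets",
    "rank_targets",
    "mask_variants",
]

TARGET_LENGTH = 23  # 20-nt protospacer (starting GG) + 3-nt PAM (NGG)

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class TargetValidation:
    """Verdict of the GG...NGG rule with machine-readable reason codes."""

    valid: bool
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class GuideTarget:
    """One protospacer+PAM hit.

    ``seq`` is always given in target-strand orientation (the 23-mer the
    guide is built from); ``start``/``end`` are 0-based half-open coordinates
    on the forward strand of the source record.
    """

    gene: str
    seq: str
    strand: str
    start: int
    end: int
    distance_to_cds_start: Optional[int] = None

    def __post_init__(self) -> None:
        verdict = validate_target(self.seq)
        if not verdict.valid:
            raise ValueError(
                f"invalid target {self.seq!r}: {', '.join(verdict.reasons)}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}")
        if self.end - self.start != TARGET_LENGTH:
            raise ValueError("coordinates must span exactly 23 nt")

    @property
    def protospacer(self) -> str:
        return self.seq[:20]

    @property
    def pam(self) -> str:
        return self.seq[20:]


def validate_target(seq: str) -> TargetValidation:
    """Check a 23-mer against the selection rule: starts GG, ends NGG.

    The PAM's N (position 21 of the 23-mer) is free; positions 22-23 must be
    GG. Returns a verdict object carrying every failed check, never raises.
    """
    reasons: list[str] = []
    seq = str(seq)
    if len(seq) != TARGET_LENGTH:
        reasons.append(f"length {len(seq)} != {TARGET_LENGTH}")
    if set(seq) - set("ACGT"):
        reasons.append("alphabet not restricted to ACGT")
    if not seq.startswith("GG"):
        reasons.append("no GG prefix")
    if len(seq) < 3 or seq[-2:] != "GG":
        reasons.append("no NGG suffix")
    return TargetValidation(valid=not reasons, reasons=tuple(reasons))


def find_targets(
    record: SeqRecord, scan_both_strands: bool = True, gene: Optional[str] = None
) -> list[GuideTarget]:
    """Scan every 23-nt window of a record for valid targets.

    Windows containing N are skipped (the PAM rule is undefined on N).
    Overlapping and nested hits are all reported. Hits are sorted by start
    coordinate, plus strand before minus at the same start. Records shorter
    than 23 nt yield an empty list.
    """
    gene = gene if gene is not None else record.id
    seq = record.seq
    hits: list[GuideTarget] = []
    for start in range(len(seq) - TARGET_LENGTH + 1):
        window = seq[start : start + TARGET_LENGTH]
        if "N" in window:
            continue
        if validate_target(window).valid:
            hits.append(
                GuideTarget(gene=gene, seq=window, strand="+", start=start,
                            end=start + TARGET_LENGTH)
            )
        if scan_both_strands:
            rc = revcomp(window)
            if validate_target(rc).valid:
                hits.append(
                    GuideTarget(gene=gene, seq=rc, strand="-", start=start,
                                end=start + TARGET_LENGTH)
                )
    hits.sort(key=lambda t: (t.start, 0 if t.strand == "+" else 1))
    return hits


def rank_targets(targets: Sequence[GuideTarget], cds_start: int) -> list[GuideTarget]:
    """Order targets by distance to the coding-sequence start.

    Distance is |start - cds_start| in nt on the forward strand. Ties break
    plus strand first, then lower start. Returns new target objects with
    ``distance_to_cds_start`` filled in.
    """
    if cds_start < 0:
        raise ValueError("cds_start must be a non-negative forward-strand coordinate")
    annotated = [
        replace(t, distance_to_cds_start=abs(t.start - cds_start)) for t in targets
    ]
    annotated.sort(
        key=lambda t: (t.distance_to_cds_start, 0 if t.strand == "+" else 1, t.start)
    )
    return annotated


def mask_variants(
    targets: Iterable[GuideTarget], variant_positions: Iterable[int]
) -> list[GuideTarget]:
    """Drop targets overlapping known variant sites.

    ``variant_positions`` are 0-based forward-strand coordinates (e.g. known
    SNPs); a target is removed iff its [start, end) interval contains any of
    them. Intervals are half-open, so a variant at ``end`` is harmless.
    """
    positions = sorted(set(int(p) for p in variant_positions))
    kept = []
    for t in targets:
        if not any(t.start <= p < t.end for p in positions):
            kept.append(t)
    return kept
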