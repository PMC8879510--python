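"""Synthetic fixtures: exons with planted targets, mutant alleles with known
indels, and behavioural / staining data with known group parameters.

Everything is driven by one explicitly passed numpy Generator (or an integer
seed); there is no global random state, so identical seeds give identical
fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .guides import GuideTarget, TARGET_LENGTH, find_targets
from .indels import MutationEvent, build_event, call_event
from .seqio import SeqRecord, revcomp

__all__ = [
    "AlleleSpec",
    "synth_exon",
    "synth_alleles",
    "simulate_cstart_trials",
    "simulate_intensity",
    "simulate_counts",
]

_BASES = np.array(list("ACGT"))


def _rng(seed_or_rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _random_motif(rng: np.random.Generator) -> str:
    """A 23-mer satisfying the selection rule: GG + 18 random + N + GG."""
    return "GG" + _random_bases(rng, 18) + _random_bases(rng, 1) + "GG"


def synth_exon(
    length: int,
    n_targets: int,
    seed: Union[int, np.random.Generator, None] = None,
    collision_free: bool = True,
    max_attempts: int = 500,
) -> tuple[SeqRecord, list[GuideTarget]]:
    """Generate an exon-like sequence with exactly the planted GG...NGG targets.

    Targets are planted at random non-overlapping positions on random
    strands. In collision-free mode (default) the whole sequence is
    resampled until a both-strand scan finds exactly the planted hits, so
    scanner tests have an unambiguous ground truth.
    """
    rng = _rng(seed)
    if n_targets < 0:
        raise ValueError("n_targets must be >= 0")
    if length < TARGET_LENGTH * n_targets:
        raise ValueError(
            f"cannot pack {n_targets} non-overlapping 23-nt targets into {length} nt"
        )

    def place() -> list[int]:
        if n_targets == 0:
            return []
        if length == TARGET_LENGTH * n_targets:
            return [i * TARGET_LENGTH for i in range(n_targets)]
        for _ in range(1000):
            starts = sorted(rng.integers(0, length - TARGET_LENGTH + 1,
                                         size=n_targets))
            if all(b - a >= TARGET_LENGTH for a, b in zip(starts, starts[1:])):
                return list(int(s) for s in starts)
        raise RuntimeError("could not place targets without overlap")

    for _ in range(max_attempts):
        starts = place()
        strands = [str(rng.choice(["+", "-"])) for _ in range(n_targets)]
        seq = list(_random_bases(rng, length))
        planted: list[GuideTarget] = []
        for start, strand in zip(starts, strands):
            motif = _random_motif(rng)
            insert = motif if strand == "+" else revcomp(motif)
            seq[start : start + TARGET_LENGTH] = insert
            planted.append(
                GuideTarget(gene="synthetic", seq=motif, strand=strand,
                            start=start, end=start + TARGET_LENGTH)
            )
        record = SeqRecord(id="synthetic", seq="".join(seq))
        if not collision_free:
            return record, planted
        found = {(t.start, t.strand, t.seq) for t in find_targets(record)}
        want = {(t.start, t.strand, t.seq) for t in planted}
        if found == want:
            return record, planted
    raise RuntimeError(
        f"no collision-free sequence found in {max_attempts} attempts "
        f"(length={length}, n_targets={n_targets})"
    )


@dataclass(frozen=True)
class AlleleSpec:
    """Requested edit for one synthetic allele.

    ``n_del`` bases deleted and ``n_ins`` bases inserted inside the target
    window. Positions and inserted bases are drawn at random unless pinned
    via ``del_start`` / ``ins_pos`` / ``ins_bases`` (coordinates on the
    wild-type sequence).
    """

    n_del: int
    n_ins: int
    del_start: Optional[int] = None
    ins_pos: Optional[int] = None
    ins_bases: Optional[str] = None


#: Minimum matched bases kept between a deletion and an insertion of the
#: same allele, so the aligner resolves them as two distinct gap runs.
_EDIT_SEPARATION = 6


def synth_alleles(
    wt_seq: str,
    target: GuideTarget,
    spec_list: Sequence[Union[AlleleSpec, tuple[int, int]]],
    seed: Union[int, np.random.Generator, None] = None,
    strict: bool = True,
    collision_free: bool = True,
    max_attempts: int = 100,
) -> list[tuple[str, MutationEvent]]:
    """Generate mutant alleles with known ground-truth events.

    Edits are placed inside the target window [target.start, target.end).
    Inserted bases never extend flanking repeat context (first and last
    inserted base differ from the wild-type base each would duplicate), and
    a deletion and insertion of the same allele keep at least 6 matched
    bases between them. The net length change of a planted event is always
    recoverable by the caller; the complex *class* is ambiguous whenever a
    net gap plus substitutions scores better than two gap runs, so in
    collision-free mode (default) any randomised placement/bases of a
    complex spec are resampled until the optimal alignment recovers the
    planted event, and a spec for which no unambiguous embedding can be
    found raises. Fully pinned specs are emitted as requested without the
    check. In strict mode a deletion longer than the window raises.
    """
    rng = _rng(seed)
    lo, hi = target.start, target.end
    if not (0 <= lo < hi <= len(wt_seq)):
        raise ValueError("target window outside wild-type sequence")

    def one_draw(spec: AlleleSpec) -> tuple[str, MutationEvent]:
        deletions: list[tuple[int, int]] = []
        insertions: list[tuple[int, str]] = []
        allele = wt_seq

        p = spec.del_start
        if spec.n_del > 0:
            if p is None:
                p_hi = min(hi - spec.n_del, len(wt_seq) - spec.n_del)
                if spec.n_ins > 0 and spec.ins_pos is None:
                    # leave room for a separated insertion downstream
                    p_hi = min(p_hi, hi - spec.n_del - _EDIT_SEPARATION)
                if p_hi < lo:
                    raise ValueError("deletion does not fit in the target window")
                p = int(rng.integers(lo, p_hi + 1))
            deletions.append((p, spec.n_del))

        if spec.n_ins > 0:
            q = spec.ins_pos
            if q is None:
                q_lo = lo if not deletions else (
                    deletions[0][0] + spec.n_del + _EDIT_SEPARATION
                )
                if q_lo > hi:
                    raise ValueError(
                        "cannot separate insertion from deletion inside the window"
                    )
                q = int(rng.integers(q_lo, hi + 1))
            bases = spec.ins_bases
            if bases is None:
                chars = []
                for k in range(spec.n_ins):
                    avoid = set()
                    if k == 0 and q < len(wt_seq):
                        avoid.add(wt_seq[q])
                    if k == spec.n_ins - 1 and q > 0:
                        avoid.add(wt_seq[q - 1])
                    choices = [b for b in "ACGT" if b not in avoid]
                    chars.append(str(rng.choice(choices)))
                bases = "".join(chars)
            insertions.append((q, bases))

        # apply right-to-left so earlier coordinates stay valid
        edits = [("del", pos, length) for pos, length in deletions] + [
            ("ins", pos, b) for pos, b in insertions
        ]
        for kind, pos, payload in sorted(edits, key=lambda e: -e[1]):
            if kind == "del":
                allele = allele[:pos] + allele[pos + payload :]
            else:
                allele = allele[:pos] + payload + allele[pos:]

        event = build_event(
            gene=target.gene,
            deletions=tuple(deletions),
            insertions=tuple(insertions),
        )
        return allele, event

    out: list[tuple[str, MutationEvent]] = []
    for raw in spec_list:
        spec = raw if isinstance(raw, AlleleSpec) else AlleleSpec(*raw)
        if spec.n_del < 0 or spec.n_ins < 0:
            raise ValueError("edit sizes must be non-negative")
        if strict and spec.n_del > hi - lo:
            raise ValueError(
                f"deletion of {spec.n_del} nt exceeds the {hi - lo}-nt target window"
            )
        randomized = (
            (spec.n_del > 0 and spec.del_start is None)
            or (spec.n_ins > 0 and (spec.ins_pos is None or spec.ins_bases is None))
        )
        ambiguous_class = spec.n_del > 0 and spec.n_ins > 0
        if not (collision_free and randomized and ambiguous_class):
            out.append(one_draw(spec))
            continue
        for _ in range(max_attempts):
            allele, event = one_draw(spec)
            called = call_event(wt_seq, allele, gene=target.gene)
            if (
                called.net_change == event.net_change
                and called.mutation_class == event.mutation_class
                and called.frameshift == event.frameshift
            ):
                out.append((allele, event))
                break
        else:
            raise RuntimeError(
                f"no unambiguous embedding found for complex spec "
                f"(-{spec.n_del}, +{spec.n_ins}) in {max_attempts} attempts; "
                f"the components are too small to be identifiable here"
            )
    return out


def simulate_cstart_trials(
    n_fish: int,
    n_trials: int,
    response_rate: float,
    group: str = "wt",
    seed: Union[int, np.random.Generator, None] = None,
    rate_dispersion: Optional[float] = None,
    fish_prefix: Optional[str] = None,
) -> pd.DataFrame:
    """Simulate a C-start trial table.

    Each fish receives ``n_trials`` independent Bernoulli(``response_rate``)
    trials; a response gets a latency drawn Uniform(4, 24) ms (inside the
    25-ms gate), a non-response an empty latency. ``rate_dispersion`` > 0
    switches on per-fish Beta-distributed rates (mean ``response_rate``,
    concentration 1/dispersion), modelling fish-to-fish heterogeneity; the
    default (None) is exchangeable Bernoulli, the assumption a per-fish-rate
    t-test makes.
    """
    rng = _rng(seed)
    if not 0.0 <= response_rate <= 1.0:
        raise ValueError("response_rate must be in [0, 1]")
    prefix = fish_prefix if fish_prefix is not None else group
    rows = []
    for i in range(n_fish):
        p = response_rate
        if rate_dispersion:
            conc = 1.0 / rate_dispersion
            a = max(response_rate * conc, 1e-9)
            b = max((1.0 - response_rate) * conc, 1e-9)
            p = float(rng.beta(a, b))
        fish_id = f"{prefix}_{i + 1:03d}"
        for t in range(1, n_trials + 1):
            responded = rng.random() < p
            latency = round(float(rng.uniform(4.0, 24.0)), 1) if responded else np.nan
            rows.append((fish_id, group, t, latency))
    return pd.DataFrame(rows, columns=["fish_id", "group", "trial_index", "latency_ms"])


def simulate_intensity(
    n: int,
    mean: float,
    sd: Optional[float] = None,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Gaussian fluorescence intensities; default sd is 10% of the mean
    (typical replicate spread for cluster-averaged staining), clipped at 0."""
    rng = _rng(seed)
    if sd is None:
        sd = 0.10 * mean
    return np.clip(rng.normal(mean, sd, size=n), 0.0, None)


def simulate_counts(
    n: int,
    mean: float,
    sd: float = 2.0,
    seed: Union[int, np.random.Generator, None] = None,
) -> np.ndarray:
    """Integer-valued hair-cell cluster counts: rounded Gaussian, floor 0."""
    rng = _rng(seed)
    vals = np.rint(rng.normal(mean, sd, size=n))
    return np.clip(vals, 0, None).astype(int)
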