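"""Cloning-free gRNA template assembly from six oligonucleotides.

The in-vitro transcription template is a single ~125-bp duplex:

    T7 promoter (21 nt) + target 23-mer (GGN18NGG) + scaffold constant (81 nt)

Rather than cloning it, the template is assembled by annealing six
chemically synthesised oligos (38-46 nt) into three sticky-ended duplex
fragments and ligating them in one pot. The two junction overhangs are
chosen so that only the intended order can ligate and no product can
circularise; both overhangs sit in constant sequence, so switching to a new
gene replaces only the two fragment-1 oligos.

`simulate_ligation` is the verifier for those claims: it exhaustively joins
fragments wherever sticky ends are Watson-Crick compatible (both
orientations, each fragment once per product) and reports every maximal
linear or circular product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .guides import GuideTarget, validate_target
from .seqio import revcomp

__all__ = [
    "T7_PROMOTER",
    "SCAFFOLD",
    "GuideTemplate",
    "Overhang",
    "BLUNT",
    "DuplexFragment",
    "Oligo",
    "OligoSet",
    "LigationProduct",
    "SplitError",
    "build_template",
    "split_template",
    "simulate_ligation",
    "diff_oligos",
    "can_ligate",
]

#: T7 promoter as printed in the template pattern; transcription initiates
#: at the GG that begins the target 23-mer.
T7_PROMOTER = "AATTTAATACGACTCACTATA"

#: The 81-nt constant gRNA scaffold (includes 3' tracrRNA-derived extension).
SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCC"
    "GTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGCTTTTT"
)

OLIGO_MIN = 38
OLIGO_MAX = 46


class SplitError(ValueError):
    """Raised when no oligo split satisfies the design constraints."""


@dataclass(frozen=True)
class GuideTemplate:
    """Full transcription template for one target."""

    target: GuideTarget
    seq: str
    include_pam_in_spacer: bool = True

    @property
    def variable_positions(self) -> range:
        """Template positions that change when the target changes.

        The protospacer (20 nt) plus, when the PAM is kept, its N base; the
        PAM's GG is invariant across targets.
        """
        n_var = 21 if self.include_pam_in_spacer else 20
        return range(len(T7_PROMOTER), len(T7_PROMOTER) + n_var)

    @property
    def target_region(self) -> range:
        n = 23 if self.include_pam_in_spacer else 20
        return range(len(T7_PROMOTER), len(T7_PROMOTER) + n)


@dataclass(frozen=True)
class Overhang:
    """A single-stranded extension at a fragment end.

    ``seq`` is read 5'->3' along the protruding strand; ``protruding`` names
    that strand; ``kind`` is five_prime/three_prime/blunt.
    """

    seq: str = ""
    protruding: str = ""
    kind: str = "blunt"


BLUNT = Overhang()


def can_ligate(a: Overhang, b: Overhang) -> bool:
    """True iff two sticky ends anneal: same protrusion chemistry and
    Watson-Crick complementary single strands. Blunt ends never ligate in
    this model (the one-pot reaction uses no blunt ligation)."""
    if a.kind == "blunt" or b.kind == "blunt":
        return False
    return a.kind == b.kind and a.seq == revcomp(b.seq)


@dataclass(frozen=True)
class DuplexFragment:
    """One annealed fragment: top/bottom oligos plus its two ends.

    ``top`` runs 5'->3' left-to-right, ``bottom`` 5'->3' right-to-left (both
    stored 5'->3' as synthesised).
    """

    index: int
    top_oligo: str
    bottom_oligo: str
    left_overhang: Overhang = BLUNT
    right_overhang: Overhang = BLUNT

    def flipped(self) -> "DuplexFragment":
        """The same physical molecule read in the opposite direction."""

        def swap(o: Overhang) -> Overhang:
            if o.kind == "blunt":
                return o
            return Overhang(
                seq=o.seq,
                protruding="bottom" if o.protruding == "top" else "top",
                kind=o.kind,
            )

        return DuplexFragment(
            index=self.index,
            top_oligo=self.bottom_oligo,
            bottom_oligo=self.top_oligo,
            left_overhang=swap(self.right_overhang),
            right_overhang=swap(self.left_overhang),
        )


@dataclass(frozen=True)
class Oligo:
    name: str
    seq: str
    fragment: int
    strand: str  # top | bottom
    variable_per_target: bool

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OligoSet:
    """The six synthesis-ready oligos for one template."""

    oligos: tuple[Oligo, ...]

    def __iter__(self):
        return iter(self.oligos)

    def __len__(self) -> int:
        return len(self.oligos)

    def by_name(self, name: str) -> Oligo:
        for o in self.oligos:
            if o.name == name:
                return o
        raise KeyError(name)

    def variable_oligos(self) -> list[Oligo]:
        return [o for o in self.oligos if o.variable_per_target]


def build_template(
    target: GuideTarget, include_pam_in_spacer: bool = True
) -> GuideTemplate:
    """Assemble the printed template pattern for a validated target.

    With the PAM kept (default, faithful to the printed pattern) the
    template is T7(21) + 23-mer + scaffold(81) = 125 nt; without it the
    3-nt PAM is omitted (122 nt).
    """
    verdict = validate_target(target.seq)
    if not verdict.valid:
        raise ValueError(f"invalid target: {', '.join(verdict.reasons)}")
    spacer = target.seq if include_pam_in_spacer else target.seq[:20]
    return GuideTemplate(
        target=target,
        seq=T7_PROMOTER + spacer + SCAFFOLD,
        include_pam_in_spacer=include_pam_in_spacer,
    )


def _junction_candidates(L: int, overhang_len: int):
    """Enumerate (u1, v1, u2, v2) cut pairs; u = top-strand cut, v = bottom.

    Fragment i top spans [u_{i-1}, u_i), bottom spans [v_{i-1}, v_i) (as
    forward coordinates; bottom oligos are the reverse complement). Outer
    ends are blunt by construction.
    """
    for s1 in (overhang_len, -overhang_len):
        for u1 in range(OLIGO_MIN, OLIGO_MAX + 1):
            v1 = u1 + s1
            if not (OLIGO_MIN <= v1 <= OLIGO_MAX):
                continue
            for s2 in (overhang_len, -overhang_len):
                for u2 in range(u1 + 1, L):
                    v2 = u2 + s2
                    lengths = (u1, v1, u2 - u1, v2 - v1, L - u2, L - v2)
                    if all(OLIGO_MIN <= x <= OLIGO_MAX for x in lengths):
                        # keep a double-stranded core at every junction
                        if min(u2, v2) > max(u1, v1) + 1:
                            yield (u1, v1, u2, v2)


def _make_fragments(seq: str, cuts: tuple[int, int, int, int]) -> list[DuplexFragment]:
    u1, v1, u2, v2 = cuts
    L = len(seq)

    def junction_overhang(u: int, v: int, left_fragment: bool) -> Overhang:
        lo, hi = min(u, v), max(u, v)
        region = seq[lo:hi]
        if v > u:
            # bottom strand extends further right at the junction
            if left_fragment:
                return Overhang(seq=revcomp(region), protruding="bottom",
                                kind="five_prime")
            return Overhang(seq=region, protruding="top", kind="five_prime")
        # top strand extends further right (3' protrusion on the left piece)
        if left_fragment:
            return Overhang(seq=region, protruding="top", kind="three_prime")
        return Overhang(seq=revcomp(region), protruding="bottom",
                        kind="three_prime")

    tops = (seq[0:u1], seq[u1:u2], seq[u2:L])
    bottoms = (revcomp(seq[0:v1]), revcomp(seq[v1:v2]), revcomp(seq[v2:L]))
    ends = [
        (BLUNT, junction_overhang(u1, v1, True)),
        (junction_overhang(u1, v1, False), junction_overhang(u2, v2, True)),
        (junction_overhang(u2, v2, False), BLUNT),
    ]
    return [
        DuplexFragment(index=i + 1, top_oligo=tops[i], bottom_oligo=bottoms[i],
                       left_overhang=ends[i][0], right_overhang=ends[i][1])
        for i in range(3)
    ]


def _sticky_ends_admissible(fragments: Sequence[DuplexFragment]) -> bool:
    """Only the two intended junctions may ligate.

    Checks every pairing (including an end with itself, which catches
    palindromic overhangs and hence circularisation) among the four sticky
    ends; exactly the designed neighbours may be complementary.
    """
    ends = {
        "f1R": fragments[0].right_overhang,
        "f2L": fragments[1].left_overhang,
        "f2R": fragments[1].right_overhang,
        "f3L": fragments[2].left_overhang,
    }
    intended = {frozenset(("f1R", "f2L")), frozenset(("f2R", "f3L"))}
    names = list(ends)
    for i, a in enumerate(names):
        for b in names[i:]:
            ok = can_ligate(ends[a], ends[b])
            if ok != (frozenset((a, b)) in intended):
                return False
    return True


def split_template(
    template: GuideTemplate, overhang_len: int = 4
) -> tuple[OligoSet, list[DuplexFragment]]:
    """Split a template into three sticky-ended fragments / six oligos.

    Constraints enforced: every oligo 38-46 nt; all target-dependent bases
    confined to fragment 1 (so only two oligos are resynthesised per gene);
    fragment 1 spans the whole protospacer+PAM; junction overhangs pairwise
    distinct, non-palindromic and not cross-complementary; outer ends blunt.
    The search is a deterministic scan preferring balanced oligo lengths, so
    the same template always yields the same design.
    """
    if overhang_len not in (3, 4, 5):
        raise SplitError("overhang_len must be 3, 4 or 5")
    seq = template.seq
    L = len(seq)
    var_lo = template.variable_positions.start
    var_hi = template.variable_positions.stop  # exclusive
    region_hi = template.target_region.stop

    sized: list[tuple[int, int, int, int]] = []
    confined: list[tuple[int, int, int, int]] = []
    for cuts in _junction_candidates(L, overhang_len):
        sized.append(cuts)
        u1, v1, u2, v2 = cuts
        # no variable base may leak into fragment 2's oligos
        if min(u1, v1) < var_hi:
            continue
        # fragment 1 must contain the entire target region on some strand
        if max(u1, v1) < region_hi:
            continue
        confined.append(cuts)
    if not sized:
        raise SplitError(
            f"no junction placement gives six oligos of {OLIGO_MIN}-{OLIGO_MAX} nt "
            f"for a {L}-nt template with {overhang_len}-nt overhangs"
        )
    if not confined:
        raise SplitError(
            "no oligo-length-feasible split confines the target-dependent bases "
            "to fragment 1"
        )

    def balance(cuts: tuple[int, int, int, int]) -> tuple:
        u1, v1, u2, v2 = cuts
        lengths = (u1, v1, u2 - u1, v2 - v1, L - u2, L - v2)
        mean = sum(lengths) / 6.0
        return (
            max(lengths) - min(lengths),
            sum(abs(x - mean) for x in lengths),
            cuts,
        )

    for cuts in sorted(confined, key=balance):
        fragments = _make_fragments(seq, cuts)
        if _sticky_ends_admissible(fragments):
            break
    else:
        raise SplitError(
            "no admissible overhang set: every candidate junction pair is "
            "palindromic, repeated, or cross-complementary (try overhang_len "
            "3 or 5)"
        )

    u1, v1, u2, v2 = cuts
    top_spans = ((0, u1), (u1, u2), (u2, L))
    bot_spans = ((0, v1), (v1, v2), (v2, L))
    var = set(template.variable_positions)
    oligos = []
    for i, frag in enumerate(fragments):
        t_lo, t_hi = top_spans[i]
        b_lo, b_hi = bot_spans[i]
        oligos.append(
            Oligo(name=f"F{i + 1}-top", seq=frag.top_oligo, fragment=i + 1,
                  strand="top",
                  variable_per_target=bool(var & set(range(t_lo, t_hi))))
        )
        oligos.append(
            Oligo(name=f"F{i + 1}-bottom", seq=frag.bottom_oligo, fragment=i + 1,
                  strand="bottom",
                  variable_per_target=bool(var & set(range(b_lo, b_hi))))
        )
    oligo_set = OligoSet(oligos=tuple(oligos))
    n_var = len(oligo_set.variable_oligos())
    if n_var != 2:  # guaranteed by the confinement constraint
        raise SplitError(f"internal error: {n_var} variable oligos, expected 2")
    return oligo_set, fragments


@dataclass(frozen=True)
class LigationProduct:
    """A maximal ligation product: an ordered chain of (fragment index into
    the input list, flipped?) pairs, linear or circular."""

    chain: tuple[tuple[int, bool], ...]
    circular: bool
    top_sequence: Optional[str] = None  # linear products only

    def __len__(self) -> int:
        return len(self.chain)


def _oriented(fragments: Sequence[DuplexFragment], idx: int, flip: bool):
    return fragments[idx].flipped() if flip else fragments[idx]


def _canonical_linear(chain: tuple[tuple[int, bool], ...]):
    rev = tuple((i, not f) for i, f in reversed(chain))
    return min(chain, rev)


def _canonical_circular(chain: tuple[tuple[int, bool], ...]):
    forms = []
    n = len(chain)
    for rot in range(n):
        rotated = chain[rot:] + chain[:rot]
        forms.append(rotated)
        rev = tuple((i, not f) for i, f in reversed(rotated))
        forms.append(rev)
    return min(forms)


def simulate_ligation(fragments: Sequence[DuplexFragment]) -> list[LigationProduct]:
    """Exhaustively enumerate maximal ligation products.

    Chains grow by joining any unused fragment, in either orientation, to an
    open sticky end. A chain is a product when neither open end can accept
    any remaining fragment; if its own two ends are complementary it is
    reported circular. Products identical up to reading direction (and
    rotation, for circles) are deduplicated, so the result is
    input-order-invariant.
    """
    frags = list(fragments)
    if not frags:
        raise ValueError("at least one fragment required")
    n = len(frags)
    products: dict[tuple, LigationProduct] = {}

    def right_end(chain) -> Overhang:
        i, f = chain[-1]
        return _oriented(frags, i, f).right_overhang

    def left_end(chain) -> Overhang:
        i, f = chain[0]
        return _oriented(frags, i, f).left_overhang

    def extensions(chain, used):
        out = []
        for j in range(n):
            if j in used:
                continue
            for flip in (False, True):
                cand = _oriented(frags, j, flip)
                if can_ligate(right_end(chain), cand.left_overhang):
                    out.append(("right", j, flip))
                if can_ligate(cand.right_overhang, left_end(chain)):
                    out.append(("left", j, flip))
        return out

    def record(chain):
        circ = can_ligate(right_end(chain), left_end(chain))
        if circ:
            key = ("c", _canonical_circular(chain))
            if key not in products:
                products[key] = LigationProduct(
                    chain=_canonical_circular(chain), circular=True
                )
        else:
            key = ("l", _canonical_linear(chain))
            if key not in products:
                top = "".join(
                    _oriented(frags, i, f).top_oligo for i, f in chain
                )
                products[key] = LigationProduct(
                    chain=_canonical_linear(chain), circular=False,
                    top_sequence=top,
                )

    def grow(chain, used):
        exts = extensions(chain, used)
        if not exts:
            record(chain)
            return
        for side, j, flip in exts:
            new_chain = chain + ((j, flip),) if side == "right" else ((j, flip),) + chain
            grow(new_chain, used | {j})

    for i in range(n):
        grow(((i, False),), {i})
    return list(products.values())


def diff_oligos(set_a: OligoSet, set_b: OligoSet) -> list[tuple[Oligo, Oligo]]:
    """Pairs of same-named oligos whose sequences differ between two designs."""
    if len(set_a) != len(set_b):
        raise ValueError("oligo sets must come from the same split parameters")
    out = []
    for a in set_a:
        b = set_b.by_name(a.name)
        if a.seq != b.seq:
            out.append((a, b))
    return out
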