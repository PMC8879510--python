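"""Template construction, oligo splitting, and ligation simulation."""

import itertools

import numpy as np
import pytest

from multiguide import (
    GuideTarget,
    build_template,
    diff_oligos,
    simulate_ligation,
    split_template,
)
from multiguide.assembly import (
    BLUNT,
    DuplexFragment,
    Overhang,
    SCAFFOLD,
    SplitError,
    T7_PROMOTER,
    can_ligate,
)
from multiguide.seqio import revcomp

from conftest import PUBLISHED_TARGETS


def _target(gene="gabbr1a"):
    return GuideTarget(gene=gene, seq=PUBLISHED_TARGETS[gene], strand="+",
                       start=0, end=23)


def _random_target(rng):
    seq = "GG" + "".join(rng.choice(list("ACGT"), size=19)) + "GG"
    return GuideTarget(gene="r", seq=seq, strand="+", start=0, end=23)


class TestBuildTemplate:
    def test_constants_have_printed_lengths(self):
        assert len(T7_PROMOTER) == 21
        assert len(SCAFFOLD) == 81

    def test_published_target_prefix(self):
        tpl = build_template(_target("gabbr1a"))
        assert tpl.seq.startswith(
            "AATTTAATACGACTCACTATAGGATGTCCCTTGAGAACGGGAGGGTTTTAGAG"
        )

    @pytest.mark.parametrize("gene", sorted(PUBLISHED_TARGETS))
    def test_template_length_125(self, gene):
        assert len(build_template(_target(gene)).seq) == 125

    def test_without_pam_length_122_and_no_ngg_junction(self):
        t = _target("gabbr1a")
        tpl = build_template(t, include_pam_in_spacer=False)
        assert len(tpl.seq) == 122
        # spacer runs straight into the scaffold constant
        assert tpl.seq[21:41] == t.seq[:20]
        assert tpl.seq[41:] == SCAFFOLD

    def test_invalid_target_rejected(self):
        bad = GuideTarget.__new__(GuideTarget)
        object.__setattr__(bad, "seq", "AAA")
        object.__setattr__(bad, "gene", "bad")
        with pytest.raises(ValueError):
            build_template(bad)


class TestSplitTemplate:
    def test_six_oligos_three_fragments_lengths_in_range(self):
        oligos, fragments = split_template(build_template(_target()))
        assert len(oligos) == 6
        assert len(fragments) == 3
        assert all(38 <= len(o.seq) <= 46 for o in oligos)

    def test_exactly_two_variable_oligos_both_fragment_1(self):
        oligos, _ = split_template(build_template(_target()))
        variable = oligos.variable_oligos()
        assert len(variable) == 2
        assert {o.fragment for o in variable} == {1}

    def test_outer_ends_blunt(self):
        _, fragments = split_template(build_template(_target()))
        assert fragments[0].left_overhang == BLUNT
        assert fragments[2].right_overhang == BLUNT

    def test_frozen_junctions_for_published_targets(self):
        """The deterministic solver's split for the 125-nt template:
        top-strand cuts at 42/82, bottom-strand cuts at 46/86 (4-nt
        overhangs GGGT and TCCG, both in constant sequence)."""
        tpl = build_template(_target("tmem183a"))
        oligos, fragments = split_template(tpl)
        assert [len(o.seq) for o in oligos] == [42, 46, 40, 40, 43, 39]
        assert fragments[0].top_oligo == tpl.seq[:42]
        assert fragments[1].top_oligo == tpl.seq[42:82]
        assert fragments[0].right_overhang.seq == revcomp("GGGT")
        assert fragments[1].right_overhang.seq == revcomp("TCCG")

    @pytest.mark.parametrize("overhang_len, include_pam", [(3, True), (4, True), (5, False)])
    def test_reassembly_identity_random_targets(self, overhang_len, include_pam):
        """Ligating the three fragments reproduces the template exactly,
        for 100 random valid targets."""
        rng = np.random.default_rng(11)
        n = 100 if overhang_len == 4 else 10
        for _ in range(n):
            tpl = build_template(_random_target(rng),
                                 include_pam_in_spacer=include_pam)
            _, fragments = split_template(tpl, overhang_len=overhang_len)
            products = simulate_ligation(fragments)
            assert len(products) == 1
            (p,) = products
            assert not p.circular
            assert p.top_sequence in (tpl.seq, revcomp(tpl.seq))

    def test_five_nt_overhang_with_pam_geometry_infeasible(self):
        """With the PAM kept, a 5-nt overhang cannot both confine the
        variable bases to fragment 1 and keep oligos <= 46 nt; the solver
        reports the violated constraint instead of emitting a bad design."""
        with pytest.raises(SplitError, match="fragment 1"):
            split_template(build_template(_target()), overhang_len=5)

    def test_variable_region_confined_to_fragment_1(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            tpl = build_template(_random_target(rng))
            oligos, _ = split_template(tpl)
            for o in oligos:
                if o.fragment != 1:
                    # fragments 2/3 must be target-independent
                    assert not o.variable_per_target

    def test_bad_overhang_len_rejected(self):
        with pytest.raises(SplitError):
            split_template(build_template(_target()), overhang_len=2)


class TestDiffOligos:
    def test_two_targets_differ_in_exactly_two_fragment1_oligos(self):
        a, _ = split_template(build_template(_target("gabbr1a")))
        b, _ = split_template(build_template(_target("tmem183a")))
        diff = diff_oligos(a, b)
        assert len(diff) == 2
        assert all(oa.fragment == 1 for oa, _ in diff)

    def test_same_target_empty_diff(self):
        a, _ = split_template(build_template(_target()))
        b, _ = split_template(build_template(_target()))
        assert diff_oligos(a, b) == []

    def test_fragments_2_and_3_identical_across_all_published_targets(self):
        sets = [split_template(build_template(_target(g)))[0]
                for g in sorted(PUBLISHED_TARGETS)]
        for s in sets[1:]:
            for name in ("F2-top", "F2-bottom", "F3-top", "F3-bottom"):
                assert s.by_name(name).seq == sets[0].by_name(name).seq


# --- ligation simulator ------------------------------------------------------


def _frag(i, left, right, core_len=10, rng=None):
    rng = rng or np.random.default_rng(i)
    top = "".join(rng.choice(list("ACGT"), size=core_len))
    return DuplexFragment(index=i, top_oligo=top, bottom_oligo=revcomp(top),
                          left_overhang=left, right_overhang=right)


def _sticky(seq, protruding="bottom", kind="five_prime"):
    return Overhang(seq=seq, protruding=protruding, kind=kind)


class TestSimulateLigation:
    def test_split_output_unique_full_length_linear(self, ):
        tpl = build_template(_target())
        _, fragments = split_template(tpl)
        products = simulate_ligation(fragments)
        linear = [p for p in products if not p.circular]
        circular = [p for p in products if p.circular]
        assert len(linear) == 1 and len(circular) == 0
        assert len(linear[0].top_sequence) == 125

    def test_input_order_never_changes_product_set(self):
        _, fragments = split_template(build_template(_target()))
        base = {(p.chain and len(p.chain), p.circular,
                 p.top_sequence in (None,) or len(p.top_sequence))
                for p in simulate_ligation(fragments)}
        for perm in itertools.permutations(fragments):
            got = {(p.chain and len(p.chain), p.circular,
                    p.top_sequence in (None,) or len(p.top_sequence))
                   for p in simulate_ligation(list(perm))}
            assert got == base

    def test_identical_complementary_overhangs_circularize(self):
        """Two fragments whose matching sticky ends recur on both sides can
        close into a circle — the failure mode the overhang design rules out."""
        oh, mate = _sticky("ACCC"), _sticky(revcomp("ACCC"), protruding="top")
        a = _frag(0, mate, oh)
        b = _frag(1, mate, oh)
        products = simulate_ligation([a, b])
        assert any(p.circular for p in products)

    def test_palindromic_overhang_self_circularizes(self):
        pal = "GATC"  # its own reverse complement
        frag = _frag(0, _sticky(pal, protruding="top"), _sticky(pal))
        products = simulate_ligation([frag])
        assert [p.circular for p in products] == [True]

    def test_blunt_ends_never_ligate(self):
        a = _frag(0, BLUNT, BLUNT)
        b = _frag(1, BLUNT, BLUNT)
        products = simulate_ligation([a, b])
        assert all(len(p.chain) == 1 and not p.circular for p in products)

    def test_kind_mismatch_never_ligates(self):
        a = _frag(0, BLUNT, _sticky("ACCC", kind="five_prime"))
        b = _frag(1, _sticky(revcomp("ACCC"), protruding="top",
                             kind="three_prime"), BLUNT)
        products = simulate_ligation([a, b])
        assert all(len(p.chain) == 1 for p in products)

    def test_matches_factorial_enumeration_oracle(self):
        """Random sticky-end systems of <=4 fragments: the product set equals
        a brute-force enumeration over all orderings and orientations."""
        rng = np.random.default_rng(23)
        overhangs = ["ACCC", "TCCG", "GATC", "AGCT", "TTAA", "CGAT"]
        for trial in range(40):
            n = int(rng.integers(2, 5))
            frags = []
            for i in range(n):
                ends = []
                for _ in range(2):
                    if rng.random() < 0.2:
                        ends.append(BLUNT)
                    else:
                        seq = str(rng.choice(overhangs))
                        if rng.random() < 0.5:
                            seq = revcomp(seq)
                        ends.append(_sticky(
                            seq,
                            protruding=str(rng.choice(["top", "bottom"])),
                        ))
                frags.append(_frag(i, ends[0], ends[1], rng=rng))
            got = {(p.chain, p.circular) for p in simulate_ligation(frags)}
            want = oracle_products(frags)
            assert got == want, f"trial {trial}"


# Independent oracle: enumerate every ordering x orientation of every subset.
def oracle_products(frags):
    n = len(frags)

    def oriented(i, flip):
        return frags[i].flipped() if flip else frags[i]

    def chain_valid(chain):
        for (i, fi), (j, fj) in zip(chain, chain[1:]):
            if not can_ligate(oriented(i, fi).right_overhang,
                              oriented(j, fj).left_overhang):
                return False
        return True

    def canonical_linear(chain):
        rev = tuple((i, not f) for i, f in reversed(chain))
        return min(chain, rev)

    def canonical_circular(chain):
        forms = []
        for r in range(len(chain)):
            rot = chain[r:] + chain[:r]
            forms.append(rot)
            forms.append(tuple((i, not f) for i, f in reversed(rot)))
        return min(forms)

    out = set()
    indices = range(n)
    for k in range(1, n + 1):
        for subset in itertools.permutations(indices, k):
            for flips in itertools.product([False, True], repeat=k):
                chain = tuple(zip(subset, flips))
                if not chain_valid(chain):
                    continue
                used = set(subset)
                # maximal: no unused fragment extends either end
                extendable = False
                for j in indices:
                    if j in used:
                        continue
                    for fj in (False, True):
                        cand = oriented(j, fj)
                        if can_ligate(oriented(*chain[-1]).right_overhang,
                                      cand.left_overhang):
                            extendable = True
                        if can_ligate(cand.right_overhang,
                                      oriented(*chain[0]).left_overhang):
                            extendable = True
                if extendable:
                    continue
                circ = can_ligate(oriented(*chain[-1]).right_overhang,
                                  oriented(*chain[0]).left_overhang)
                if circ:
                    out.add((canonical_circular(chain), True))
                else:
                    out.add((canonical_linear(chain), False))
    return out
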