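"""Dyad-symmetry detection: core hits, arm extension, oracle equivalence,
CNE dyad classification."""

import numpy as np
import pytest

import cnescan as cs
from cnescan.dyad_detect import DSC_SPEC, DSL_SPEC

from conftest import random_dna


def instantiate(rng, pattern):
    """Draw one concrete sequence from an IUPAC pattern."""
    from cnescan.core_types_io import IUPAC_SETS
    return "".join(sorted(IUPAC_SETS[c])[rng.integers(0, len(IUPAC_SETS[c]))]
                   for c in pattern)


def plant_random_dyads(rng, n):
    """Random background with one terminal-style and one central-style dyad
    instance (strictly complementary arms) spliced in."""
    seq = list(random_dna(rng, n, at=0.62))
    inserts = []
    left = instantiate(rng, DSL_SPEC.core_left.symbols)
    inserts.append(left + random_dna(rng, 5) + cs.reverse_complement(left))
    left = instantiate(rng, DSC_SPEC.core_left.symbols)
    spacer = int(rng.integers(DSC_SPEC.spacer_min, DSC_SPEC.spacer_max + 1))
    inserts.append(left + random_dna(rng, spacer) + cs.reverse_complement(left))
    positions = sorted(rng.choice(n // 2 - 30, size=2, replace=False))
    for k, ins in enumerate(inserts):
        p = positions[k] + k * (n // 2)
        seq[p: p + len(ins)] = list(ins)
    return "".join(seq)


class TestFindCoreHits:
    def test_terminal_core_with_five_spacer(self):
        hits = cs.find_core_hits("TTTTTGACGTACAAAAA", DSL_SPEC)
        assert hits == [(0, 11, 5)]

    def test_all_g_sequence_is_empty(self):
        assert cs.find_core_hits("G" * 60, DSL_SPEC) == []

    def test_central_core_with_nine_spacer(self):
        hits = cs.find_core_hits("GAAGACTATCCCCCCCCCATAGTCTTC", DSC_SPEC)
        assert hits == [(0, 18, 9)]
        # verify both cores through the IUPAC oracle
        assert cs.iupac_match("GWAGACTWT", "GAAGACTAT")
        assert cs.iupac_match("AHAGTCTWC", "ATAGTCTTC")

    def test_spacer_window_enforced(self):
        # spacer of 4 must not match the 5-nt terminal spec
        assert cs.find_core_hits("TTTTTGACGTCAAAAA", DSL_SPEC) == []


class TestExtendArms:
    def test_core_ds_with_hostile_flanks_spans_17(self):
        seq = "GG" + "TTTTTGACGTACAAAAA" + "GG"
        el = cs.extend_arms(seq, cs.find_core_hits(seq, DSL_SPEC)[0], DSL_SPEC)
        assert el.arm_length == 6
        assert el.spacer_length == 5
        assert el.total_span == 17

    def test_complementary_flanks_extend_arm_to_8(self):
        seq = "CATTTTTGACGTACAAAAATG"
        el = cs.extend_arms(seq, cs.find_core_hits(seq, DSL_SPEC)[0], DSL_SPEC)
        assert el.arm_length == 8
        assert (el.left_arm, el.right_arm) == ((1, 8), (14, 21))
        # cross-check against the exhaustive enumerator
        oracle = cs.enumerate_inverted_repeats(seq, 6, (5, 5))
        assert any(o.left_arm == el.left_arm and o.arm_length == 8
                   for o in oracle)

    def test_central_core_ds_spans_27(self):
        seq = "GG" + "GAAGACTATCCCCCCCCCATAGTCTTC" + "GG"
        el = cs.extend_arms(seq, cs.find_core_hits(seq, DSC_SPEC)[0], DSC_SPEC)
        assert el.total_span == 27

    def test_extension_never_shrinks_arm(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 120, at=0.6)
            for spec in (DSL_SPEC, DSC_SPEC):
                for cand in cs.find_core_hits(seq, spec):
                    el = cs.extend_arms(seq, cand, spec)
                    assert el.arm_length >= spec.core_len
                    assert el.total_span >= 2 * spec.core_len + cand[2]


class TestEnumerateInvertedRepeats:
    def test_perfect_palindrome(self):
        els = cs.enumerate_inverted_repeats("AAATTT", 3, (0, 0))
        assert len(els) == 1
        assert els[0].arm_length == 3 and els[0].spacer_length == 0

    def test_too_short_arms_yield_nothing(self):
        assert cs.enumerate_inverted_repeats("ACGT", 3, (0, 2)) == []

    def test_length_cap(self):
        with pytest.raises(ValueError):
            cs.enumerate_inverted_repeats("A" * 10_001, 3, (0, 0))

    def test_oracle_contains_extended_core_hits(self, rng):
        """Every strictly-complementary extended dyad appears in the
        exhaustive enumeration with identical geometry. Random backgrounds
        rarely contain core dyads, so instances built from the degenerate
        cores are planted at random positions."""
        checked = 0
        for _ in range(60):
            seq = plant_random_dyads(rng, 250)
            for spec in (DSL_SPEC, DSC_SPEC):
                oracle = cs.enumerate_inverted_repeats(
                    seq, spec.core_len, (spec.spacer_min, spec.spacer_max))
                by_geometry = {(o.left_arm[1], o.spacer_length): o
                               for o in oracle}
                for cand in cs.find_core_hits(seq, spec):
                    lp, rp, spacer = cand
                    core_l = seq[lp: lp + spec.core_len]
                    core_r = seq[rp: rp + spec.core_len]
                    if cs.reverse_complement(core_l) != core_r:
                        continue  # degenerate, non-complementary core pair
                    el = cs.extend_arms(seq, cand, spec)
                    key = (el.left_arm[1], el.spacer_length)
                    assert key in by_geometry
                    o = by_geometry[key]
                    assert o.arm_length == el.arm_length
                    assert o.left_arm == el.left_arm
                    assert o.right_arm == el.right_arm
                    checked += 1
        assert checked >= 20  # the property must actually have been exercised


class TestClassifyCneDyads:
    def test_template_instance_finds_all_three(self, template):
        calls = cs.classify_cne_dyads(template.sequence)
        spans = {el.element_id: (el.start, el.end) for el in template.elements
                 if el.kind == "dyad"}
        for name in ("DSl", "DSc", "DSr"):
            el = calls[name]
            assert el is not None
            # planted coordinates (template spans are 0-based)
            assert (el.start - 1, el.end - 1) == spans[name]

    def test_dsc_ablation_leaves_terminals(self, template):
        seq = list(template.sequence)
        dsc = next(e for e in template.elements if e.element_id == "DSc")
        for j in range(dsc.start, dsc.start + 9):
            seq[j] = "C"  # destroy the left nonamer core
        calls = cs.classify_cne_dyads("".join(seq))
        assert calls["DSc"] is None
        assert calls["DSl"] is not None and calls["DSr"] is not None

    def test_absence_is_legal(self):
        calls = cs.classify_cne_dyads("ACGT" * 40)
        assert set(calls) == {"DSl", "DSc", "DSr"}

    def test_strand_symmetry(self, template):
        fwd = cs.classify_cne_dyads(template.sequence)
        rev = cs.classify_cne_dyads(cs.reverse_complement(template.sequence))
        n = len(template.sequence)
        # DSl and DSr swap with mirrored coordinates; DSc maps to itself
        for a, b in (("DSl", "DSr"), ("DSr", "DSl"), ("DSc", "DSc")):
            fa, rb = fwd[a], rev[b]
            assert fa is not None and rb is not None
            assert (rb.start, rb.end) == (n - fa.end + 1, n - fa.start + 1)

    def test_degenerate_fallback_cores(self):
        # TTATTG/CAATAA terminal variant is picked up by the fallback list
        seq = "GG" + "TTATTGACGTACAATAA" + ("C" * 30) + \
              "TTATTGTTGCACAATAA" + "GG"
        calls = cs.classify_cne_dyads(seq)
        assert calls["DSl"] is not None and calls["DSr"] is not None
        calls_strict = cs.classify_cne_dyads(seq, use_degenerate_fallback=False)
        assert calls_strict["DSr"] is None

    def test_total_span_at_least_17_for_terminals(self, small_family):
        seqs, _ = small_family
        for s in seqs:
            calls = cs.classify_cne_dyads(s.residues)
            for name in ("DSl", "DSr"):
                if calls[name] is not None:
                    assert calls[name].total_span >= 17


class TestDyadSpecValidation:
    def test_incompatible_core_pair_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            cs.DyadSpec("bad", cs.IupacPattern("TTTTTG"),
                        cs.IupacPattern("TTTTTT"), 5, 5)

    def test_published_pairs_validate(self):
        # AHAGTCTWC is broader than the literal reverse complement of
        # GWAGACTWT at one position; compatibility (set intersection) holds
        assert DSC_SPEC.core_right.symbols == "AHAGTCTWC"
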