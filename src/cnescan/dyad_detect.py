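"""Dyad-symmetry element (DS) detection.

A DS is a pair of inverted repeats (arms) separated by a non-symmetric
spacer. The CNE carries three: terminal DSl and DSr, whose degenerate core
arms are WTTWTG in forward and reverse orientation around a 5-nt spacer
(a 17-bp "core DS"), and a central DSc with nonameric cores GWAGACTWT /
AHAGTCTWC around a 9-10-nt spacer (a 27-bp "core DSc"). Arms extend beyond
the core wherever the flanking bases remain Watson-Crick complementary;
extension is strict (no mismatches) by default, with a configurable
allowance for the handful of naturally degenerate species variants
(TTATTG/CAATAA arms, CAAAAT cores).

An exhaustive inverted-repeat enumerator is included as an independent
oracle for small sequences.
"""

from __future__ import annotations

import dataclasses

from .core_types_io import (
    IUPAC_SETS,
    IupacPattern,
    NucleotideSequence,
    iupac_find,
    iupac_match,
    reverse_complement,
)

__all__ = [
    "DyadSpec",
    "DyadElement",
    "DSL_SPEC",
    "DSC_SPEC",
    "DSR_SPEC",
    "DEGENERATE_TERMINAL_SPECS",
    "find_core_hits",
    "extend_arms",
    "enumerate_inverted_repeats",
    "classify_cne_dyads",
]

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclasses.dataclass(frozen=True)
class DyadSpec:
    """Degenerate core inverted-repeat pair with a spacer-length window."""

    name: str
    core_left: IupacPattern
    core_right: IupacPattern
    spacer_min: int
    spacer_max: int

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max or self.spacer_min < 0:
            raise ValueError("need 0 <= spacer_min <= spacer_max")
        if len(self.core_left) != len(self.core_right):
            raise ValueError("core arms must have equal length")
        # core_right must be compatible with the reverse complement of
        # core_left: at every position the two base sets intersect. Set
        # equality is NOT required; published core pairs differ in breadth
        # at some positions (e.g. AHAGTCTWC vs the literal AWAGTCTWC).
        rc = reverse_complement(self.core_left.symbols)
        for i, (a, b) in enumerate(zip(rc, self.core_right.symbols)):
            if not (IUPAC_SETS[a] & IUPAC_SETS[b]):
                raise ValueError(
                    f"core_right incompatible with reverse complement of "
                    f"core_left at position {i + 1} ({b} vs {a})"
                )

    @property
    def core_len(self) -> int:
        return len(self.core_left)


# Published CNE dyad specs: terminal cores WTTWTG / reverse around exactly
# 5 nt; central cores GWAGACTWT / AHAGTCTWC around 9-10 nt.
DSL_SPEC = DyadSpec("DSl", IupacPattern("WTTWTG"),
                    IupacPattern(reverse_complement("WTTWTG")), 5, 5)
DSR_SPEC = DyadSpec("DSr", IupacPattern("WTTWTG"),
                    IupacPattern(reverse_complement("WTTWTG")), 5, 5)
DSC_SPEC = DyadSpec("DSc", IupacPattern("GWAGACTWT"),
                    IupacPattern("AHAGTCTWC"), 9, 10)

# Fallbacks for the four species whose terminal cores deviate from WTTWTG:
# symmetric T-A/A-T substitutions give TTATTG/CAATAA arms.
DEGENERATE_TERMINAL_SPECS = [
    DyadSpec("DS-degenerate", IupacPattern("TTATTG"),
             IupacPattern("CAATAA"), 5, 5),
]


@dataclasses.dataclass(frozen=True)
class DyadElement:
    """A located DS: arm/spacer geometry in 1-based coordinates of the
    searched sequence. left/right arm intervals are (start, end) inclusive."""

    seq_id: str
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    arm_length: int
    spacer_length: int
    core_matched: str
    mismatches: tuple[int, ...] = ()   # empty under strict extension

    @property
    def total_span(self) -> int:
        return 2 * self.arm_length + self.spacer_length

    @property
    def start(self) -> int:
        return self.left_arm[0]

    @property
    def end(self) -> int:
        return self.right_arm[1]

    def __post_init__(self) -> None:
        assert self.total_span == self.end - self.start + 1


def find_core_hits(seq: "NucleotideSequence | str", spec: DyadSpec
                   ) -> list[tuple[int, int, int]]:
    """All (left_pos, right_pos, spacer_length) core placements, 0-based
    left-arm / right-arm start offsets, in left-to-right order."""
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    k = spec.core_len
    hits = []
    for lp in iupac_find(spec.core_left, s):
        for spacer in range(spec.spacer_min, spec.spacer_max + 1):
            rp = lp + k + spacer
            if rp + k > len(s):
                continue
            if iupac_match(spec.core_right, s[rp: rp + k]):
                hits.append((lp, rp, spacer))
    hits.sort()
    return hits


def extend_arms(seq: "NucleotideSequence | str",
                candidate: tuple[int, int, int],
                spec: DyadSpec,
                max_mismatch: int = 0) -> DyadElement:
    """Grow arms symmetrically outward from the cores one bp at a time while
    the outer left base Watson-Crick pairs with the outer right base; stop at
    the first failure (or after max_mismatch tolerated failures) or at a
    sequence boundary."""
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    sid = seq.id if isinstance(seq, NucleotideSequence) else ""
    lp, rp, spacer = candidate
    k = spec.core_len
    ext = 0
    mism: list[int] = []
    budget = max_mismatch
    while True:
        li = lp - ext - 1
        ri = rp + k + ext
        if li < 0 or ri >= len(s):
            break
        a, b = s[li], s[ri]
        if a in _WC and _WC[a] == b:
            ext += 1
        elif budget > 0 and a in "ACGT" and b in "ACGT":
            budget -= 1
            mism.append(li + 1)
            ext += 1
        else:
            break
    # trim trailing mismatches: an arm never ends on a tolerated mismatch
    while mism and mism[-1] == lp - ext + 1:
        mism.pop()
        ext -= 1
    arm = k + ext
    return DyadElement(
        seq_id=sid,
        left_arm=(lp - ext + 1, lp + k),
        right_arm=(rp + 1, rp + k + ext),
        arm_length=arm,
        spacer_length=spacer,
        core_matched=spec.name,
        mismatches=tuple(mism),
    )


def enumerate_inverted_repeats(seq: "NucleotideSequence | str",
                               min_arm: int,
                               spacer_range: tuple[int, int]
                               ) -> list[DyadElement]:
    """Exhaustive maximal inverted repeats: for every (position, spacer)
    pair, extend complementary arms as far as possible and keep those with
    arm >= min_arm. Intended as a brute-force oracle; capped at 10 kb."""
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    sid = seq.id if isinstance(seq, NucleotideSequence) else ""
    if len(s) > 10_000:
        raise ValueError("enumerate_inverted_repeats is capped at 10,000 bp")
    lo, hi = spacer_range
    out = []
    for spacer in range(lo, hi + 1):
        # inner edge of the left arm at offset e-1; right arm starts at e+spacer
        for e in range(1, len(s)):
            if e + spacer >= len(s):
                break
            # extend outward from the innermost pair
            arm = 0
            while True:
                li = e - arm - 1
                ri = e + spacer + arm
                if li < 0 or ri >= len(s):
                    break
                a = s[li]
                if a in _WC and _WC[a] == s[ri]:
                    arm += 1
                else:
                    break
            if arm >= min_arm:
                out.append(DyadElement(
                    seq_id=sid,
                    left_arm=(e - arm + 1, e),
                    right_arm=(e + spacer + 1, e + spacer + arm),
                    arm_length=arm,
                    spacer_length=spacer,
                    core_matched="enumerated",
                ))
    out.sort(key=lambda d: (d.start, d.spacer_length))
    return out


def _select_non_overlapping(elements: list[DyadElement]) -> list[DyadElement]:
    """Overlap policy: keep the longest arm; ties go to the leftmost."""
    chosen: list[DyadElement] = []
    for el in sorted(elements, key=lambda d: (-d.arm_length, d.start)):
        if all(el.end < c.start or el.start > c.end for c in chosen):
            chosen.append(el)
    chosen.sort(key=lambda d: d.start)
    return chosen


def classify_cne_dyads(cne_seq: "NucleotideSequence | str",
                       max_mismatch: int = 0,
                       use_degenerate_fallback: bool = True
                       ) -> dict[str, "DyadElement | None"]:
    """Locate DSl, DSc and DSr within a CNE-scale sequence.

    Terminal-spec hits are deduplicated by the overlap policy, then the
    leftmost is assigned to DSl and the rightmost to DSr; the best (longest
    arm, then leftmost) central-spec hit becomes DSc. Missing elements are
    None. When a terminal DS is missing under the primary WTTWTG spec, the
    degenerate-core fallback specs (TTATTG/CAATAA arm variants) are tried.
    """
    s = cne_seq.residues if isinstance(cne_seq, NucleotideSequence) else cne_seq.upper()

    def _terminal_hits(specs: list[DyadSpec]) -> list[DyadElement]:
        found = []
        for sp in specs:
            for cand in find_core_hits(s, sp):
                found.append(extend_arms(s, cand, sp, max_mismatch))
        return _select_non_overlapping(found)

    terminals = _terminal_hits([DSL_SPEC])
    if len(terminals) < 2 and use_degenerate_fallback:
        terminals = _terminal_hits([DSL_SPEC] + DEGENERATE_TERMINAL_SPECS)

    result: dict[str, DyadElement | None] = {"DSl": None, "DSc": None, "DSr": None}
    if terminals:
        left = terminals[0]
        result["DSl"] = dataclasses.replace(left, core_matched="DSl")
        if len(terminals) > 1:
            right = terminals[-1]
            result["DSr"] = dataclasses.replace(right, core_matched="DSr")

    central = [extend_arms(s, c, DSC_SPEC, max_mismatch)
               for c in find_core_hits(s, DSC_SPEC)]
    if central:
        best = sorted(central, key=lambda d: (-d.arm_length, d.start))[0]
        result["DSc"] = dataclasses.replace(best, core_matched="DSc")
    return result
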