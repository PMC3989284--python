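"""CNE architecture model, AT statistics, ORF overlap analysis, and a
both-strand genome scanner for CNE-like loci.

The architecture model is an ordered list of elements (three dyads, the TAT
clusters between them) with a window of admissible start offsets for each
element relative to the locus start, plus a total-length window (default
154-157 bp). A candidate window scores one point per element found at a
position consistent with the offset windows, minus a small penalty
(lambda, default 0.1/bp) for spacing violations; the default calling
threshold of 5 demands all three dyads plus at least two of the three TAT
clusters. These weights operationalise the qualitative architecture
conservation of the element; they are exposed in configuration, not claims
about the biology.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import yaml

from .conservation_profile import (
    ConsensusProfile,
    ConservedCluster,
)
from .core_types_io import (
    IUPAC_SETS,
    GenomicInterval,
    IupacPattern,
    NucleotideSequence,
    iupac_find,
    reverse_complement,
)
from .dyad_detect import (
    DSC_SPEC,
    DSL_SPEC,
    DSR_SPEC,
    DyadSpec,
    find_core_hits,
)
from .msa_identity import Alignment
from .synthetic_data import CneTemplate, default_cne_template

__all__ = [
    "AtStats",
    "OrfRecord",
    "ArchElement",
    "CneArchitecture",
    "ScanHit",
    "at_content",
    "at_enrichment",
    "find_orfs",
    "overlap_classify",
    "build_model",
    "architecture_from_template",
    "score_window",
    "scan_genome",
    "model_to_yaml",
    "model_from_yaml",
]


# ---------------------------------------------------------------------------
# AT content

@dataclasses.dataclass(frozen=True)
class AtStats:
    region_at: float        # percent
    background_at: float    # percent
    enrichment: float       # percentage points (region - background)
    is_at_rich: bool        # region > 50% AND region > background


def at_content(seq: "NucleotideSequence | str") -> float:
    """Percent A+T among unambiguous bases; NaN when no A/C/G/T present."""
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    return 100.0 * (counts["A"] + counts["T"]) / total


def at_enrichment(region_seq: "NucleotideSequence | str",
                  background_seq: "NucleotideSequence | str") -> AtStats:
    """Two-part AT-richness test: the region must exceed 50% AT and exceed
    its background (the resident genome)."""
    r = at_content(region_seq)
    b = at_content(background_seq)
    rich = bool(r > 50.0 and r > b)
    return AtStats(region_at=r, background_at=b, enrichment=r - b, is_at_rich=rich)


# ---------------------------------------------------------------------------
# ORFs

_STOPS = {"TAA", "TAG", "TGA"}


@dataclasses.dataclass(frozen=True)
class OrfRecord:
    """A complete ORF: ATG through in-frame stop, length in bp including the
    stop codon. Coordinates are 1-based inclusive on the forward strand."""

    interval: GenomicInterval
    frame: int           # 0/1/2 on the strand the ORF is read from
    length: int          # bp, divisible by 3

    def __post_init__(self) -> None:
        assert self.length % 3 == 0
        assert self.length == self.interval.end - self.interval.start + 1


def find_orfs(seq: "NucleotideSequence | str", min_len: int = 150,
              include_incomplete: bool = False) -> list[OrfRecord]:
    """Scan all six reading frames for ORFs of at least min_len bp.

    An ORF runs from the first ATG after the previous in-frame stop to the
    next in-frame stop (maximal ORFs; nested ATGs are not reported
    separately). ORFs truncated by the sequence end (no stop) are skipped
    unless include_incomplete is set, in which case their length excludes
    any partial codon. Results are sorted by forward-strand start.
    """
    s = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    sid = seq.id if isinstance(seq, NucleotideSequence) else ""
    out: list[OrfRecord] = []
    L = len(s)

    def scan_strand(strand_seq: str, strand: str) -> None:
        for frame in range(3):
            start_atg: int | None = None
            i = frame
            while i + 3 <= len(strand_seq):
                codon = strand_seq[i: i + 3]
                if codon in _STOPS and start_atg is not None:
                    length = i + 3 - start_atg
                    if length >= min_len:
                        out.append(_mk_record(sid, start_atg, i + 2, frame,
                                              strand, L, length))
                    start_atg = None
                elif codon == "ATG" and start_atg is None:
                    start_atg = i
                i += 3
            if include_incomplete and start_atg is not None:
                last_full = start_atg + 3 * ((len(strand_seq) - start_atg) // 3)
                length = last_full - start_atg
                if length >= min_len:
                    out.append(_mk_record(sid, start_atg, last_full - 1, frame,
                                          strand, L, length))

    scan_strand(s, "+")
    scan_strand(reverse_complement(s), "-")
    out.sort(key=lambda o: (o.interval.start, o.interval.strand))
    return out


def _mk_record(sid: str, a0: int, b0: int, frame: int, strand: str,
               total_len: int, length: int) -> OrfRecord:
    if strand == "+":
        iv = GenomicInterval(sid or "seq", a0 + 1, b0 + 1, "+")
    else:
        iv = GenomicInterval(sid or "seq", total_len - b0, total_len - a0, "-")
    return OrfRecord(interval=iv, frame=frame, length=length)


def overlap_classify(orf: "OrfRecord | GenomicInterval",
                     region: GenomicInterval) -> str:
    """Interval relation of an ORF to a region (strandless):
    'none', 'partial', 'region_contains_orf' or 'orf_contains_region'.
    Identical intervals classify as orf_contains_region (containment of the
    region is checked first)."""
    o = orf.interval if isinstance(orf, OrfRecord) else orf
    if o.seq_id != region.seq_id:
        raise ValueError(f"seq_id mismatch: {o.seq_id!r} vs {region.seq_id!r}")
    if o.start <= region.start and region.end <= o.end:
        return "orf_contains_region"
    if region.start <= o.start and o.end <= region.end:
        return "region_contains_orf"
    if o.start <= region.end and region.start <= o.end:
        return "partial"
    return "none"


# ---------------------------------------------------------------------------
# Architecture model

@dataclasses.dataclass(frozen=True)
class ArchElement:
    """One ordered model element with its admissible start-offset window
    (0-based offsets relative to the locus start, inclusive)."""

    element_id: str
    kind: str                      # 'dyad' | 'tat_cluster' | 'conserved_cluster'
    pattern: "IupacPattern | None" = None
    dyad_spec: "DyadSpec | None" = None
    offset_min: int = 0
    offset_max: int = 0

    def __post_init__(self) -> None:
        if (self.pattern is None) == (self.dyad_spec is None):
            raise ValueError("element needs exactly one of pattern / dyad_spec")
        if self.offset_min < 0 or self.offset_max < self.offset_min:
            raise ValueError("bad offset window")

    def occurrences(self, window: str) -> list[int]:
        if self.dyad_spec is not None:
            return [lp for lp, _rp, _sp in find_core_hits(window, self.dyad_spec)]
        return iupac_find(self.pattern, window)


@dataclasses.dataclass
class CneArchitecture:
    """Ordered element template with offset windows and total length window."""

    elements: list[ArchElement]
    length_min: int = 154
    length_max: int = 157

    def __post_init__(self) -> None:
        if len(self.elements) < 2:
            raise ValueError("architecture needs at least 2 elements")
        offs = [e.offset_min for e in self.elements]
        if offs != sorted(offs):
            raise ValueError("elements must be ordered by offset")
        if self.length_min > self.length_max or self.length_min < 1:
            raise ValueError("bad total length window")

    @property
    def max_score(self) -> float:
        return float(len(self.elements))

    def spacing_windows(self) -> list[tuple[str, str, int, int]]:
        """(from, to, min, max) start-to-start spacing between neighbours."""
        out = []
        for a, b in zip(self.elements, self.elements[1:]):
            out.append((a.element_id, b.element_id,
                        b.offset_min - a.offset_max,
                        b.offset_max - a.offset_min))
        return out


@dataclasses.dataclass(frozen=True)
class ScanHit:
    """A genome locus matching the architecture."""

    interval: GenomicInterval
    score: float
    at_content: float                     # fraction in [0,1]
    matched: dict[str, "int | None"]      # element -> found offset (0-based)

    @property
    def n_found(self) -> int:
        return sum(1 for v in self.matched.values() if v is not None)


def architecture_from_template(template: "CneTemplate | None" = None,
                               offset_slack: int = 4) -> CneArchitecture:
    """Build the default architecture directly from the annotated template,
    widening each element's start offset by offset_slack bp on each side to
    absorb inter-cluster spacing variation."""
    tpl = template or default_cne_template()
    elements = []
    for el in tpl.elements:
        seq = tpl.sequence[el.start: el.end + 1]
        if el.kind == "dyad":
            spec = DSC_SPEC if el.element_id == "DSc" else (
                DSL_SPEC if el.element_id == "DSl" else DSR_SPEC)
            elements.append(ArchElement(
                el.element_id, "dyad", dyad_spec=spec,
                offset_min=max(0, el.start - offset_slack),
                offset_max=el.start + offset_slack,
            ))
        else:
            elements.append(ArchElement(
                el.element_id, el.kind, pattern=IupacPattern(seq),
                offset_min=max(0, el.start - offset_slack),
                offset_max=el.start + offset_slack,
            ))
    # up to 3 bp of total deletion relative to the template
    return CneArchitecture(elements=elements,
                           length_min=min(len(tpl) - 3, 154),
                           length_max=max(len(tpl), 157))


@dataclasses.dataclass(frozen=True)
class ColumnSpan:
    """1-based inclusive span in alignment-column space."""

    start: int
    end: int


def consensus_dyads(aln: Alignment) -> dict[str, "ColumnSpan | None"]:
    """Locate DSl/DSc/DSr in alignment-column space by majority vote.

    Each family member is classified individually (on its ungapped sequence);
    the member coordinates are lifted to alignment columns and, per dyad, the
    most common column span wins (ties to the leftmost). A dyad found in
    fewer than half the members is reported as absent.
    """
    from collections import Counter

    from .dyad_detect import classify_cne_dyads

    votes: dict[str, Counter] = {n: Counter() for n in ("DSl", "DSc", "DSr")}
    for _rid, gapped in aln.records:
        residues = gapped.replace("-", "")
        pos_to_col = [j + 1 for j, c in enumerate(gapped) if c != "-"]
        calls = classify_cne_dyads(residues)
        for name, el in calls.items():
            if el is None:
                continue
            votes[name][(pos_to_col[el.start - 1], pos_to_col[el.end - 1])] += 1
    out: dict[str, ColumnSpan | None] = {}
    half = aln.n_records / 2
    for name, counter in votes.items():
        if not counter or counter.most_common(1)[0][1] < half:
            out[name] = None
            continue
        best = max(counter.items(), key=lambda kv: (kv[1], -kv[0][0]))
        out[name] = ColumnSpan(*best[0])
    return out


def _degenerate_pattern(profile: ConsensusProfile, start: int, end: int,
                        min_frac: float = 0.25) -> IupacPattern:
    """Collapse profile columns to IUPAC codes: bases reaching min_frac of
    the non-gap residues enter the code set."""
    inv = {v: k for k, v in IUPAC_SETS.items()}
    symbols = []
    for j in range(start, end + 1):
        col = profile.columns[j]
        total = sum(col.counts.values())
        if total == 0:
            symbols.append("N")
            continue
        allowed = frozenset(b for b in "ACGT"
                            if col.counts[b] / total >= min_frac)
        if not allowed:
            allowed = frozenset(col.modal_base)
        symbols.append(inv[allowed])
    return IupacPattern("".join(symbols))


def build_model(profile: ConsensusProfile,
                clusters: list[ConservedCluster],
                dyads: dict[str, "object | None"],
                aln: Alignment,
                tolerance: int = 1) -> CneArchitecture:
    """Assemble an architecture from a family's profile, conserved clusters
    and consensus-level dyad calls.

    dyads maps DSl/DSc/DSr to DyadElement-like objects whose start/end are
    1-based positions in *consensus column* space (i.e. detected on a gapless
    family representative aligned to the profile) or None when absent.
    Offset windows are the per-sequence min/max ungapped start offsets of
    each element observed in the alignment, widened by the tolerance.
    """
    if len(clusters) + sum(1 for v in dyads.values() if v) < 2:
        raise ValueError("architecture needs at least 2 elements")

    # alignment-column spans for each element; dyad spans shadow the clusters
    # they cover
    spans: list[tuple[str, str, int, int, "DyadSpec | None"]] = []
    dyad_cols: list[tuple[int, int]] = []
    for name, el in dyads.items():
        if el is None:
            continue
        spec = DSC_SPEC if name == "DSc" else (DSL_SPEC if name == "DSl" else DSR_SPEC)
        spans.append((name, "dyad", el.start - 1, el.end - 1, spec))
        dyad_cols.append((el.start - 1, el.end - 1))
    for cl in clusters:
        # clusters overlapping a dyad span are that dyad's arms (possibly
        # widened by coincidentally conserved flanking columns)
        covered = any(cl.start_col <= b and a <= cl.end_col
                      for a, b in dyad_cols)
        if covered:
            cl.category = "dyad-arm"
            continue
        kind = "tat_cluster" if cl.category == "TAT-containing" else "conserved_cluster"
        spans.append((cl.label, kind, cl.start_col, cl.end_col, None))
    spans.sort(key=lambda t: t[2])

    # per-sequence ungapped offsets of each element start
    rows = [s for _, s in aln.records]
    elements: list[ArchElement] = []
    prev_min = 0
    for name, kind, c0, c1, spec in spans:
        offs = []
        for s in rows:
            if all(c == "-" for c in s[c0:c1 + 1]):
                continue
            offs.append(sum(1 for c in s[:c0] if c != "-"))
        if not offs:
            continue
        omin = max(0, min(offs) - tolerance, prev_min)  # keep element order
        omax = max(max(offs) + tolerance, omin)
        if spec is not None:
            el = ArchElement(name, "dyad", dyad_spec=spec,
                             offset_min=omin, offset_max=omax)
        else:
            pat = _degenerate_pattern(profile, c0, c1)
            el = ArchElement(name, kind, pattern=pat,
                             offset_min=omin, offset_max=omax)
        prev_min = omin
        elements.append(el)

    lengths = [len(s.replace("-", "")) for s in rows]
    return CneArchitecture(
        elements=elements,
        length_min=min(lengths) - tolerance,
        length_max=max(lengths) + tolerance,
    )


# ---------------------------------------------------------------------------
# Scoring and scanning

def score_window(window_seq: str, model: CneArchitecture,
                 lam: float = 0.1, off_slack: int = 5
                 ) -> tuple[float, dict[str, "int | None"]]:
    """Score one candidate locus against the model.

    Each element found with its pattern/spec at an offset inside its window
    contributes 1; an occurrence within off_slack bp of the window still
    counts but accrues a lambda-weighted spacing violation; otherwise the
    element is absent. Returns (score, per-element found offsets).
    """
    w = window_seq.upper()
    score = 0.0
    matched: dict[str, int | None] = {}
    for el in model.elements:
        occ = el.occurrences(w)
        if not occ:
            matched[el.element_id] = None
            continue
        best_off, best_v = None, None
        for o in occ:
            v = max(el.offset_min - o, o - el.offset_max, 0)
            if best_v is None or v < best_v:
                best_off, best_v = o, v
        if best_v == 0:
            score += 1.0
            matched[el.element_id] = best_off
        elif best_v <= off_slack:
            score += 1.0 - lam * best_v
            matched[el.element_id] = best_off
        else:
            matched[el.element_id] = None
    return score, matched


def _candidate_starts(strand_seq: str, model: CneArchitecture,
                      off_slack: int) -> set[int]:
    """Window starts anchored on occurrences of the model's dyad elements
    anywhere in the strand sequence."""
    starts: set[int] = set()
    n = len(strand_seq)
    for el in model.elements:
        if el.dyad_spec is None:
            continue
        for lp, _rp, _sp in find_core_hits(strand_seq, el.dyad_spec):
            lo = lp - el.offset_max - off_slack
            hi = lp - el.offset_min + off_slack
            for w0 in range(max(0, lo), min(hi, n - model.length_min) + 1):
                starts.add(w0)
    return starts


def scan_genome(genome: NucleotideSequence, model: CneArchitecture,
                threshold: float = 5.0, lam: float = 0.1,
                off_slack: int = 5, circular: bool = False) -> list[ScanHit]:
    """Slide model-length windows over both strands and report non-overlapping
    hits with score >= threshold, greedy by score then leftmost.

    Scanning is anchored on dyad-core occurrences (any hit above the default
    threshold must contain at least two of the three dyads, so anchoring on
    all of them loses nothing). Circular genomes are scanned on an
    end-wrapped copy extended by (max window - 1) bases; a hit whose interval
    runs past the sequence end wraps around the origin.
    """
    fwd = genome.residues
    L = len(fwd)
    if L < model.length_max:
        raise ValueError("genome shorter than the model's maximum length")
    if circular:
        fwd = fwd + fwd[: model.length_max - 1]
    rev = reverse_complement(fwd)

    raw: list[ScanHit] = []
    for strand, s in (("+", fwd), ("-", rev)):
        for w0 in sorted(_candidate_starts(s, model, off_slack)):
            for lw in range(model.length_min, model.length_max + 1):
                if w0 + lw > len(s):
                    continue
                window = s[w0: w0 + lw]
                score, matched = score_window(window, model, lam, off_slack)
                if score < threshold:
                    continue
                if strand == "+":
                    start0, end0 = w0, w0 + lw - 1
                else:
                    end0 = len(s) - 1 - w0
                    start0 = end0 - lw + 1
                if start0 >= L:      # pure duplicate inside the wrap copy
                    continue
                raw.append(ScanHit(
                    interval=GenomicInterval(genome.id, start0 + 1, end0 + 1,
                                             strand),
                    score=score,
                    at_content=at_content(window) / 100.0,
                    matched=matched,
                ))

    # greedy non-overlap selection by score, then leftmost, then strand
    raw.sort(key=lambda h: (-h.score, h.interval.start, h.interval.strand))
    chosen: list[ScanHit] = []
    for h in raw:
        if all(h.interval.end < c.interval.start or h.interval.start > c.interval.end
               for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.interval.start)
    return chosen


# ---------------------------------------------------------------------------
# Model serialization (human-readable YAML)

def model_to_yaml(model: CneArchitecture, path: str) -> None:
    doc = {
        "length_window": [model.length_min, model.length_max],
        "elements": [],
    }
    for el in model.elements:
        d: dict = {
            "id": el.element_id,
            "kind": el.kind,
            "offset_window": [el.offset_min, el.offset_max],
        }
        if el.dyad_spec is not None:
            d["dyad"] = {
                "core_left": el.dyad_spec.core_left.symbols,
                "core_right": el.dyad_spec.core_right.symbols,
                "spacer": [el.dyad_spec.spacer_min, el.dyad_spec.spacer_max],
            }
        else:
            d["pattern"] = el.pattern.symbols
        doc["elements"].append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def model_from_yaml(path: str) -> CneArchitecture:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    elements = []
    for d in doc["elements"]:
        omin, omax = d["offset_window"]
        if "dyad" in d:
            dy = d["dyad"]
            spec = DyadSpec(d["id"], IupacPattern(dy["core_left"]),
                            IupacPattern(dy["core_right"]),
                            int(dy["spacer"][0]), int(dy["spacer"][1]))
            elements.append(ArchElement(d["id"], d["kind"], dyad_spec=spec,
                                        offset_min=omin, offset_max=omax))
        else:
            elements.append(ArchElement(d["id"], d["kind"],
                                        pattern=IupacPattern(d["pattern"]),
                                        offset_min=omin, offset_max=omax))
    lo, hi = doc["length_window"]
    return CneArchitecture(elements=elements, length_min=lo, length_max=hi)
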