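"""Synthetic CNE families and host genomes with known ground truth.

The generator emulates the statistical shape of the published family: a
155-bp template carrying, left to right, a terminal dyad (DSl: WTTWTG core,
5-nt conserved spacer, reverse core), a TAT cluster (c2), a TAT-ending
cluster (c3), a central dyad (DSc: GWAGACTWT core, 9-nt spacer, AHAGTCTWC
core, i.e. clusters c4/c5), another TAT cluster (c6) and a terminal dyad
(DSr). Conserved (cluster) columns never mutate; the variable inter-cluster
segments mutate with an AT-biased substitution process and may lose 0-3 bp
per segment, reproducing the narrow 1-3 bp inter-cluster spacing variation
seen in the real family. Length variation is realised as deletions drawn
per inter-element segment, so the template coordinate system doubles as the
true alignment.

A single integer seed governs all randomness; identical spec + seed gives
byte-identical output.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_types_io import (
    Alignment,
    GenomicInterval,
    NucleotideSequence,
    reverse_complement,
)

__all__ = [
    "CneTemplate",
    "TemplateElement",
    "FamilySpec",
    "GenomeSpec",
    "FamilyTruth",
    "default_cne_template",
    "simulate_family",
    "simulate_genome",
]


@dataclasses.dataclass(frozen=True)
class TemplateElement:
    """One annotated template element in 0-based template coordinates
    (end inclusive)."""

    element_id: str
    kind: str          # 'dyad' | 'tat_cluster' | 'conserved_cluster'
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass(frozen=True)
class CneTemplate:
    """Template string + element annotations + mutability masks.

    soft_columns mark partially conserved context: in the real family the
    bare TAT triplets sit among positions conserved at the 50%-or-better
    level (the lowercase letters of the published consensus, e.g. cluster 2
    reads gTAgTaTAT), not in free-drifting sequence. Soft columns mutate at
    a reduced rate so the triplets remain alignable, as they evidently are
    in the real alignment.
    """

    sequence: str
    elements: tuple[TemplateElement, ...]
    conserved_columns: tuple[int, ...]   # 0-based absolutely conserved columns
    variable_segments: tuple[tuple[int, int], ...]  # deletable inter-element runs
    cluster_spans: tuple[tuple[str, int, int], ...]  # truth for segmentation
    soft_columns: tuple[int, ...] = ()   # partially conserved context

    def __len__(self) -> int:
        return len(self.sequence)


def default_cne_template() -> CneTemplate:
    """The deterministic 155-bp CNE-like template (within the 154-157 bp
    length class of the real element)."""
    # Variable segments never start with the base that ends the preceding
    # cluster: deletions are placed in variable segments only, and a shared
    # boundary base would let an alignment gap slide (at equal score) into
    # the cluster columns, eroding conservation the family actually has.
    parts = [
        ("v0", "TGA", False),
        ("DSl", "TTTTTG" "AATCA" "CAAAAA", True),        # 17 bp terminal dyad
        ("v1", "GTACAGTTAAACGATG", False),
        ("c2", "TAT", True),
        ("v2", "CTGAACATAGATCAA", False),
        ("c3", "TGTTAT", True),                           # TAT-ending cluster
        ("v3", "ACGATTAAAGTGCA", False),
        ("c4", "GAAGACTAT", True),                        # DSc left arm
        ("sc", "TTGACCATA", False),                       # DSc 9-nt spacer
        ("c5", "ATAGTCTTC", True),                        # DSc right arm
        ("v4", "AATCGTATTAACAGA", False),
        ("c6", "TAT", True),
        ("v5", "CACGAATTATAGCATA", False),
        ("DSr", "TTTTTG" "TCGAA" "CAAAAA", True),         # 17 bp terminal dyad
        ("v6", "ACA", False),
    ]
    seq = "".join(p[1] for p in parts)
    assert 154 <= len(seq) <= 157

    pos = 0
    spans: dict[str, tuple[int, int]] = {}
    conserved: list[int] = []
    for name, chunk, is_conserved in parts:
        spans[name] = (pos, pos + len(chunk) - 1)
        if is_conserved:
            conserved.extend(range(pos, pos + len(chunk)))
        pos += len(chunk)

    # partially conserved context flanking the short TAT triplets (3 columns
    # either side), mirroring the 50%-conserved positions around them in the
    # published consensus
    soft: list[int] = []
    for name in ("c2", "c6"):
        a, b = spans[name]
        soft.extend(range(a - 3, a))
        soft.extend(range(b + 1, b + 4))

    # c4 + spacer + c5 compose the central dyad DSc
    dsc_span = (spans["c4"][0], spans["c5"][1])
    elements = (
        TemplateElement("DSl", "dyad", *spans["DSl"]),
        TemplateElement("c2", "tat_cluster", *spans["c2"]),
        TemplateElement("c3", "tat_cluster", *spans["c3"]),
        TemplateElement("DSc", "dyad", *dsc_span),
        TemplateElement("c6", "tat_cluster", *spans["c6"]),
        TemplateElement("DSr", "dyad", *spans["DSr"]),
    )
    # only inter-element variable runs may shrink (not the terminal flanks,
    # not the conserved DSl/DSr internal spacers, not the DSc spacer whose
    # length is constrained to 9-10 nt by the dyad definition)
    variable_segments = tuple(spans[v] for v in ("v1", "v2", "v3", "v4", "v5"))
    cluster_spans = tuple(
        (name, spans[name][0], spans[name][1])
        for name in ("DSl", "c2", "c3", "c4", "c5", "c6", "DSr")
    )
    return CneTemplate(
        sequence=seq,
        elements=elements,
        conserved_columns=tuple(conserved),
        variable_segments=variable_segments,
        cluster_spans=cluster_spans,
        soft_columns=tuple(soft),
    )


@dataclasses.dataclass
class FamilySpec:
    """Conditions for one simulated homolog family.

    sub_rate may be a scalar (applied to every variable column) or a
    per-column vector of length len(template); conserved columns are always
    forced to 0. at_bias is the stationary A+T fraction of substituted bases.
    indel_range bounds the per-sequence TOTAL deletion budget (bp), spent at
    random positions within the inter-element segments, reproducing both the
    1-3 bp inter-cluster spacing variation and the narrow total-length band
    of the real family.
    """

    template: CneTemplate = dataclasses.field(default_factory=default_cne_template)
    n_sequences: int = 38
    sub_rate: "float | np.ndarray" = 0.2
    indel_range: tuple[int, int] = (0, 3)
    at_bias: float = 0.63
    soft_factor: float = 0.3    # rate multiplier on partially conserved columns
    seed: int = 0

    def rate_vector(self) -> np.ndarray:
        n = len(self.template)
        rates = np.full(n, float(self.sub_rate)) if np.isscalar(self.sub_rate) \
            else np.asarray(self.sub_rate, dtype=float).copy()
        if rates.shape != (n,):
            raise ValueError("per-column rate vector length mismatch")
        if (rates < 0).any() or (rates > 1).any():
            raise ValueError("substitution probabilities must lie in [0,1]")
        if self.template.soft_columns:
            rates[list(self.template.soft_columns)] *= self.soft_factor
        rates[list(self.template.conserved_columns)] = 0.0
        return rates

    def validate(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")
        lo, hi = self.indel_range
        if lo < 0 or hi < lo:
            raise ValueError("indel range must be non-negative and ordered")
        if not (0 < self.at_bias < 1):
            raise ValueError("at_bias must lie in (0,1)")
        self.rate_vector()


@dataclasses.dataclass
class FamilyTruth:
    """Ground truth of a simulated family."""

    alignment: Alignment                     # template-coordinate alignment
    element_coords: dict[str, dict[str, tuple[int, int]]]
    # element_coords[seq_id][element_id] = 1-based inclusive coords in that
    # sequence's own (ungapped) coordinate system
    conserved_columns: tuple[int, ...]       # alignment columns, 0-based
    n_clusters: int


def simulate_family(spec: FamilySpec
                    ) -> tuple[list[NucleotideSequence], FamilyTruth]:
    """Draw a family from the template; returns sequences plus ground truth
    (true alignment in template coordinates, per-sequence element coords)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tpl = spec.template
    n_cols = len(tpl)
    rates = spec.rate_vector()
    base_idx = {b: i for i, b in enumerate("ACGT")}
    # AT-biased substitution target distribution
    p_at = spec.at_bias
    target = np.array([p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2, p_at / 2])

    seqs: list[NucleotideSequence] = []
    gapped_rows: list[tuple[str, str]] = []
    coords: dict[str, dict[str, tuple[int, int]]] = {}
    lo, hi = spec.indel_range

    for k in range(spec.n_sequences):
        row = list(tpl.sequence)
        # substitutions at variable columns: replacement differs from the
        # original base, drawn AT-biased among the other three
        do_sub = rng.random(n_cols) < rates
        for j in np.nonzero(do_sub)[0]:
            orig = base_idx[row[j]]
            w = target.copy()
            w[orig] = 0.0
            w /= w.sum()
            row[j] = "ACGT"[rng.choice(4, p=w)]
        # deletions: a per-sequence total budget of indel_range bp spread over
        # the inter-element segments, so family lengths stay within the
        # narrow band the real element shows (its total length is conserved
        # to within a few bp)
        deleted: set[int] = set()
        d_total = int(rng.integers(lo, hi + 1))
        deletable = [j for a, b in tpl.variable_segments
                     for j in range(a, b + 1)]
        if d_total > 0:
            picks = rng.choice(len(deletable), size=min(d_total, len(deletable)),
                               replace=False)
            deleted.update(deletable[p] for p in picks)
        gapped = "".join("-" if j in deleted else row[j] for j in range(n_cols))
        residues = gapped.replace("-", "")
        sid = f"synth{k + 1:02d}"
        seqs.append(NucleotideSequence(sid, residues))
        gapped_rows.append((sid, gapped))

        # map template coords -> ungapped 1-based coords
        prefix = np.cumsum([0 if j in deleted else 1 for j in range(n_cols)])
        coords[sid] = {
            el.element_id: (int(prefix[el.start]), int(prefix[el.end]))
            for el in tpl.elements
        }

    truth = FamilyTruth(
        alignment=Alignment(gapped_rows),
        element_coords=coords,
        conserved_columns=tpl.conserved_columns,
        n_clusters=len(tpl.cluster_spans),
    )
    return seqs, truth


# ---------------------------------------------------------------------------
# Genomes


def _shuffled_cne(rng: np.random.Generator) -> str:
    tpl = default_cne_template().sequence
    chars = np.array(list(tpl))
    rng.shuffle(chars)
    return "".join(chars)


def _decoy_sequence(kind: str, rng: np.random.Generator) -> str:
    if kind == "lone_DS":
        # a single terminal core DS with nothing else around it
        return "TTTTTG" + "AATCA" + "CAAAAA"
    if kind == "shuffled_CNE":
        return _shuffled_cne(rng)
    if kind == "tandem_TAT":
        return "TAT" * 8
    raise ValueError(f"unknown decoy kind {kind!r}")


@dataclasses.dataclass
class GenomeSpec:
    """Conditions for one synthetic host genome.

    plants: (sequence, 1-based start position or None for random, strand).
    decoys: decoy kind names, placed at random non-overlapping positions.
    """

    length: int = 50_000
    gc: float = 0.43
    plants: list[tuple[str, "int | None", str]] = dataclasses.field(default_factory=list)
    decoys: list[str] = dataclasses.field(default_factory=list)
    circular: bool = False
    seq_id: str = "synthetic_genome"
    seed: int = 0

    def validate(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be positive")
        if not (0 < self.gc < 1):
            raise ValueError("gc must lie in (0,1)")
        for seq, pos, strand in self.plants:
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r}")
            if pos is not None and not (1 <= pos <= self.length - len(seq) + 1):
                raise ValueError(f"plant at {pos} does not fit in genome")


def simulate_genome(spec: GenomeSpec
                    ) -> tuple[NucleotideSequence, list[tuple[GenomicInterval, str]]]:
    """i.i.d. background at the stated GC with planted elements and decoys
    spliced in at recorded coordinates. Returns the genome and a truth list
    of (interval, label); labels are 'cne' for plants, decoy kind otherwise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    at = 1 - spec.gc
    probs = np.array([at / 2, spec.gc / 2, spec.gc / 2, at / 2])
    genome = list("".join(np.array(list("ACGT"))[rng.choice(4, spec.length, p=probs)]))

    items: list[tuple[str, "int | None", str, str]] = [
        (seq.upper(), pos, strand, "cne") for seq, pos, strand in spec.plants
    ]
    for kind in spec.decoys:
        items.append((_decoy_sequence(kind, rng), None, "+", kind))

    occupied: list[tuple[int, int]] = []  # 0-based half-open
    for seq, pos, strand, _label in items:
        if pos is None:
            continue
        s0 = pos - 1
        _claim(occupied, s0, s0 + len(seq), spec.length)

    truth: list[tuple[GenomicInterval, str]] = []
    for seq, pos, strand, label in items:
        if pos is None:
            s0 = _random_slot(rng, occupied, len(seq), spec.length)
        else:
            s0 = pos - 1
        insert = reverse_complement(seq) if strand == "-" else seq
        genome[s0: s0 + len(seq)] = list(insert)
        truth.append((GenomicInterval(spec.seq_id, s0 + 1, s0 + len(seq), strand),
                      label))
    truth.sort(key=lambda t: t[0].start)
    return NucleotideSequence(spec.seq_id, "".join(genome)), truth


def _claim(occupied: list[tuple[int, int]], s0: int, e0: int, length: int) -> None:
    if e0 > length:
        raise ValueError("planted element does not fit in the genome")
    for a, b in occupied:
        if s0 < b and a < e0:
            raise ValueError("overlap between planted items")
    occupied.append((s0, e0))


def _random_slot(rng: np.random.Generator, occupied: list[tuple[int, int]],
                 size: int, length: int, max_tries: int = 1000) -> int:
    for _ in range(max_tries):
        s0 = int(rng.integers(0, length - size + 1))
        try:
            _claim(occupied, s0, s0 + size, length)
            return s0
        except ValueError:
            continue
    raise ValueError("could not place item without overlap")
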