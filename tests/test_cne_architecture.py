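"""AT statistics, ORF calling, architecture scoring and genome scanning."""

import numpy as np
import pytest

import cnescan as cs
from cnescan.cne_architecture import architecture_from_template, score_window

from conftest import random_dna


class TestAtContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATAT", 100.0),
        ("ACGT", 50.0),
        ("AANNTT", 100.0),   # ambiguous bases excluded from both sides
    ])
    def test_examples(self, seq, expected):
        assert cs.at_content(seq) == pytest.approx(expected)

    def test_undefined_on_all_ambiguous(self):
        assert np.isnan(cs.at_content("NNNN"))

    def test_invariant_under_reverse_complement(self, rng):
        for _ in range(30):
            s = random_dna(rng, int(rng.integers(10, 300)), at=0.55)
            assert cs.at_content(s) == pytest.approx(
                cs.at_content(cs.reverse_complement(s)))


class TestAtEnrichment:
    def test_at_rich_region(self):
        st = cs.at_enrichment("ATATAT", "ACGTACGT")
        assert st.is_at_rich and st.enrichment == pytest.approx(50.0)

    def test_region_equal_background_not_enriched(self):
        st = cs.at_enrichment("ACGTAT", "ACGTAT")
        assert st.enrichment == 0.0 and not st.is_at_rich

    def test_two_part_criterion(self):
        # above background but below 50% AT is not AT-rich
        st = cs.at_enrichment("ACGCACGA", "GCGCGCGC")
        assert st.region_at < 50 and st.enrichment > 0 and not st.is_at_rich


def brute_force_orfs(seq, min_len):
    """Independent codon-walk oracle: for each strand and each ATG that
    directly follows a stop (or the frame start), walk to the first in-frame
    stop."""
    stops = {"TAA", "TAG", "TGA"}
    found = []
    L = len(seq)
    for strand, s in (("+", seq), ("-", cs.reverse_complement(seq))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, len(s) - 2, 3)]
            open_idx = None
            for k, codon in enumerate(codons):
                if codon in stops:
                    if open_idx is not None:
                        length = 3 * (k - open_idx + 1)
                        if length >= min_len:
                            a0 = frame + 3 * open_idx
                            b0 = frame + 3 * k + 2
                            if strand == "+":
                                found.append((a0 + 1, b0 + 1, "+", length))
                            else:
                                found.append((L - b0, L - a0, "-", length))
                        open_idx = None
                    continue
                if codon == "ATG" and open_idx is None:
                    open_idx = k
    return sorted(found)


class TestFindOrfs:
    def test_279bp_construct(self, rng):
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if a + b + c not in ("TAA", "TAG", "TGA", "ATG")]
        body = "".join(rng.choice(codons) for _ in range(91))
        seq = "TAATAGTGA" + "ATG" + body + "TAA" + "TAGTAATAG"
        orfs = [o for o in cs.find_orfs(seq, min_len=150)
                if o.interval.strand == "+"]
        assert len(orfs) == 1
        assert orfs[0].length == 279

    def test_poly_a_has_no_complete_orf(self):
        assert cs.find_orfs("A" * 600, min_len=150) == []
        # ... unless truncated ORFs are requested (none start: no ATG)
        assert cs.find_orfs("ATG" + "A" * 300, min_len=150,
                            include_incomplete=True)[0].length == 303

    def test_reverse_complement_mirrors_orf_set(self, rng):
        s = random_dna(rng, 900, at=0.5)
        L = len(s)
        fwd = {(o.interval.start, o.interval.end, o.interval.strand, o.length)
               for o in cs.find_orfs(s, min_len=90)}
        mirrored = {(L - e + 1, L - a + 1, "-" if st == "+" else "+", ln)
                    for a, e, st, ln in fwd}
        rev = {(o.interval.start, o.interval.end, o.interval.strand, o.length)
               for o in cs.find_orfs(cs.reverse_complement(s), min_len=90)}
        assert rev == mirrored

    def test_agrees_with_codon_walk_oracle(self, rng):
        for _ in range(8):
            s = random_dna(rng, 1000, at=0.5)
            got = sorted((o.interval.start, o.interval.end, o.interval.strand,
                          o.length) for o in cs.find_orfs(s, min_len=60))
            assert got == brute_force_orfs(s, 60)


class TestOverlapClassify:
    def test_acmnpv_orf_contains_cne(self):
        orf = cs.GenomicInterval("AcMNPV", 132109, 132387)
        cne = cs.GenomicInterval("AcMNPV", 132228, 132383)
        assert cs.overlap_classify(orf, cne) == "orf_contains_region"

    def test_eupsnpv_partial(self):
        assert cs.overlap_classify(cs.GenomicInterval("e", 5295, 5465),
                                   cs.GenomicInterval("e", 5241, 5395)) == "partial"

    def test_disjoint_and_contained(self):
        r = cs.GenomicInterval("g", 100, 200)
        assert cs.overlap_classify(cs.GenomicInterval("g", 300, 400), r) == "none"
        assert cs.overlap_classify(cs.GenomicInterval("g", 120, 180), r) == \
            "region_contains_orf"

    def test_seq_mismatch(self):
        with pytest.raises(ValueError):
            cs.overlap_classify(cs.GenomicInterval("a", 1, 9),
                                cs.GenomicInterval("b", 1, 9))


class TestScoreWindow:
    def test_exact_template_is_maximal(self, template):
        model = architecture_from_template()
        score, matched = score_window(template.sequence, model)
        assert score == model.max_score == 6.0
        assert all(v is not None for v in matched.values())

    def test_dsc_ablation_costs_exactly_one(self, template):
        model = architecture_from_template()
        seq = list(template.sequence)
        dsc = next(e for e in template.elements if e.element_id == "DSc")
        for j in range(dsc.start, dsc.start + 9):
            seq[j] = "C"
        score, matched = score_window("".join(seq), model)
        assert matched["DSc"] is None
        assert score == model.max_score - 1.0

    def test_shuffled_composition_scores_below_threshold(self, template):
        model = architecture_from_template()
        rng = np.random.default_rng(5)
        chars = np.array(list(template.sequence))
        below = 0
        for _ in range(200):
            rng.shuffle(chars)
            score, _ = score_window("".join(chars), model)
            if score < 5.0:
                below += 1
        assert below >= 190  # >= 95% of shuffles


class TestBuildModel:
    def test_model_from_simulated_family(self):
        spec = cs.FamilySpec(sub_rate=0.1, seed=21)
        seqs, truth = cs.simulate_family(spec)
        aln = truth.alignment
        prof = cs.column_profiles(aln)
        clusters = cs.segment_clusters(prof)
        dyads = cs.consensus_dyads(aln)
        model = cs.build_model(prof, clusters, dyads, aln)
        assert [e.element_id for e in model.elements] == \
               ["DSl", "c2", "c3", "DSc", "c6", "DSr"]
        assert model.length_min >= 154 - 16 and model.length_max <= 158
        # model must recognise its own family members
        for s in seqs[:5]:
            score, _ = score_window(s.residues, model)
            assert score >= 5.0

    def test_spacing_windows_reflect_planted_jitter(self):
        spec = cs.FamilySpec(sub_rate=0.1, seed=22)
        _, truth = cs.simulate_family(spec)
        prof = cs.column_profiles(truth.alignment)
        clusters = cs.segment_clusters(prof)
        model = cs.build_model(prof, clusters,
                               cs.consensus_dyads(truth.alignment),
                               truth.alignment, tolerance=0)
        for el in model.elements:
            assert el.offset_max - el.offset_min <= 15  # cumulative 5x3 bp

    def test_too_few_elements_rejected(self):
        aln = cs.Alignment([("a", "ACGT"), ("b", "ACGT")])
        prof = cs.column_profiles(aln)
        with pytest.raises(ValueError):
            cs.build_model(prof, [], {"DSl": None, "DSc": None, "DSr": None},
                           aln)


def plant_genome(seed, plant_seq, strand, pos=20001, decoys=()):
    spec = cs.GenomeSpec(length=40_000, gc=0.43,
                         plants=[(plant_seq, pos, strand)],
                         decoys=list(decoys), seed=seed)
    return cs.simulate_genome(spec)


class TestScanGenome:
    def test_recovers_plus_strand_plant(self, template):
        genome, truth = plant_genome(101, template.sequence, "+")
        hits = cs.scan_genome(genome, architecture_from_template())
        assert len(hits) == 1
        planted = next(iv for iv, lab in truth if lab == "cne")
        h = hits[0]
        assert h.interval.strand == "+"
        assert abs(h.interval.start - planted.start) <= 6
        assert abs(h.interval.end - planted.end) <= 6

    def test_recovers_minus_strand_plant(self, template):
        genome, truth = plant_genome(102, template.sequence, "-")
        hits = cs.scan_genome(genome, architecture_from_template())
        assert len(hits) == 1
        planted = next(iv for iv, lab in truth if lab == "cne")
        assert hits[0].interval.strand == "-"
        assert abs(hits[0].interval.start - planted.start) <= 6

    def test_decoys_not_called(self, template):
        spec = cs.GenomeSpec(length=40_000, gc=0.43,
                             decoys=["lone_DS", "shuffled_CNE", "tandem_TAT"],
                             seed=103)
        genome, _ = cs.simulate_genome(spec)
        assert cs.scan_genome(genome, architecture_from_template()) == []

    def test_reverse_complement_mirrors_hits(self, template):
        genome, _ = plant_genome(104, template.sequence, "+")
        model = architecture_from_template()
        hits = cs.scan_genome(genome, model)
        rc = cs.NucleotideSequence(genome.id,
                                   cs.reverse_complement(genome.residues))
        rc_hits = cs.scan_genome(rc, model)
        L = len(genome.residues)
        mirrored = sorted((L - h.interval.end + 1, L - h.interval.start + 1,
                           "-" if h.interval.strand == "+" else "+")
                          for h in hits)
        got = sorted((h.interval.start, h.interval.end, h.interval.strand)
                     for h in rc_hits)
        # same loci and strand mapping; boundaries may differ by the window
        # placement ambiguity among equal-scoring starts
        assert len(got) == len(mirrored)
        for (gs, ge, gst), (ms, me, mst) in zip(got, mirrored):
            assert gst == mst
            assert abs(gs - ms) <= 10 and abs(ge - me) <= 10

    def test_hits_never_overlap(self, template):
        # two plants close together; greedy selection keeps them disjoint
        spec = cs.GenomeSpec(length=30_000, gc=0.43,
                             plants=[(template.sequence, 10_001, "+"),
                                     (template.sequence, 10_400, "+")],
                             seed=105)
        genome, _ = cs.simulate_genome(spec)
        hits = cs.scan_genome(genome, architecture_from_template())
        assert len(hits) == 2
        for a, b in zip(hits, hits[1:]):
            assert a.interval.end < b.interval.start

    def test_circular_wrap(self, template):
        # plant crossing the origin is only found with circular scanning
        tpl = template.sequence
        background = cs.simulate_genome(cs.GenomeSpec(length=20_000, gc=0.43,
                                                      seed=106))[0].residues
        genome_seq = tpl[80:] + background[200:-200] + tpl[:80]
        genome = cs.NucleotideSequence("circ", genome_seq)
        model = architecture_from_template()
        assert cs.scan_genome(genome, model, circular=False) == []
        hits = cs.scan_genome(genome, model, circular=True)
        assert len(hits) == 1
        assert hits[0].interval.start > len(genome_seq) - 160


class TestModelSerialization:
    def test_yaml_round_trip(self, tmp_path, template):
        model = architecture_from_template()
        path = tmp_path / "model.yaml"
        cs.model_to_yaml(model, str(path))
        back = cs.model_from_yaml(str(path))
        assert [e.element_id for e in back.elements] == \
               [e.element_id for e in model.elements]
        score_a, _ = score_window(template.sequence, model)
        score_b, _ = score_window(template.sequence, back)
        assert score_a == score_b
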