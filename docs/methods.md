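# Methods

This note documents the models, conventions and numerical choices behind
cnescan, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates

External I/O and all reports use GenBank convention: 1-based, inclusive on
both ends, as genome annotations print them (the AcMNPV element at
132228–132383 has length 132383 − 132228 + 1 = 156 bp). Internal
arithmetic is 0-based half-open; conversion happens only at the boundary
(`to_zero_based` / `from_zero_based`), and BED output is 0-based half-open
per the format. Minus-strand intervals are interpreted as placements on
the reverse strand; flank expansion (`expand_flanks`) applies up/downstream
in transcriptional orientation, i.e. mirrored on the minus strand.

## Alignment (`msa_identity`)

`align_family` is a classical progressive aligner: pairwise k-mer (k = 3)
distances feed a UPGMA (average-linkage, scipy) guide tree; sub-alignments
are merged with a Gotoh affine-gap dynamic program over column-vs-column
substitution scores (mean pairwise score between the two columns' residues,
gaps excluded; a length-d gap costs `open + (d−1)·extend`).

Defaults: match +1, mismatch −1, gap open 5, gap extend 1. These are
deliberately simple; they are adequate for families of 150–200 bp
homologs at 60–100% identity and are all configurable. DP tie-breaking is
fixed (diagonal, then gap in the second profile, then gap in the first;
guide-tree ties resolve by input order), so alignments are bit-reproducible.

The progressive pass is followed by (default) two rounds of leave-one-out
refinement: each row is realigned against the profile of the remaining
rows, keeping the existing columns; all-gap columns are then dropped.
Refinement uses *linear*, column-weighted gap costs (a gap is cheaper in a
column where the other rows are also gapped). The rationale: with the
column set fixed, the number of gapped bases per row is constant, so
linear costs make gap placement depend purely on profile agreement. An
affine merge bonus (open − extend) would instead pull two nearby deletions
together across any conserved anchor shorter than ~4 bp — exactly the
failure mode that destroys the element's 3-bp TAT clusters. Greedy
progressive merges cannot revisit early gap placements; the refinement
pass corrects that, in the spirit of the iterative-refinement stage of
standard MSA tools.

Percent identity is computed over co-aligned columns (both rows non-gap):
`100 · #(equal ∧ both non-gap) / #(both non-gap)`. Columns where either
row is gapped do not enter the denominator; a pair with no co-aligned
columns is reported missing (NaN), never 0. This choice is configurable in
the sense that the raw alignment is exposed; note the published 66–100%
family range was produced by a different tool whose identity definition is
not documented, so small shifts against it are expected.

## Conservation profile (`conservation_profile`)

Per column: base counts over non-gap residues, gap count, coverage, modal
base and frequency, information content `R = 2 − H` bits (Shannon entropy
of non-gap base frequencies). No small-sample correction is applied — at
family sizes near 38 it is minor, and omitting it keeps logo heights
exactly reproducible. A display value scaled by the non-gap coverage
fraction is carried alongside (`ic_display`), used by the bar-plot helper.

Consensus characters follow the field's display convention: '.' where the
majority of rows are gapped (gap fraction > 0.5); uppercase modal base at
complete conservation (modal frequency = 1.0); lowercase at ≥ 50%;
otherwise 'n'. A tie between two modal bases at the threshold renders 'n'.
All three thresholds are parameters.

**Absolutely conserved** means modal frequency exactly 1.0 over non-gap
residues AND a gap-free, N-free column; `allow_gaps=True` relaxes the gap
condition. Cluster segmentation groups absolutely conserved columns into
maximal runs in which consecutive conserved columns are separated by at
most `max_intervening` (default 2) non-conserved columns, then discards
runs with fewer than `min_conserved` (default 3) conserved columns. The
defaults are this package's operationalisation of cluster boxes that were
originally drawn by eye; both knobs are exposed on the CLI. Clusters whose
consensus contains TAT are tagged TAT-containing; clusters overlapping a
dyad location are tagged dyad-arm by the architecture builder.

Inter-cluster spacing is measured per family member as the number of that
member's residues strictly between adjacent cluster spans; a member whose
cluster span is fully deleted yields a missing value.

## Dyad detection (`dyad_detect`)

A `DyadSpec` holds a degenerate core pair and a spacer window. The two
shipped terminal specs use `WTTWTG` and its reverse complement `CAWAAW`
at exactly 5 nt spacing; the central spec uses `GWAGACTWT`/`AHAGTCTWC` at
9–10 nt. Validation requires the right core to be *compatible* with the
reverse complement of the left core (non-empty base-set intersection at
every position) rather than identical, because the published central pair
is broader than a literal reverse complement at one position.

`find_core_hits` anchors on forward-strand core matches; `extend_arms`
grows both arms outward one base at a time while the outer bases are
Watson–Crick complementary, stopping at the first failure or the sequence
boundary. Extension is strict by default; a mismatch allowance
(`max_mismatch`, default 0) exists for the four species with degenerate
cores but is off by default, and an arm never ends on a tolerated
mismatch. With hostile flanks this yields exactly the 17-bp terminal core
DS and the 27-bp central core DS.

`classify_cne_dyads` deduplicates overlapping terminal hits (longest arm
wins, ties to the leftmost), assigns the leftmost to DSl and the rightmost
to DSr, and the best central hit to DSc; when fewer than two terminal
dyads are found with the primary core, the degenerate fallback cores
(TTATTG/CAATAA) are tried. Absence is a legal result. Note that `WTTWTG`
does not actually subsume the TTATTG variant (position 3 differs), which
is why the fallback list is explicit.

`enumerate_inverted_repeats` is a brute-force enumerator over every
(inner-boundary, spacer) pair, kept deliberately independent of the
detector; it is the oracle in the equivalence tests and is capped at
10 kb.

## Architecture model and scanner (`cne_architecture`)

A `CneArchitecture` is an ordered list of elements — dyad specs and IUPAC
cluster patterns — each with a window of admissible start offsets relative
to the locus start, plus a total-length window (default 154–157 bp).
`build_model` derives the windows from a family: per-member ungapped start
offsets of each element observed in the alignment, widened by a tolerance
(default ±1 bp); cluster patterns collapse profile columns to IUPAC codes
(bases at ≥ 25% of non-gap residues enter the code). Dyad locations in
column space come from `consensus_dyads` (per-member classification lifted
to columns, majority vote). `architecture_from_template` builds the
default model directly from the simulator's annotated template with ±4 bp
offset slack.

`score_window` gives one point per element found inside its offset window;
an occurrence within `off_slack` (default 5) bp of the window still counts
but accrues a penalty of λ (default 0.1) per bp of violation; anything
further is absent. The default calling threshold of 5 on the 6-element
model demands all three dyads plus at least two TAT clusters. The score,
weights and threshold are this package's operationalisation of
architecture conservation — they are configuration, not biology — and the
permutation test (composition-preserving shuffles score below threshold in
≥ 95% of cases) is the calibration check.

`scan_genome` slides windows of every admissible length over both strands.
Candidate starts are anchored on dyad-core occurrences: any hit at the
default threshold must contain at least two of the three dyads, so
anchoring on all dyad elements loses nothing and reduces the scan from
O(genome × windows) to a handful of candidate loci. Hits are selected
greedily (score, then leftmost) without overlap. Circular genomes are
scanned on an end-wrapped copy extended by (max window − 1) bases; a hit
interval may then run past the sequence end, meaning it wraps the origin.
Where several overlapping window placements score identically, the
reported boundaries are tie-dependent; mirror-image scans therefore agree
on locus and strand but may differ by a few bp in boundary placement.

ORFs are ATG-initiated, stop-terminated, length counted in bp including
the stop codon (a 279-bp ORF = 92 codons + stop, consistent with
baculovirus annotation practice); maximal ORFs only (the first ATG after
the previous in-frame stop). Sequence-end-truncated ORFs are excluded by
default (`include_incomplete` flag to include, with partial codons
trimmed). All six frames are scanned; reverse-strand ORFs are reported in
forward coordinates with strand '−'. AT content is `100·(A+T)/(A+C+G+T)`
with ambiguity codes excluded from both numerator and denominator, and the
AT-richness call uses the two-part criterion: region > 50% AND region >
background.

## Synthetic data (`synthetic_data`)

The generator's defaults define the test conditions. The 155-bp annotated
template carries, in order: DSl (TTTTTG + conserved 5-nt spacer +
CAAAAA, 17 bp), TAT cluster c2, TAT-ending cluster c3 (TGTTAT), DSc
(GAAGACTAT + 9-nt spacer + ATAGTCTTC, 27 bp, arms = clusters c4/c5), TAT
cluster c6, and DSr (17 bp) — 7 conserved clusters totalling 64 absolutely
conserved columns, 78% of them A/T, separated by free-drifting variable
segments. Two intentional design constraints on the fixed filler sequence:
variable segments never begin with the base that ends the preceding
cluster (a shared boundary base would let alignment gaps slide into
cluster columns at no cost), and the bases immediately flanking each dyad
are non-complementary so the planted core arms are also the maximal arms.

Families of (default) 38 members are drawn column-wise: conserved columns
never mutate; variable columns substitute with probability `sub_rate`
(default 0.2), replacements drawn AT-biased (target A+T fraction 0.63,
matching the element's observed AT-richness) among the three other bases.
The six columns flanking each bare TAT triplet mutate at 0.3× the base
rate, emulating the partially conserved (≥ 50%, lowercase-consensus)
context those triplets actually sit in; without that context a 3-bp anchor
in otherwise free sequence is not reliably alignable by any method, which
would misrepresent the real family. Length variation is realised as a
per-sequence total deletion budget of 0–3 bp (uniform), spent at random
positions within the inter-element segments only: this reproduces both the
1–3 bp inter-cluster spacing variation and the narrow 154–157 bp
total-length band. Deletions-only (no insertions) keeps the template
coordinate system as the true alignment. One integer seed drives
everything; identical spec + seed is byte-identical.

Host genomes are i.i.d. background at a stated GC fraction (default 0.43,
mid-range for the genus) with planted elements spliced at recorded,
non-overlapping coordinates (reverse-complemented for minus-strand
plants) and optional decoys: a lone terminal core DS, a
composition-preserving shuffle of the template, and a TAT tandem.

What the generator does **not** emulate: phylogenetic correlation between
family members (members are i.i.d. around the template, so identity
distributions are narrower than a real clade's); insertions; context
dependence of the substitution process; real intergenic sequence
composition around planted elements; and genome-scale features (genes,
repeats, homologous regions). Passing recovery tests therefore show the
pipeline is correct under the stated statistical conditions, not that it
is robust to every property of real genomes.

Simulation sizes used by the test suite and the acceptance script — 20
families of 38 members spanning substitution rates 0.05–0.25 (pairwise
identities roughly 70–100%), and 8 decoy-bearing 30-kb genomes — were
chosen to exercise the published divergence range at problem sizes the
pipeline handles in about a minute.

## Known limitations

* The aligner is O(L²) per merge and intended for CNE-scale families
  (≤ a few hundred bp, ≤ ~100 members), not genome-length alignments.
* Exact reproduction of the published 66–100% identity range would require
  the original alignment tool's (undocumented) identity definition; the
  co-aligned-column definition used here is stated above and exposed via
  the alignment itself.
* The scanner's score is a rank statistic, not a calibrated probability;
  no background model or E-value is attached.
* Dyad arm statistics count strictly complementary arms only (default);
  whether published arm-length figures tolerate internal degeneracies is
  not derivable from the text, so the mismatch allowance is explicit and
  off by default.
* Table-scale coordinate fixtures beyond the AcMNPV row are not bundled:
  several published coordinate pairs are internally inconsistent
  (apparent typographic errors), so loaders must not assume they validate.
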