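# Methods

This note documents the models, algorithms, parameters and numerical
choices behind `protqc`, and what the synthetic-data experiments do and
do not demonstrate.

## Problem setting

A predicted proteome from a newly annotated genome is audited against a
trusted reference proteome of a closely related species.  The pipeline
assumes: (i) the reference proteins are correct; (ii) target proteins
are linked to CDS-only gene models (ordered coding exon intervals with
strand) on genomic contigs; (iii) orthologs are close enough (> 80%
identity) that disagreement between an ortholog and its reference is
evidence of a prediction artifact rather than true divergence.
Coordinates are 0-based half-open internally; GFF3 I/O converts to and
from 1-based closed at the boundary.  Minus-strand gene models store
exons in transcript (5′→3′) order, i.e. genomically decreasing, because
all downstream logic is transcript-centric.

## Orthology

Each reference protein is searched against each target proteome with
exact Smith–Waterman (Gotoh affine-gap DP via Biopython's
`PairwiseAligner`): BLOSUM62, gap open 11, extend 1 (a gap of length L
costs 11 + L).  Exactness replaces heuristic seeded search: at this
scale it is affordable and removes any seed dependence.  An optional
shared-6-mer prefilter skips targets with no exact 6-mer in common with
the query; any pair that could pass the identity threshold shares many
6-mers, and a dedicated test verifies prefiltered and unfiltered runs
agree.  Significance uses the Karlin–Altschul form E = K·m·n·e^(−λS)
with gapped BLOSUM62 constants K = 0.041, λ = 0.267; m is the query
length, n the summed target-proteome length.  Absolute E-values from
different tools are not comparable — only the thresholding behavior
(E < 10⁻⁵⁰, identity > 80%, best raw score per reference protein, score
ties broken by lexicographic target id) is meaningful here.

## Reference-anchored alignment

Orthologs of one reference protein are aligned by the star method: each
ortholog is globally aligned to the reference (free end gaps) and the
pairwise alignments are merged on reference coordinates; insertions
relative to the reference occupy shared reference-gap columns,
left-justified.  The MSA scheme uses stiffer gaps (open 20, extend 2)
than the local search: within an alignment used for error calling, gaps
should model genuine indels — with cheap gaps the aligner shreds
non-homologous (wrong-frame) segments into scattered short gap runs and
spurious residue pairings, hiding exactly the signal being sought.
Ungapping any row reproduces its input sequence exactly (tested as an
invariant).

## Error detection

Orthologs more than `length_ratio_max` (3.0) times longer or shorter
than the reference are excluded before alignment (strict inequality:
exactly 3× is kept).  Each remaining row is scanned per column class
(aligned pair / insertion / deletion, projected over columns where the
reference or the row has a residue):

* leading/trailing insertion columns → N-/C-terminal extension;
  leading/trailing deletion columns → N-/C-terminal deletion;
* internal gap runs of ≥ `indel_min_len` (5 aa) → internal
  insertion/deletion.  The minimum suppresses single-gap alignment
  jitter and is applied to terminal calls as well;
* mismatched segments: the internal region is decomposed into disjoint
  maximal-scoring segments where a non-identical aligned column scores
  +t, an identical one −(1−t), and a gap column 0, with t the identity
  threshold (0.50).  A segment's aligned-column identity is strictly
  below t exactly when its score is positive, so the decomposition
  (recursive best-segment splitting, deterministic leftmost-longest
  tie-break) yields segments that are below threshold, start and end on
  non-identical columns, and bridge gap runs only when low-identity
  material flanks them.  Segments with ≥ `mismatch_min_len` (20)
  aligned columns are reported.

Two boundary conventions are fixed deliberately: 20 aligned columns are
eligible (non-strict) and identity exactly 50.0% is *not* a mismatch
(strict).  'X' residues never count as identical.

The maximal-scoring-segment formulation was chosen over naive greedy
window extension because greedy extension under an aggregate-identity
rule absorbs roughly one well-conserved flanking column per mismatching
column before crossing 50%, systematically bloating segments by the
length of the true error and mislocalizing the downstream correction.
Scoring-based segmentation is the standard remedy for this family of
problems and keeps segments tight.

## Characterization and classification

Nine features are computed per mismatch; evidence classes are fixed per
feature.

Gene-misprediction evidence: (1) any 'N' in the transcript's full
genomic span — introns included, because assembly gaps commonly sit
outside the mispredicted exon itself; (2) any intron < 30 nt, the
minimum length a spliceosome can process; (3) one reference exon facing
≥ `exon_split_min` (3) target exons over the segment; (4) non-GT/AG
splice sites on reference introns adjacent to the exons coding the
corresponding reference segment (strand-aware); (5) a target exon whose
length differs from its reference counterpart by a non-multiple of 3
(the net indel of a nucleotide-level global alignment equals the length
difference, so it is computed directly).

Exon correspondence for (3) and (5) uses dominant overlap rather than
exact counts: a mismatch's mapped span can be displaced by up to the
aligned gap length (gap placement inside a non-homologous region is
arbitrary), and junction-straddling codons contribute 1–2 nt overlaps
to neighboring exons.  Overlaps below 6 nt are ignored; where several
reference exons overlap, the one covering the majority of the span is
taken as the counterpart.

False-positive evidence: (6) an alternative reference isoform to which
the segment aligns locally at ≥ 50% identity over ≥ 80% of its length —
the segment would not have been a mismatch against that isoform; (7)
the mismatch dissolves (≥ 50% identity over its residues) when the two
full-length proteins are realigned pairwise with the MSA gap scheme;
(8) ≥ 50% of the segment covered by exact tandem repeats of period ≤ 6
(autocorrelation scan, ≥ 2 copies) — no repeat detector is prescribed
by the protocol, so the simplest deterministic one is used.

Undetermined: (9) a mismatch with ≥ 50% reciprocal column overlap
(pooled over a row's possibly fragmented segments) present in ≥ 4 rows.

Classification is a pure function of the flag set: misprediction-only →
`GENE_PREDICTION_ERROR`; false-positive-only → `FALSE_POSITIVE`; both,
or only the recurrence feature → `UNCONFIRMED`; no flags →
`UNEXPLAINED`.  The partition is verified exhaustively over all 2⁹ flag
combinations.  Features whose genomic inputs are missing are recorded
as skipped (unevaluated), never as negative.

## Correction

Only mismatches classified `GENE_PREDICTION_ERROR` are touched in
production runs (`require_gene_prediction_error=True`).  The pipeline:

1. The reference segment corresponding to the mismatch is searched
   six-frame against the transcript's genomic span padded by
   `correction_region_margin` (500 nt) on each side.  Stop codons break
   each frame into ORF fragments; each fragment ≥ 3 aa is aligned
   locally to the query; hits need E < 10⁻³ and identity > 80%.  The
   best raw score wins.
2. Exons overlapping the mismatch-coding nucleotides by at least one
   full codon are removed (junction-straddling 1–2 nt overlaps do not
   condemn a neighboring exon).  The hit is extended colinearly to
   cover the whole query segment, snapped to the running codon phase
   (0–2 nt 5′ extension) and adjusted 3′ so the inserted length is
   congruent mod 3 with the removed length, keeping downstream exons in
   frame.  Because junction-straddling codons are invisible to a
   translated search, the exact exon ends remain ambiguous by about one
   codon per side; in-frame boundary variants (±3, ±6 nt each end) are
   therefore integrity-checked and scored against the reference, and
   the best-scoring valid variant is kept (deterministic tie-break
   preferring the unadjusted boundary).
3. Transcript integrity: overlapping exons, inverted exon order,
   CDS length ≢ 0 (mod 3), internal stop codons — first failure wins
   and the correction is refused.
4. A new CDS and protein are built.  If the CDS no longer begins with a
   start codon, frame 0 is scanned for the first ATG and translation
   starts there, with a fallback flag (this can introduce an N-terminal
   deletion, as the before/after census shows).

New exon splice sites are *not* required to be canonical: the goal is a
more accurate protein at the expense of splicing logic.  Multiple
mismatches in one protein are corrected independently in sequence
order.  Multi-HSP reconstruction is out of scope.

Quality scores on the global alignment with the reference: identity
I = i/N × 100 (i identical pairs, N aligned residue pairs) and coverage
C = N/N_tot × 100 (N_tot total alignment columns).  Both are symmetric
by definition; the implementation aligns the pair in canonical order so
co-optimal traceback choices cannot make the result order-dependent.
Coverage may legitimately *decrease* after a good correction, because
over-alignment of a bogus segment inflates the original coverage.

## Synthetic study design

The simulator emulates the study conditions the pipeline is built for.
Defaults (chosen once, as the study conditions): 200 genes, 5 target
species; 10–14 coding exons of 120–240 nt per gene, so proteins run
~500–800 aa and a 50–70 aa corrupted segment leaves full-protein
identity above the 80% ortholog threshold, as it does in real
proteomes; one internal "anchor" exon of 150–210 nt hosts corruptions;
introns 35–120 nt with GT/AG sites; per-species divergence evenly
spaced over 0.01–0.08 (protein identity 92–99%, inside the 80–99%
ortholog band), applied per codon with a 3:1 synonymous:non-synonymous
bias.  Divergence never introduces stop codons; corruptions that would
create internal stops are repaired by synonymous resampling (or, rarely,
a residue change) before emission, mirroring the fact that real
predictors emit open reading frames.  Every emitted triple satisfies
protein = translate(extract_cds(model, contig)) exactly, including
corrupted ones, and the whole bundle is byte-reproducible from the seed.

Scenarios: the canonical mismatch generator shifts one internal exon's
boundaries by 1–2 nt (wrong reading frame, length preserved, true exon
surviving in the contig).  The N-run, short-intron, exon-split and
non-canonical-splice scenarios combine their genomic evidence with this
shift, because features are only evaluated on detected mismatches; the
exon-split scenario places its two fake introns near the anchor's edges
so the wrong-frame remnant stays one contiguous detectable block.  The
frameshift scenario inserts 1–2 nt into the contig itself, with exon
boundaries absorbing the length change so the frameshift stays local.
The isoform and repeat scenarios modify reference and target coherently
(swapped block / different tandem repeats), producing mismatches that
are *correct* predictions — the false-positive mechanisms.  The
propagated scenario applies one identical shift to four species.  'N'
runs are placed in introns so emitted proteins stay X-free; the feature
scans the whole transcript span either way.

What the simulator does not model: real intron length and GC
distributions, codon-usage bias, paralogy, repeat families beyond exact
tandem repeats, assembly artifacts beyond 'N' runs, alternative
splicing beyond a single swapped-exon isoform, and real phylogenetic
tree structure.  Passing recovery tests therefore demonstrates the
*logic* of detection/characterization/correction under controlled
conditions, not performance on real proteomes, where orthology errors
and alignment ambiguity are harsher.

## Controlled experiments

* Recovery study (200 genes × 5 species, every scenario at 8–9%): each
  scenario must fire its intended feature in ≥ 90% of labeled genes;
  a clean control must yield zero mismatch calls (divergence alone must
  never trigger the 50% rule).
* Correction round-trip (50 wrong-frame genes): ≥ 90% of genes
  corrected, every refined transcript passing integrity, mismatch
  counts strictly decreasing, ≥ 80% of genes recovering the true
  protein exactly.  This experiment disables the classification
  precondition: pure wrong-frame mismatches carry no characterization
  feature by design (no N runs, no short introns, no length changes),
  so the classifier labels them `UNEXPLAINED`; ground-truth labels
  stand in for classification in the controlled setting.
* Directional checks: after correction, total errors do not increase
  and mean identity does not decrease.

Problem sizes were chosen so the full test suite and the acceptance
script each run in a few minutes on one CPU.

## Known limitations

* Star alignment is reference-greedy; MAFFT-style iterative refinement
  would place insertions more consistently across rows.
* The detector's N-/C-terminal asymmetry (free end gaps plus the
  5-column minimum) is uncorrected.
* Correction inserts a single exon per mismatch; errors needing several
  new exons are refused at the integrity check.
* E-values are calibrated for ranking and thresholding within this
  pipeline only.
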