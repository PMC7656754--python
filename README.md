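# protqc — quality control of predicted protein-coding genes

Eukaryotic gene prediction is error-prone: complex exon–intron
structures lead to predicted proteins with missing or extra segments,
and — most damagingly — *mismatched segments*, where a stretch of the
protein is replaced by an alternative, erroneous sequence because an
exon was translated in the wrong reading frame or its boundaries were
mispredicted.  `protqc` is a pipeline for detecting such errors in a
predicted proteome by comparison with a trusted reference proteome,
diagnosing their causes from the underlying genome, and repairing them.

It is aimed at genome-annotation and comparative-genomics practitioners
who have: a reference proteome (e.g. a well-curated model organism), one
or more predicted proteomes of related species, and the genomic contigs
and gene models behind those predictions.

## What it computes

1. **Orthology** — for each reference protein, the best local-alignment
   hit (exact Smith–Waterman, BLOSUM62, affine gaps) in each target
   proteome, kept as an ortholog if E < 10⁻⁵⁰ and identity > 80%
   (Karlin–Altschul E = *K·m·n·e^(−λS)*).
2. **Error detection** — a reference-anchored (star) multiple alignment
   per gene family, scanned for seven error types: N/C-terminal
   extension, N/C-terminal deletion, internal insertion, internal
   deletion, and mismatched segments — runs of ≥ 20 aligned residues
   below 50% identity.  Orthologs more than 3× longer or shorter than
   the reference are excluded first.
3. **Characterization** — each mismatch is tested for nine features in
   three evidence classes: *gene misprediction* ('N' runs in the genomic
   span, introns < 30 nt, one reference exon facing ≥ 3 target exons,
   non-canonical (non-GT/AG) reference splice sites, frameshifting exon
   indels), *false positive* (an alternative reference isoform matching
   the segment, dissolution under pairwise realignment, tandem-repeat
   regions), and *undetermined* (the same mismatch in ≥ 4 species).
   Misprediction-only evidence ⇒ `GENE_PREDICTION_ERROR`; false-positive
   only ⇒ `FALSE_POSITIVE`; both, or recurrence only ⇒ `UNCONFIRMED`;
   none ⇒ `UNEXPLAINED`.
4. **Correction** — for gene-prediction errors, the reference segment is
   searched six-frame against the transcript's genomic region; a hit
   with E < 0.001 and identity > 80% is spliced into the transcript as a
   new exon, the transcript is integrity-checked (overlapping/inverted
   exons, frameshift, internal stops), and a new CDS/protein is built.
   Quality is scored before and after as identity *I = i/N × 100* and
   coverage *C = N/N*<sub>tot</sub> *× 100* on a global alignment with
   the reference.

A synthetic-genome simulator (`protqc.simulator`) generates the full
study design — multi-exon genes with canonical GT/AG introns, diverged
orthologs, and every error scenario injected with ground-truth labels —
so the whole pipeline is testable end to end without external data.

## Worked example

```bash
protqc run-all --simulate --n-genes 50 --n-species 5 --seed 11 --out run/
```

This simulates 50 gene families across 5 species (each non-clean
scenario at 8%), runs all stages, and prints the mismatch cause census:

```
{
  "FALSE_POSITIVE": 8,
  "GENE_PREDICTION_ERROR": 20,
  "UNCONFIRMED": 16,
  "UNEXPLAINED": 4
}
full outputs -> run/
```

Read: of the 48 mismatched segments detected, 20 carry only
misprediction evidence (N runs, short introns, split or frameshifted
exons — these are the ones the corrector then repairs), 8 carry only
false-positive evidence (isoform or repeat artifacts: the *call* is
suspect, not the gene), 16 are unconfirmed (recurrent across ≥ 4
species, or mixed evidence), and 4 have no explanatory feature.
`run/summary.json` holds the full census (per-species ortholog counts,
error tables, correction before/after), and `run/*.tsv` the per-record
tables.

The same stages are available as numbered drivers over a shared bundle
in `analysis/` (01 simulate → 02 orthologs → 03 detect →
04 characterize → 05 correct), writing their tables under `results/`.

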