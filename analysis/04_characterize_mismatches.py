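#!/usr/bin/env python
"""Characterize each mismatched segment with the nine genomic features
and classify its probable cause.

For every detected mismatch the gene models and contigs are consulted
for misprediction evidence (N runs, short introns, exon splitting,
non-canonical reference splice sites, frameshifted exons) and
false-positive evidence (alternative isoform match, alignment artifact,
repeat region), plus the cross-species recurrence feature.  Writes
results/mismatch_report.tsv and prints the feature census and the
four-way cause classification, with the scenario -> intended-feature
recovery matrix against the simulator's ground truth.
"""

import csv
from collections import Counter
from pathlib import Path

from protqc.features import ALL_FEATURES
from protqc.io_formats import write_tsv
from protqc.pipeline import (
    PipelineConfig, StudyInputs, stage_characterize, stage_detect,
    stage_orthologs,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

INTENDED_FEATURE = {
    "N_RUN": "N_CHARS", "SHORT_INTRON": "SHORT_INTRON",
    "EXON_SPLIT": "EXON_SPLIT_1_TO_3",
    "NONCANONICAL_SPLICE_REF": "NONCANONICAL_SPLICE_REF",
    "FRAMESHIFT_INDEL": "FRAMESHIFT_EXON", "ALT_ISOFORM": "ALT_ISOFORM_MATCH",
    "REPEAT_REGION": "REPEAT_REGION", "PROPAGATED_4PLUS": "CONSERVED_4PLUS",
}


def main():
    inputs = StudyInputs.load(RESULTS / "bundle")
    cfg = PipelineConfig(seed=1)
    stage = stage_orthologs(inputs, cfg)
    stage_detect(inputs, stage, cfg)
    stage_characterize(inputs, stage, cfg)

    feat_cols = list(ALL_FEATURES)
    write_tsv(
        [
            {
                "species": stage.species_of.get(r.error.sequence_id, "?"),
                "sequence_id": r.error.sequence_id,
                "seq_start": r.error.seq_positions[0],
                "seq_end": r.error.seq_positions[1],
                **{f: ("NA" if f in r.skipped_features else int(f in r.flag_names))
                   for f in feat_cols},
                "classification": r.classification,
            }
            for r in stage.reports
        ],
        RESULTS / "mismatch_report.tsv",
        ["species", "sequence_id", "seq_start", "seq_end", *feat_cols,
         "classification"],
    )

    feats = Counter(f for r in stage.reports for f in r.flag_names)
    classes = Counter(r.classification for r in stage.reports)
    n = len(stage.reports)
    print(f"characterized {n} mismatched segments")
    print("\nfeature counts:")
    for f in feat_cols:
        print(f"  {f:24s} {feats.get(f, 0):4d} ({100.0 * feats.get(f, 0) / n:.1f}%)")
    print("\nclassification:")
    for c, k in sorted(classes.items()):
        print(f"  {c:24s} {k:4d} ({100.0 * k / n:.1f}%)")

    with open(RESULTS / "bundle" / "ground_truth.tsv") as fh:
        labels = {
            l["protein_id"]: l["scenario"]
            for l in csv.DictReader(fh, delimiter="\t") if l["scenario"] != "NONE"
        }
    fired = {}
    for r in stage.reports:
        fired.setdefault(r.error.sequence_id, set()).update(r.flag_names)
    print("\nscenario -> intended feature recovery:")
    for scenario, feature in INTENDED_FEATURE.items():
        ids = [p for p, s in labels.items() if s == scenario]
        hit = sum(1 for p in ids if feature in fired.get(p, set()))
        print(f"  {scenario:24s} {hit}/{len(ids)}")


if __name__ == "__main__":
    main()
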