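"""Sequence and gene-model types, standard-format I/O, and coordinate mapping.

All coordinates are 0-based, half-open internally.  GFF3 input/output
converts to and from the 1-based closed convention at the boundary.  Gene
models are CDS-only: exons here are *coding* exon intervals, stored in
transcript (5'->3') order, which for minus-strand genes means strictly
decreasing genomic coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import reverse_complement

NUCLEOTIDE_ALPHABET = frozenset("ACGTURYSWKMBDHVN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUO*")


class FormatError(ValueError):
    """Raised on malformed input files or invalid record content."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence."""

    id: str
    seq: str
    moltype: str = "protein"  # "nucleotide" or "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"empty sequence for record {self.id!r}")
        if self.seq != self.seq.upper():
            object.__setattr__(self, "seq", self.seq.upper())
        if self.moltype not in ("nucleotide", "protein"):
            raise FormatError(f"unknown moltype {self.moltype!r}")
        alphabet = (
            NUCLEOTIDE_ALPHABET if self.moltype == "nucleotide" else PROTEIN_ALPHABET
        )
        bad = set(self.seq) - alphabet
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                f"{self.moltype} alphabet"
            )
        if self.moltype == "protein" and "*" in self.seq[:-1]:
            raise FormatError(f"record {self.id!r}: internal stop ('*') in protein")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class ExonInterval:
    """A genomic interval, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "ExonInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class GeneModel:
    """Coding exon structure of one transcript on one genomic contig.

    ``exons`` are in transcript order: genomically increasing for '+',
    decreasing for '-'.
    """

    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str
    exons: list[ExonInterval]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene model {self.transcript_id}: no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.overlaps(b):
                raise ValueError(
                    f"gene model {self.transcript_id}: overlapping exons {a} {b}"
                )
            if self.strand == "+" and not b.start >= a.end:
                raise ValueError(f"{self.transcript_id}: exons not increasing on '+'")
            if self.strand == "-" and not b.end <= a.start:
                raise ValueError(f"{self.transcript_id}: exons not decreasing on '-'")

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def genomic_exons(self) -> list[ExonInterval]:
        """Exons sorted by genomic coordinate (ascending)."""
        return sorted(self.exons)

    @property
    def span(self) -> ExonInterval:
        ge = self.genomic_exons
        return ExonInterval(ge[0].start, ge[-1].end)

    @property
    def introns(self) -> list[ExonInterval]:
        """Intron intervals in transcript order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            lo, hi = (a.end, b.start) if self.strand == "+" else (b.end, a.start)
            out.append(ExonInterval(lo, hi))
        return out


class CodonTable:
    """A codon -> amino-acid mapping with start codons; default is the
    standard genetic code, with stops rendered as '*'."""

    def __init__(self, table_id: int = 1):
        bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
        self.mapping: dict[str, str] = dict(bio.forward_table)
        for codon in bio.stop_codons:
            self.mapping[codon] = "*"
        self.start_codons = frozenset(bio.start_codons)
        if len(self.mapping) != 64:
            raise ValueError("codon table does not map all 64 codons")
        # amino acid -> synonymous codons, for back-translation
        self.codons_for: dict[str, list[str]] = {}
        for codon, aa in sorted(self.mapping.items()):
            self.codons_for.setdefault(aa, []).append(codon)

    def translate_codon(self, codon: str) -> str:
        """One codon to one amino acid; anything outside ACGT yields 'X'."""
        codon = codon.upper()
        return self.mapping.get(codon, "X") if set(codon) <= set("ACGT") else "X"


STANDARD_TABLE = CodonTable(1)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, moltype: str = "protein") -> list[SequenceRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Sequences are uppercased.  Duplicate ids and empty sequences are
    rejected with the offending header's line number.
    """
    header_lines: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                name = line[1:].split(None, 1)[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: malformed FASTA header")
                if name in header_lines:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate record id {name!r} "
                        f"(first seen at line {header_lines[name]})"
                    )
                header_lines[name] = lineno
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(
                f"{path}:{header_lines.get(rec.id, '?')}: empty sequence "
                f"for record {rec.id!r}"
            )
        records.append(
            SequenceRecord(id=rec.id, seq=seq, moltype=moltype,
                           description=rec.description[len(rec.id):].strip())
        )
    if not records and not header_lines:
        with open(path) as fh:
            if fh.read().strip():
                raise FormatError(f"{path}: not FASTA-formatted (no records)")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene/mRNA/CDS features only)
# ---------------------------------------------------------------------------

def read_gff3_models(path) -> list[GeneModel]:
    """Parse gene models from GFF3: one GeneModel per mRNA, built from its
    CDS children.  1-based closed coordinates are converted to 0-based
    half-open and exons reordered into transcript order."""
    mrna_meta: dict[str, dict] = {}
    cds_by_parent: dict[str, list[tuple[int, int, str, str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "mRNA":
                mrna_id = attr.get("ID")
                if not mrna_id:
                    raise FormatError(f"{path}:{lineno}: mRNA without ID")
                mrna_meta[mrna_id] = {
                    "contig": seqid,
                    "strand": strand,
                    "gene": attr.get("Parent", attr.get("gene_id", mrna_id)),
                    "protein": attr.get("protein_id", mrna_id),
                }
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if not parent:
                    raise FormatError(f"{path}:{lineno}: CDS without Parent")
                cds_by_parent.setdefault(parent, []).append(
                    (int(start) - 1, int(end), seqid, strand)
                )
    models = []
    for mrna_id, meta in mrna_meta.items():
        segs = cds_by_parent.get(mrna_id)
        if not segs:
            continue
        ivals = sorted(ExonInterval(s, e) for s, e, _c, _s in segs)
        for a, b in zip(ivals, ivals[1:]):
            if a.overlaps(b):
                raise FormatError(
                    f"{path}: transcript {mrna_id}: overlapping CDS segments"
                )
        if meta["strand"] == "-":
            ivals = ivals[::-1]
        models.append(
            GeneModel(
                gene_id=meta["gene"],
                transcript_id=mrna_id,
                contig_id=meta["contig"],
                strand=meta["strand"],
                exons=ivals,
                protein_id=meta["protein"],
            )
        )
    orphans = set(cds_by_parent) - set(mrna_meta)
    if orphans:
        raise FormatError(
            f"{path}: CDS features with no parent mRNA: {sorted(orphans)[:5]}"
        )
    return models


def write_gff3_models(models, path) -> None:
    """Write gene/mRNA/CDS features, converting back to 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            common = f"{m.contig_id}\tprotqc"
            fh.write(
                f"{common}\tgene\t{span.start + 1}\t{span.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            fh.write(
                f"{common}\tmRNA\t{span.start + 1}\t{span.end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id};protein_id={m.protein_id}\n"
            )
            phase = 0
            for e in m.exons:
                fh.write(
                    f"{common}\tCDS\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t{phase}\t"
                    f"ID=cds-{m.transcript_id};Parent={m.transcript_id}\n"
                )
                phase = (3 - ((len(e) - phase) % 3)) % 3


# ---------------------------------------------------------------------------
# CDS extraction and translation
# ---------------------------------------------------------------------------

def extract_cds(model: GeneModel, genome: SequenceRecord) -> SequenceRecord:
    """Spliced coding sequence of a gene model, in transcript orientation."""
    if model.contig_id != genome.id:
        raise ValueError(
            f"model {model.transcript_id} is on contig {model.contig_id!r}, "
            f"not {genome.id!r}"
        )
    parts = []
    for e in model.exons:
        if e.end > len(genome.seq):
            raise ValueError(
                f"exon {e} outside contig {genome.id!r} (length {len(genome.seq)})"
            )
        chunk = genome.seq[e.start : e.end].upper()
        parts.append(reverse_complement(chunk) if model.strand == "-" else chunk)
    return SequenceRecord(
        id=model.transcript_id, seq="".join(parts), moltype="nucleotide"
    )


@dataclass(frozen=True)
class Translation:
    protein: SequenceRecord
    incomplete_codon: bool


def translate_cds(cds: SequenceRecord, table: CodonTable = STANDARD_TABLE) -> Translation:
    """Translate complete codons; N-containing codons give 'X', stops give
    '*' wherever they occur (truncation is the caller's decision)."""
    if cds.moltype != "nucleotide":
        raise ValueError("translate_cds requires a nucleotide record")
    n = len(cds.seq)
    aas = [table.translate_codon(cds.seq[i : i + 3]) for i in range(0, n - n % 3, 3)]
    if not aas:
        raise ValueError(f"CDS {cds.id!r} shorter than one codon")
    return Translation(
        protein=_protein_record(cds.id, "".join(aas)),
        incomplete_codon=bool(n % 3),
    )


def _protein_record(name: str, seq: str) -> SequenceRecord:
    """Protein record constructor that tolerates internal stops (a
    mispredicted translation legitimately contains them while being
    integrity-checked)."""
    rec = object.__new__(SequenceRecord)
    object.__setattr__(rec, "id", name)
    object.__setattr__(rec, "seq", seq)
    object.__setattr__(rec, "moltype", "protein")
    object.__setattr__(rec, "description", "")
    return rec


# ---------------------------------------------------------------------------
# Protein <-> genome coordinate mapping
# ---------------------------------------------------------------------------

class ProteinGenomeMap:
    """Per-residue genomic coordinates for a gene model's protein.

    Residue ``i`` maps to three genomic positions (the codon), which may
    straddle an exon junction.
    """

    def __init__(self, gene_model: GeneModel):
        self.gene_model = gene_model
        positions: list[int] = []
        for e in gene_model.exons:
            rng = (
                range(e.start, e.end)
                if gene_model.strand == "+"
                else range(e.end - 1, e.start - 1, -1)
            )
            positions.extend(rng)
        self._positions = positions  # CDS index -> genomic position

    @property
    def protein_length(self) -> int:
        return len(self._positions) // 3

    def codon_positions(self, aa_index: int) -> tuple[int, int, int]:
        i = 3 * aa_index
        return tuple(self._positions[i : i + 3])

    def protein_interval_to_genomic(self, aa_start: int, aa_end: int) -> list[ExonInterval]:
        """Minimal genomic intervals covering residues [aa_start, aa_end),
        split at exon boundaries; returned in transcript order."""
        if not (0 <= aa_start < aa_end <= self.protein_length):
            raise ValueError(
                f"residue interval [{aa_start}, {aa_end}) outside protein "
                f"of length {self.protein_length}"
            )
        pos = self._positions[3 * aa_start : 3 * aa_end]
        step = 1 if self.gene_model.strand == "+" else -1
        out: list[ExonInterval] = []
        run_start = prev = pos[0]
        for p in pos[1:]:
            if p != prev + step:
                out.append(_interval(run_start, prev))
                run_start = p
            prev = p
        out.append(_interval(run_start, prev))
        return out


def _interval(a: int, b: int) -> ExonInterval:
    lo, hi = (a, b) if a <= b else (b, a)
    return ExonInterval(lo, hi + 1)


def write_tsv(rows: list[dict], path, columns: list[str] | None = None) -> None:
    """Minimal deterministic TSV writer (UTF-8, header row)."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    buf = io.StringIO()
    buf.write("\t".join(columns) + "\n")
    for row in rows:
        buf.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
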