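"""Pairwise local protein search and thresholded best-hit ortholog assignment.

Orthology between a reference proteome and each target proteome is
approximated by the best local-alignment hit per reference protein, kept
only if it passes an E-value and a percent-identity threshold (defaults
1e-50 and 80%).  Local alignment is exact Smith-Waterman with affine gaps
(Gotoh), not a heuristic seeded search, so results are deterministic and
seed-independent.  E-values use the Karlin-Altschul formula
``E = K * m * n * exp(-lambda * S)`` with gapped BLOSUM62 defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

PROTEIN_STRICT = set("ACDEFGHIKLMNPQRSTVWYX*BZ")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap protein scoring.  A gap of length L costs
    ``gap_open + gap_extend * L``."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_K: float = 0.041
    karlin_lambda: float = 0.267

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_K <= 0 or self.karlin_lambda <= 0:
            raise ValueError("Karlin-Altschul K and lambda must be positive")


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


def _make_aligner(scheme: ScoringScheme, mode: str, free_ends: bool = False):
    al = Align.PairwiseAligner()
    al.substitution_matrix = _matrix(scheme.matrix_name)
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    al.mode = mode
    if free_ends:
        al.open_end_insertion_score = 0.0
        al.extend_end_insertion_score = 0.0
        al.open_end_deletion_score = 0.0
        al.extend_end_deletion_score = 0.0
    return al


@dataclass
class LocalHit:
    """One local alignment between a query and a subject protein."""

    query_id: str
    subject_id: str
    raw_score: float
    evalue: float
    identity_pct: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    aligned_query: str = ""
    aligned_subject: str = ""


@dataclass(frozen=True)
class OrthologPair:
    reference_id: str
    target_id: str
    species: str
    hit: LocalHit


def alignment_identity(row_a: str, row_b: str) -> float:
    """Percent identity over non-gap aligned columns of two gapped rows.
    'X' never counts as identical."""
    pairs = [
        (a, b) for a, b in zip(row_a, row_b) if a != "-" and b != "-"
    ]
    if not pairs:
        return 0.0
    ident = sum(1 for a, b in pairs if a == b and a != "X")
    return 100.0 * ident / len(pairs)


def local_align(
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    scheme: ScoringScheme = ScoringScheme(),
) -> LocalHit:
    """Optimal Smith-Waterman local alignment of two proteins.

    Traceback ties are resolved by the aligner's deterministic
    first-traceback rule, so repeated calls always return the same hit.
    """
    qid, qseq = _as_pair(query)
    sid, sseq = _as_pair(subject)
    for name, seq in ((qid, qseq), (sid, sseq)):
        bad = set(seq) - PROTEIN_STRICT
        if bad:
            raise ValueError(f"{name!r}: non-protein characters {sorted(bad)}")
    al = _make_aligner(scheme, "local")
    alns = al.align(qseq.replace("*", "X"), sseq.replace("*", "X"))
    if alns.score <= 0:  # nothing aligns locally
        return LocalHit(
            query_id=qid, subject_id=sid, raw_score=0.0, evalue=math.inf,
            identity_pct=0.0, query_span=(0, 0), subject_span=(0, 0),
        )
    aln = alns[0]
    blocks_q, blocks_s = aln.aligned
    gq, gs = str(aln[0]), str(aln[1])
    return LocalHit(
        query_id=qid,
        subject_id=sid,
        raw_score=float(aln.score),
        evalue=math.nan,
        identity_pct=alignment_identity(gq, gs),
        query_span=(int(blocks_q[0][0]), int(blocks_q[-1][1])),
        subject_span=(int(blocks_s[0][0]), int(blocks_s[-1][1])),
        aligned_query=gq,
        aligned_subject=gs,
    )


def _as_pair(rec) -> tuple[str, str]:
    if isinstance(rec, SequenceRecord):
        return rec.id, rec.seq
    return "seq", str(rec)


def estimate_evalue(
    raw_score: float, query_len: int, db_residues: int,
    scheme: ScoringScheme = ScoringScheme(),
) -> float:
    """Karlin-Altschul expected number of chance hits at this score."""
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    return (
        scheme.karlin_K
        * query_len
        * db_residues
        * math.exp(-scheme.karlin_lambda * raw_score)
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def find_orthologs(
    reference: list[SequenceRecord],
    target: list[SequenceRecord],
    species: str,
    scheme: ScoringScheme = ScoringScheme(),
    evalue_max: float = 1e-50,
    identity_min: float = 80.0,
    prefilter: bool = True,
    prefilter_k: int = 6,
) -> list[OrthologPair]:
    """Best-hit ortholog of each reference protein in one target proteome.

    For each reference protein the best raw local-alignment score over the
    target proteome is taken (score ties broken by lexicographic target
    id); the pair is kept only if its E-value and identity pass the
    thresholds.  The optional shared-k-mer prefilter skips target
    sequences with no exact k-mer in common with the query - a pair that
    could pass an 80% identity threshold shares many k-mers, so at study
    divergence levels this does not change the result.
    """
    if not reference or not target:
        raise ValueError("proteomes must be non-empty")
    db_residues = sum(len(t.seq) for t in target)
    target_sorted = sorted(target, key=lambda r: r.id)
    kmers = {t.id: _kmer_set(t.seq, prefilter_k) for t in target_sorted}
    al = _make_aligner(scheme, "local")
    pairs: list[OrthologPair] = []
    for ref in sorted(reference, key=lambda r: r.id):
        qk = _kmer_set(ref.seq, prefilter_k)
        best_id, best_score = None, -1.0
        for t in target_sorted:
            if prefilter and not (qk & kmers[t.id]):
                continue
            score = al.score(ref.seq.replace("*", "X"), t.seq.replace("*", "X"))
            if score > best_score:
                best_id, best_score = t.id, score
        if best_id is None:
            continue
        best = next(t for t in target_sorted if t.id == best_id)
        hit = local_align(ref, best, scheme)
        hit.evalue = estimate_evalue(hit.raw_score, len(ref.seq), db_residues, scheme)
        if hit.evalue < evalue_max and hit.identity_pct > identity_min:
            pairs.append(
                OrthologPair(
                    reference_id=ref.id, target_id=best.id, species=species, hit=hit
                )
            )
    return pairs
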