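"""Homology search: produce and normalize hits carrying identity and coverage.

Every comparison in the pipeline reduces to the same two numbers per match —
percent sequence identity over aligned columns (S) and percent of the query
covered by the alignment (Q) — so this module exposes a single
:class:`HomologyHit` contract behind pluggable backends:

* ``builtin`` — Smith-Waterman local alignment (Biopython's PairwiseAligner,
  BLOSUM62, gap open 11 / extend 1, i.e. a gap of length k costs 11 + k).
  Its ``evalue`` is an *approximate* Karlin-Altschul statistic (standard
  gapped parameters, no length corrections); it filters out the long weak
  alignments of unrelated sequences and breaks ties, but is not calibrated
  to BLAST's reported E-values.
* ``blast_tab`` — parse precomputed BLAST tabular output (outfmt 6, standard
  12 columns, optionally extended with qlen and qcovs).

Per (query, subject) pair only the single best local alignment is retained,
which keeps S and Q well-defined for each match.  Best-hit selection uses the
weighted score w_S*S + w_Q*Q with equal weights by default; the component
values are always carried so callers can re-weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, translate

#: Residues the BLOSUM62 matrix knows about.
_MATRIX_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")
#: Rare/extended residues are scored as 'X' (never a positive contribution).
_TO_X = str.maketrans({c: "X" for c in "JUO"})


class BlastTabFormatError(ValueError):
    """A BLAST tabular row violates the expected column layout."""


@dataclass(frozen=True)
class HomologyHit:
    """One query-vs-subject local alignment.

    Coordinates are 0-based half-open in protein space; conversion from the
    1-based inclusive BLAST convention happens only at the tabular boundary.
    """

    query_id: str
    subject_id: str
    pct_identity: float  # 0-100, over aligned columns
    qcov: float  # 0-100, percent of query residues spanned
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    bitscore: float
    evalue: float
    mismatch: int = 0
    gapopen: int = 0
    frame: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if not (0.0 <= self.qcov <= 100.0):
            raise ValueError(f"qcov out of range: {self.qcov}")
        if self.q_end <= self.q_start:
            raise ValueError("q_end must exceed q_start")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")

    def weighted_score(self, weights: tuple[float, float] = (0.5, 0.5)) -> float:
        w_s, w_q = weights
        return w_s * self.pct_identity + w_q * self.qcov


@dataclass(frozen=True)
class SearchParams:
    """Knobs for homology searches.

    ``weights`` is the (w_S, w_Q) pair used whenever identity and coverage
    must be collapsed to one score; the default weights them equally.  The
    builtin backend admits hits with positive alignment score, at least
    ``min_aln_len`` aligned columns, and approximate E-value at most
    ``evalue_max`` (computed against the searched database's total residue
    count) — a stand-in for BLAST's word/E-value filtering that suppresses
    both spurious micro-alignments and long weak alignments of unrelated
    sequences.  In database searches, pairs are only aligned when they share
    an exact word of ``word_size`` residues (BLAST-style seeding; None
    disables), which any genuine homolog above the alignment-length floor
    will, while the bulk of unrelated pairs are skipped.
    """

    evalue_max: float = 1e-3
    weights: tuple[float, float] = (0.5, 0.5)
    backend: str = "builtin"
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_aln_len: int = 15
    word_size: int | None = 4

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")
        w_s, w_q = self.weights
        if w_s < 0 or w_q < 0 or not math.isclose(w_s + w_q, 1.0, abs_tol=1e-9):
            raise ValueError("weights must be nonnegative and sum to 1")


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # Biopython charges open_gap_score for the first gap position, so a gap of
    # length k costs gap_open + k under the BLAST-style convention used here.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _clean_protein(seq: str, who: str) -> str:
    s = seq.upper().translate(_TO_X)
    bad = set(s) - _MATRIX_ALPHABET
    if bad:
        raise ValueError(f"{who}: residue(s) {sorted(bad)} outside amino-acid alphabet")
    return s


# Standard gapped Karlin-Altschul parameters for BLOSUM62 with gap costs
# 11/1, as tabulated in the BLAST sources.  Used for an *approximate*
# E-value: no edge-effect or length corrections are applied, so the numbers
# track BLAST's only to within an order of magnitude.
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _surrogate_evalue(score: float, m: int, n: int) -> float:
    """Approximate E-value of a local alignment score.

    E = K * m * n * exp(-lambda * S) with the standard gapped BLOSUM62
    parameters and no effective-length correction — close enough to rank
    hits and to reject the long, weak alignments of unrelated sequences
    that BLAST's default filtering would never report, but not a substitute
    for calibrated BLAST statistics.
    """
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def align_protein_pair(query: str, subject: str, params: SearchParams | None = None,
                       aligner: Align.PairwiseAligner | None = None
                       ) -> HomologyHit | None:
    """Best Smith-Waterman local alignment of two peptides, or None.

    Returns None when the optimal score is <= 0 (no detectable homology).
    Identity is computed over aligned columns (gap columns included in the
    denominator); coverage is the fraction of the query spanned by the local
    alignment.
    """
    if params is None:
        params = SearchParams()
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    q = _clean_protein(query, "query")
    s = _clean_protein(subject, "subject")
    if aligner is None:
        aligner = _make_aligner(params)
    alignments = aligner.align(q, s)
    score = alignments.score
    if score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    aln_len = aln.length  # aligned columns, gaps included
    identities = counts.identities
    q_start = int(aln.aligned[0][0][0])
    q_end = int(aln.aligned[0][-1][1])
    s_start = int(aln.aligned[1][0][0])
    s_end = int(aln.aligned[1][-1][1])
    return HomologyHit(
        query_id="query",
        subject_id="subject",
        pct_identity=100.0 * identities / aln_len,
        qcov=100.0 * (q_end - q_start) / len(q),
        aln_len=aln_len,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        bitscore=float(score),
        evalue=_surrogate_evalue(score, len(q), len(s)),
        mismatch=counts.mismatches,
        gapopen=int(counts.open_internal_insertions + counts.open_internal_deletions),
    )


def _as_protein(record: SequenceRecord) -> tuple[str, int | None]:
    """Protein sequence of a record; annotated CDS are translated in-frame."""
    if record.alphabet == "protein":
        return record.seq, None
    peptide = translate(record.seq).rstrip("*")
    if "*" in peptide:
        raise ValueError(
            f"CDS {record.id!r} contains an internal stop after in-frame "
            "translation; is it really an annotated coding region?"
        )
    return peptide, 1


def search(queries: Sequence[SequenceRecord], db: Sequence[SequenceRecord],
           params: SearchParams | None = None) -> list[HomologyHit]:
    """All-vs-all search of queries against a protein database.

    Nucleotide queries (annotated CDS) are translated in-frame first, so the
    comparison is always protein-vs-protein, mirroring a blastx workflow.
    Per (query, subject) pair at most the single best local alignment is
    returned; builtin-backend hits must have positive score, at least
    ``params.min_aln_len`` aligned columns, and approximate E-value (score
    vs. the database's total residue count) at most ``params.evalue_max``.
    Pairs sharing no exact word of ``params.word_size`` residues are skipped
    without alignment.
    """
    if params is None:
        params = SearchParams()
    if not db:
        raise ValueError("empty database")
    aligner = _make_aligner(params)
    hits: list[HomologyHit] = []
    prepared = [(rec, *_as_protein(rec)) for rec in queries]
    db_clean = [(rec, _clean_protein(rec.seq, rec.id)) for rec in db]
    db_residues = sum(len(s) for _, s in db_clean)
    k = params.word_size
    for rec, peptide, frame in prepared:
        q = _clean_protein(peptide, rec.id)
        q_words = (frozenset(q[i:i + k] for i in range(len(q) - k + 1))
                   if k else None)
        for subj, s in db_clean:
            if q_words is not None and not _shares_word(q_words, s, k):
                continue
            hit = align_protein_pair(q, s, params, aligner=aligner)
            if hit is None or hit.aln_len < params.min_aln_len:
                continue
            evalue = _surrogate_evalue(hit.bitscore, len(q), db_residues)
            if evalue > params.evalue_max:
                continue
            hits.append(replace(hit, query_id=rec.id, subject_id=subj.id,
                                frame=frame, evalue=evalue))
    return hits


def _shares_word(q_words: frozenset[str], subject: str, k: int) -> bool:
    return any(subject[i:i + k] in q_words
               for i in range(len(subject) - k + 1))


def best_hit(hits: Sequence[HomologyHit],
             weights: tuple[float, float] = (0.5, 0.5)) -> HomologyHit | None:
    """Select the highest-scoring hit by weighted identity + coverage.

    Ties break deterministically: higher bitscore, then lower evalue, then
    lexicographically smallest subject_id.  All hits must share one query.
    """
    if not hits:
        return None
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("best_hit requires hits sharing a single query_id")
    return max(
        hits,
        key=lambda h: (h.weighted_score(weights), h.bitscore, -h.evalue,
                       _ReverseStr(h.subject_id)),
    )


class _ReverseStr(str):
    """String whose ordering is reversed, so max() prefers the smallest id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


_BLAST_STD_COLS = 12  # qseqid sseqid pident length mismatch gapopen
#                       qstart qend sstart send evalue bitscore


def parse_blast_tab(path: str | Path, qlen: dict[str, int] | None = None
                    ) -> list[HomologyHit]:
    """Parse BLAST tabular output (outfmt 6) into hits.

    Accepts the standard 12 columns, optionally extended with ``qlen`` and
    ``qcovs`` (dialect "std qlen qcovs").  Coverage comes from qcovs when
    present, else is computed from the query span and qlen (either the 13th
    column or the ``qlen`` mapping); if neither source is available a
    configuration error is raised, because coverage cannot be derived from
    the standard columns alone.
    """
    path = Path(path)
    hits: list[HomologyHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13, 14):
                raise BlastTabFormatError(
                    f"{path}:{lineno}: expected 12-14 tab-separated columns, "
                    f"got {len(fields)}"
                )
            (qseqid, sseqid, pident, length, mismatch, gapopen,
             qstart, qend, sstart, send, evalue, bitscore) = fields[:12]
            q_start_1, q_end_1 = int(qstart), int(qend)
            s_start_1, s_end_1 = int(sstart), int(send)
            # minus-strand blastx rows report descending coordinates
            q_lo, q_hi = sorted((q_start_1, q_end_1))
            s_lo, s_hi = sorted((s_start_1, s_end_1))
            row_qlen: int | None = None
            qcovs: float | None = None
            if len(fields) >= 13:
                row_qlen = int(fields[12])
            if len(fields) == 14:
                qcovs = float(fields[13])
            if row_qlen is None and qlen is not None:
                row_qlen = qlen.get(qseqid)
            if qcovs is not None:
                qcov = qcovs
            elif row_qlen:
                qcov = 100.0 * (q_hi - q_lo + 1) / row_qlen
            else:
                raise BlastTabFormatError(
                    f"{path}:{lineno}: query coverage unavailable — supply the "
                    "qcovs or qlen column, or pass query lengths"
                )
            hits.append(HomologyHit(
                query_id=qseqid,
                subject_id=sseqid,
                pct_identity=float(pident),
                qcov=min(qcov, 100.0),
                aln_len=int(length),
                mismatch=int(mismatch),
                gapopen=int(gapopen),
                q_start=q_lo - 1,
                q_end=q_hi,
                s_start=s_lo - 1,
                s_end=s_hi,
                evalue=float(evalue),
                bitscore=float(bitscore),
            ))
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path: str | Path,
                    qlen: dict[str, int] | None = None) -> None:
    """Write hits in the extended tabular dialect "std qlen qcovs".

    Round-trips through :func:`parse_blast_tab` preserving every required
    field.  Query length is reconstructed from qcov and the query span when
    no explicit mapping is given.
    """
    path = Path(path)
    with path.open("w") as fh:
        for h in hits:
            if qlen and h.query_id in qlen:
                length_q = qlen[h.query_id]
            elif h.qcov > 0:
                length_q = round(100.0 * (h.q_end - h.q_start) / h.qcov)
            else:
                length_q = h.q_end
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.pct_identity:.3f}",
                str(h.aln_len), str(h.mismatch), str(h.gapopen),
                str(h.q_start + 1), str(h.q_end),
                str(h.s_start + 1), str(h.s_end),
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                str(length_q), f"{h.qcov:.3f}",
            ]) + "\n")
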