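"""Sequence input/output and six-frame translation of metagenomic contigs.

FASTA records are held as lightweight :class:`SequenceRecord` objects with an
explicit alphabet flag, so downstream code can tell annotated nucleotide
coding regions from protein reference sets without guessing.  Contigs are
turned into a searchable protein space by translating all six reading frames
and splitting each frame at stop codons; every stop-free segment of at least
``min_orf_aa`` residues is emitted as an :class:`OrfPeptide` with full
provenance (contig, frame, amino-acid coordinates).  ORFs are stop-to-stop
segments: no start codon is required, which maximizes sensitivity on
fragmentary contigs whose genes are routinely truncated at contig edges.

All internal coordinates are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

Alphabet = Literal["nucleotide", "protein"]

#: IUPAC nucleotide codes, ambiguity codes included.
NUCLEOTIDE_ALPHABET = frozenset("ACGTUWSMKRYBDHVN")
#: Amino-acid codes (incl. B/Z/J/U/O extensions and 'X'), plus the stop symbol.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

#: Frame order used everywhere: forward frames first, then reverse.
FRAME_ORDER = (1, 2, 3, -1, -2, -3)


class FastaFormatError(ValueError):
    """A FASTA entry violates the format contract (empty, duplicate, bad residue)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: a coding region, reference protein, or contig."""

    id: str
    seq: str
    alphabet: Alphabet
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record with empty id")
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranslatedFrame:
    """Translation of one of the six reading frames of a contig."""

    contig_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    offset: int  # 0-based start of the frame on its strand
    peptide: str  # includes '*' at stop codons


@dataclass(frozen=True)
class OrfPeptide:
    """A stop-free segment of a translated frame (stop-to-stop ORF)."""

    contig_id: str
    frame: int
    start_aa: int  # 0-based half-open, within the frame peptide
    end_aa: int
    peptide: str

    @property
    def orf_id(self) -> str:
        """Header used when ORFs are written as a protein database."""
        return f"{self.contig_id}|{self.frame:+d}|{self.start_aa}-{self.end_aa}"


_COMPLEMENT = str.maketrans("ACGTUWSMKRYBDHVNacgtuwsmkrybdhvn",
                            "TGCAAWSKMYRVHDBNtgcaawskmyrvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_residues(rec_id: str, seq: str, alphabet: Alphabet) -> None:
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    bad = set(seq.upper()) - allowed
    if bad:
        raise FastaFormatError(
            f"record {rec_id!r}: residue(s) {sorted(bad)} outside {alphabet} alphabet"
        )


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[SequenceRecord]:
    """Parse a FASTA file into validated records, order preserved.

    Record ids are the first whitespace-delimited token of each header.
    Raises :class:`FastaFormatError` on an empty sequence, a duplicate id, or
    a residue outside the declared alphabet.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record {entry.id!r} has an empty sequence")
        if entry.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        _validate_residues(entry.id, seq, alphabet)
        records.append(
            SequenceRecord(id=entry.id, seq=seq, alphabet=alphabet,
                           description=entry.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, sequence lines wrapped at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.description if rec.description and rec.description != rec.id \
                else rec.id
            if not header.startswith(rec.id):
                header = rec.id + " " + header
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def translate(seq: str, table: int = 1) -> str:
    """Translate a nucleotide sequence to protein.

    Trailing 1-2 nucleotides are ignored; stop codons become '*'; codons with
    ambiguity codes translate to the unique amino acid they imply, else 'X'.
    """
    if not seq:
        raise ValueError("cannot translate an empty sequence")
    if len(seq) < 3:
        raise ValueError(f"sequence shorter than one codon: {seq!r}")
    trimmed = seq[: len(seq) - len(seq) % 3].upper().replace("U", "T")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return str(Seq(trimmed).translate(table=table))


def six_frame_translations(contig: SequenceRecord, table: int = 1) -> list[TranslatedFrame]:
    """Translate all six reading frames of a nucleotide contig.

    Frames +1,+2,+3 start at offsets 0,1,2 of the forward strand; -1,-2,-3 at
    offsets 0,1,2 of the reverse complement.
    """
    if contig.alphabet != "nucleotide":
        raise ValueError(f"contig {contig.id!r} is not nucleotide")
    frames: list[TranslatedFrame] = []
    strands = {1: contig.seq, -1: reverse_complement(contig.seq)}
    for frame in FRAME_ORDER:
        strand = 1 if frame > 0 else -1
        offset = abs(frame) - 1
        sub = strands[strand][offset:]
        peptide = translate(sub, table=table) if len(sub) >= 3 else ""
        frames.append(TranslatedFrame(contig_id=contig.id, frame=frame,
                                      offset=offset, peptide=peptide))
    return frames


def six_frame_orfs(contig: SequenceRecord, min_orf_aa: int = 20,
                   table: int = 1) -> list[OrfPeptide]:
    """Extract stop-to-stop ORFs of length >= ``min_orf_aa`` from all six frames.

    Output order is deterministic: frames +1,+2,+3,-1,-2,-3, then
    left-to-right within each frame.  A contig shorter than one codon yields
    an empty list.
    """
    if min_orf_aa < 1:
        raise ValueError("min_orf_aa must be >= 1")
    if len(contig.seq) < 3:
        return []
    orfs: list[OrfPeptide] = []
    for tf in six_frame_translations(contig, table=table):
        start = 0
        # split at stops, keeping coordinates within the frame peptide
        for segment in tf.peptide.split("*"):
            end = start + len(segment)
            if len(segment) >= min_orf_aa:
                orfs.append(OrfPeptide(contig_id=tf.contig_id, frame=tf.frame,
                                       start_aa=start, end_aa=end, peptide=segment))
            start = end + 1  # skip the stop symbol
    return orfs


def orf_database(contigs: Iterable[SequenceRecord], min_orf_aa: int = 20,
                 table: int = 1) -> list[SequenceRecord]:
    """Build the protein database representing a metagenomic sample.

    Each ORF becomes a protein record with header ``contigID|frame|start-end``
    (amino-acid coordinates, 0-based half-open).
    """
    db: list[SequenceRecord] = []
    for contig in contigs:
        for orf in six_frame_orfs(contig, min_orf_aa=min_orf_aa, table=table):
            db.append(SequenceRecord(id=orf.orf_id, seq=orf.peptide,
                                     alphabet="protein"))
    return db


def count_cds_features(genbank_path: str | Path) -> int:
    """Count annotated CDS features in a GenBank flat file.

    Convenience for sizing a reference gene set from an annotated genome
    record (one record per file expected; multi-record files are summed).
    """
    n = 0
    for record in SeqIO.parse(str(genbank_path), "genbank"):
        n += sum(1 for f in record.features if f.type == "CDS")
    return n


def genbank_cds_records(genbank_path: str | Path) -> list[SequenceRecord]:
    """Extract nucleotide CDS sequences from a GenBank record.

    Ids are taken from locus_tag, falling back to protein_id, then gene, then
    a positional index.
    """
    out: list[SequenceRecord] = []
    for record in SeqIO.parse(str(genbank_path), "genbank"):
        for i, feat in enumerate(f for f in record.features if f.type == "CDS"):
            q = feat.qualifiers
            cds_id = (q.get("locus_tag") or q.get("protein_id")
                      or q.get("gene") or [f"{record.id}_cds{i}"])[0]
            seq = str(feat.extract(record.seq)).upper()
            out.append(SequenceRecord(id=cds_id, seq=seq, alphabet="nucleotide"))
    return out
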