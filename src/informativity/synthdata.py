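"""Seeded synthetic communities for end-to-end testing without downloads.

The generator builds the world the threshold machinery is meant to resolve:

* a *taxon of interest* — a type-species genome of random protein-coding
  genes plus relative genomes whose proteins are mutated copies at a
  controlled amino-acid identity (within-taxon conservation);
* an *out-group* of unrelated random genes, except that exact copies of
  selected taxon genes are planted into out-group genomes, emulating lateral
  gene transfer — exactly the situation in which a best homology hit
  misleads taxonomic assignment;
* *metagenomic contigs*: random substrings of the nucleotide genomes, on
  either strand, with independent per-base substitution errors.

Proteins are back-translated with uniformly random synonymous codons; codon
bias is not modeled because all downstream comparisons happen in protein
space.  A truth table records which genes were planted as transfers and
should therefore end up classified uninformative.  Everything is
deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seqio import SequenceRecord, reverse_complement, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codon choices per amino acid (standard code), plus stop codons
_TABLE1 = unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE1.forward_table.items()):
    _CODONS.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(_TABLE1.stop_codons)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic community.

    Defaults describe a moderately diverged phage taxon: five genomes
    sharing 30 genes at 85% amino-acid identity, three of which also occur
    verbatim in out-group genomes (planted lateral transfers), sampled as
    assembly-sized contigs (1-4 kb) with a 0.5% per-base error rate.
    """

    seed: int = 0
    n_taxon_genomes: int = 5
    n_genes: int = 30
    gene_len_aa: tuple[int, int] = (100, 250)
    within_taxon_identity: float = 85.0
    n_outgroup_genomes: int = 5
    n_outgroup_genes: int = 30  # random genes per out-group genome
    lgt_gene_ids: tuple[int, ...] = (0, 12, 25)
    contig_len: tuple[int, int] = (1000, 4000)
    n_contigs: int = 200
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.within_taxon_identity <= 100.0):
            raise ValueError("within_taxon_identity must be in (0, 100]")
        if any(i < 0 or i >= self.n_genes for i in self.lgt_gene_ids):
            raise ValueError("lgt_gene_ids must index into the gene set")
        for name in ("n_taxon_genomes", "n_genes", "n_outgroup_genomes",
                     "n_outgroup_genes", "n_contigs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class Genome:
    """One genome: ordered CDS with protein and nucleotide forms."""

    genome_id: str
    proteins: tuple[SequenceRecord, ...]
    cds_nucleotide: tuple[SequenceRecord, ...]

    @property
    def nucleotide(self) -> SequenceRecord:
        """The genome as one nucleotide sequence (concatenated CDS)."""
        return SequenceRecord(id=self.genome_id,
                              seq="".join(c.seq for c in self.cds_nucleotide),
                              alphabet="nucleotide")


@dataclass(frozen=True)
class Community:
    """A generated taxon + out-group world with its planted-transfer truth."""

    spec: CommunitySpec
    taxon_genomes: tuple[Genome, ...]  # first genome is the type species
    outgroup_genomes: tuple[Genome, ...]
    truth: dict[str, bool]  # gene_id -> planted as lateral transfer

    @property
    def type_species(self) -> Genome:
        return self.taxon_genomes[0]

    @property
    def relatives(self) -> tuple[Genome, ...]:
        return self.taxon_genomes[1:]

    def outgroup_proteins(self) -> list[SequenceRecord]:
        return [p for g in self.outgroup_genomes for p in g.proteins]


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_protein(seq: str, target_identity: float,
                   rng: np.random.Generator | int) -> str:
    """Substitute residues to reach a positional identity target.

    Exactly round((1 - target_identity/100) * len) positions, chosen without
    replacement, are replaced with a uniformly chosen *different* residue,
    so the positional identity to the input is exact by construction.
    """
    if not seq:
        raise ValueError("cannot mutate an empty sequence")
    if not (0.0 < target_identity <= 100.0):
        raise ValueError("target_identity must be in (0, 100]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_sub = round((1.0 - target_identity / 100.0) * len(seq))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in sorted(positions):
        alternatives = [a for a in AA20 if a != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator,
                   add_stop: bool = True) -> str:
    """Nucleotide CDS for a protein via uniform random synonymous codons."""
    codons = [
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    ]
    if add_stop:
        codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def _build_genome(genome_id: str, proteins: Sequence[tuple[str, str]],
                  rng: np.random.Generator) -> Genome:
    prot_records = []
    cds_records = []
    for gene_id, prot in proteins:
        prot_records.append(
            SequenceRecord(id=gene_id, seq=prot, alphabet="protein"))
        cds_records.append(
            SequenceRecord(id=gene_id, seq=back_translate(prot, rng),
                           alphabet="nucleotide"))
    return Genome(genome_id=genome_id, proteins=tuple(prot_records),
                  cds_nucleotide=tuple(cds_records))


def make_community(spec: CommunitySpec) -> Community:
    """Generate the taxon, relatives, and out-group with planted transfers."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_len_aa
    gene_lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    type_proteins = [
        (f"gene_{i:03d}", random_protein(int(n), rng))
        for i, n in enumerate(gene_lengths)
    ]
    taxon_genomes = [_build_genome("taxon_type", type_proteins, rng)]
    for k in range(1, spec.n_taxon_genomes):
        gid = f"taxon_rel{k}"
        mutated = [
            (f"{gid}|{gene_id}",
             mutate_protein(prot, spec.within_taxon_identity, rng))
            for gene_id, prot in type_proteins
        ]
        taxon_genomes.append(_build_genome(gid, mutated, rng))

    lgt_ids = {f"gene_{i:03d}" for i in spec.lgt_gene_ids}
    outgroup_genomes = []
    planted = sorted(lgt_ids)
    for k in range(spec.n_outgroup_genomes):
        gid = f"outgroup_{k}"
        genes: list[tuple[str, str]] = []
        # planted transfers are spread round-robin across out-group genomes
        for j, gene_id in enumerate(planted):
            if j % max(spec.n_outgroup_genomes, 1) == k:
                prot = dict(type_proteins)[gene_id]
                genes.append((f"{gid}|lgt|{gene_id}", prot))
        for j in range(spec.n_outgroup_genes):
            length = int(rng.integers(lo, hi + 1))
            genes.append((f"{gid}|rand_{j:03d}", random_protein(length, rng)))
        outgroup_genomes.append(_build_genome(gid, genes, rng))

    truth = {gene_id: gene_id in lgt_ids for gene_id, _ in type_proteins}
    return Community(spec=spec, taxon_genomes=tuple(taxon_genomes),
                     outgroup_genomes=tuple(outgroup_genomes), truth=truth)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_contigs(genomes: Sequence[Genome], spec: CommunitySpec,
                     seed: int | None = None,
                     prefix: str = "ctg") -> list[SequenceRecord]:
    """Sample error-bearing contigs from a set of nucleotide genomes.

    Each contig is a uniform random substring (length within
    ``spec.contig_len``), reverse-complemented with probability 1/2, with
    independent per-base substitution errors at ``spec.error_rate``.  The
    description encodes the source genome, coordinates, and strand — the
    per-contig truth.
    """
    if not genomes:
        raise ValueError("no genomes to sample contigs from")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    seqs = [g.nucleotide.seq for g in genomes]
    lo, hi = spec.contig_len
    shortest = min(len(s) for s in seqs)
    if lo > shortest:
        raise ValueError(
            f"minimum contig length {lo} exceeds shortest genome ({shortest} nt)"
        )
    contigs: list[SequenceRecord] = []
    for i in range(spec.n_contigs):
        g = int(rng.integers(len(genomes)))
        genome_seq = seqs[g]
        length = int(rng.integers(lo, min(hi, len(genome_seq)) + 1))
        start = int(rng.integers(0, len(genome_seq) - length + 1))
        sub = genome_seq[start:start + length]
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            sub = reverse_complement(sub)
        arr = np.frombuffer(sub.encode(), dtype=np.uint8).copy()
        err = rng.random(length) < spec.error_rate
        if err.any():
            idx = np.flatnonzero(err)
            # substitute with one of the three other bases
            shifts = rng.integers(1, 4, size=idx.size)
            for pos, shift in zip(idx, shifts):
                base_i = int(np.where(_BASES == arr[pos])[0][0])
                arr[pos] = _BASES[(base_i + shift) % 4]
        cid = f"{prefix}{i:04d}"
        desc = (f"{cid} src={genomes[g].genome_id}:{start}-{start + length}"
                f"({strand})")
        contigs.append(SequenceRecord(id=cid, seq=arr.tobytes().decode(),
                                      alphabet="nucleotide", description=desc))
    return contigs


def write_community(community: Community, outdir: str | Path) -> dict[str, Path]:
    """Write community FASTAs plus the planted-transfer truth table.

    Returns the paths written: type-species CDS (nucleotide), one protein
    FASTA per relative genome, pooled out-group proteins, and the truth TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes_path = outdir / "taxon_genes.fna"
    write_fasta(community.type_species.cds_nucleotide, genes_path)
    paths["genes_x"] = genes_path

    for genome in community.relatives:
        p = outdir / f"relative_{genome.genome_id}.faa"
        write_fasta(genome.proteins, p)
        paths[genome.genome_id] = p

    outgroup_path = outdir / "outgroup.faa"
    write_fasta(community.outgroup_proteins(), outgroup_path)
    paths["outgroup_z"] = outgroup_path

    truth_path = outdir / "truth.tsv"
    pd.DataFrame(
        [{"gene_id": gid, "planted_lgt": str(flag).lower()}
         for gid, flag in community.truth.items()]
    ).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
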