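"""Per-gene taxonomic signal thresholds from within-taxon vs out-group homology.

The threshold for a gene is established in two steps.  Step one compares the
gene against the annotated proteins of one or more known relative genomes of
the same taxon and records the identity/coverage pair (S1, Q1) of the *most
dissimilar* homolog found — the per-genome best hit with the lowest weighted
score — capturing how conserved the gene is across the group.  A gene with no
within-taxon homolog (unique to the type species) gets S1 = Q1 = 0.  Step two
compares the gene against the out-group: everything assayed by the metagenome
minus the taxon and its relatives.  Here the single *best* hit supplies
(S2, Q2); no out-group homolog means S2 = Q2 = 0.

The threshold pair is T = (dS, dQ) = (S1 - S2, Q1 - Q2), collapsed to
t_scalar = w_S*dS + w_Q*dQ with equal weights by default.  A gene is an
informative marker of the taxon's presence iff its threshold is above zero:
detection of such a gene looks more like the taxon than like anything outside
it.  Genes failing that test are either shared across groups (laterally
transferred or broadly conserved: reason ``outgroup_dominant``) or seen only
in the single reference genome (reason ``unique_to_type``), and cannot
support a taxonomic call on their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .homology import HomologyHit, SearchParams, best_hit, search
from .seqio import SequenceRecord

#: gene_class values
INFORMATIVE = "informative"
UNINFORMATIVE = "uninformative"

#: reason codes for uninformative genes
REASON_OK = "ok"
REASON_UNIQUE = "unique_to_type"
REASON_OUTGROUP = "outgroup_dominant"

THRESHOLD_COLUMNS = [
    "gene_id", "S1", "Q1", "S2", "Q2", "dS", "dQ", "t_scalar",
    "gene_class", "reason", "source_genome", "source_gene", "source_taxon",
]


@dataclass(frozen=True)
class StepOneScore:
    """Within-taxon conservation of one gene: its most dissimilar homolog."""

    gene_id: str
    S1: float
    Q1: float
    source_genome: str | None = None
    source_gene: str | None = None


@dataclass(frozen=True)
class StepTwoScore:
    """Cross-group homology of one gene: its best out-group hit."""

    gene_id: str
    S2: float
    Q2: float
    source_taxon: str | None = None


@dataclass(frozen=True)
class GeneThreshold:
    gene_id: str
    S1: float
    Q1: float
    S2: float
    Q2: float
    dS: float
    dQ: float
    t_scalar: float
    gene_class: str
    reason: str
    source_genome: str | None = None
    source_gene: str | None = None
    source_taxon: str | None = None


def step1_within_taxon(
    genes_x: Sequence[SequenceRecord],
    member_genomes: Sequence[tuple[str, Sequence[SequenceRecord]]],
    params: SearchParams | None = None,
    self_genome_id: str | None = None,
) -> list[StepOneScore]:
    """Score each gene against each relative genome; keep the weakest best hit.

    For every gene the best hit is found per member genome; among genomes
    where a homolog was detected, the genome whose best hit has the *lowest*
    weighted score supplies (S1, Q1).  Genomes without a homolog do not force
    zeros — zeros are reserved for genes with no within-taxon homolog at all.
    A genome whose id equals ``self_genome_id`` is skipped (no
    self-comparison).
    """
    if params is None:
        params = SearchParams()
    if not genes_x:
        raise ValueError("empty gene set")
    members = [(gid, prots) for gid, prots in member_genomes
               if gid != self_genome_id]
    if not members:
        raise ValueError("no member genomes to compare against")

    # best hit per (gene, genome)
    per_gene: dict[str, list[tuple[str, HomologyHit]]] = {g.id: [] for g in genes_x}
    for genome_id, proteins in members:
        hits = search(genes_x, list(proteins), params)
        by_query: dict[str, list[HomologyHit]] = {}
        for h in hits:
            by_query.setdefault(h.query_id, []).append(h)
        for gene_id, gene_hits in by_query.items():
            bh = best_hit(gene_hits, params.weights)
            if bh is not None:
                per_gene[gene_id].append((genome_id, bh))

    scores: list[StepOneScore] = []
    for gene in genes_x:
        candidates = per_gene[gene.id]
        if not candidates:
            scores.append(StepOneScore(gene_id=gene.id, S1=0.0, Q1=0.0))
            continue
        # most dissimilar homolog: minimum weighted score; ties resolved
        # toward the lexicographically smallest genome id for determinism
        genome_id, hit = min(
            candidates,
            key=lambda gh: (gh[1].weighted_score(params.weights),
                            -gh[1].bitscore, gh[0]),
        )
        scores.append(StepOneScore(gene_id=gene.id, S1=hit.pct_identity,
                                   Q1=hit.qcov, source_genome=genome_id,
                                   source_gene=hit.subject_id))
    return scores


def step2_outgroup(
    genes_x: Sequence[SequenceRecord],
    outgroup_z: Sequence[SequenceRecord],
    params: SearchParams | None = None,
) -> list[StepTwoScore]:
    """Score each gene against the out-group; keep the single best hit.

    ``outgroup_z`` must exclude the taxon of interest and the step-one
    relatives; an id collision between the gene set and the out-group is
    treated as a configuration error.
    """
    if params is None:
        params = SearchParams()
    if not genes_x:
        raise ValueError("empty gene set")
    collisions = {g.id for g in genes_x} & {z.id for z in outgroup_z}
    if collisions:
        raise ValueError(
            f"out-group shares ids with the taxon of interest: {sorted(collisions)[:5]}"
        )
    scores: list[StepTwoScore] = []
    if not outgroup_z:
        return [StepTwoScore(gene_id=g.id, S2=0.0, Q2=0.0) for g in genes_x]
    hits = search(genes_x, list(outgroup_z), params)
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    for gene in genes_x:
        bh = best_hit(by_query.get(gene.id, []), params.weights)
        if bh is None:
            scores.append(StepTwoScore(gene_id=gene.id, S2=0.0, Q2=0.0))
        else:
            scores.append(StepTwoScore(gene_id=gene.id, S2=bh.pct_identity,
                                       Q2=bh.qcov, source_taxon=bh.subject_id))
    return scores


def compute_threshold(
    s1: StepOneScore,
    s2: StepTwoScore,
    weights: tuple[float, float] = (0.5, 0.5),
    componentwise: bool = False,
) -> GeneThreshold:
    """Combine the two steps into the gene's threshold and class.

    Default test: t_scalar = w_S*dS + w_Q*dQ > 0.  With ``componentwise``
    the stricter rule dS > 0 AND dQ > 0 is applied instead; the scalar is
    still reported.
    """
    if s1.gene_id != s2.gene_id:
        raise ValueError(f"gene id mismatch: {s1.gene_id!r} vs {s2.gene_id!r}")
    w_s, w_q = weights
    d_s = s1.S1 - s2.S2
    d_q = s1.Q1 - s2.Q2
    t_scalar = w_s * d_s + w_q * d_q
    informative = (d_s > 0 and d_q > 0) if componentwise else t_scalar > 0
    if informative:
        gene_class, reason = INFORMATIVE, REASON_OK
    elif s1.S1 == s1.Q1 == 0.0 and s2.S2 == s2.Q2 == 0.0:
        gene_class, reason = UNINFORMATIVE, REASON_UNIQUE
    else:
        gene_class, reason = UNINFORMATIVE, REASON_OUTGROUP
    return GeneThreshold(
        gene_id=s1.gene_id, S1=s1.S1, Q1=s1.Q1, S2=s2.S2, Q2=s2.Q2,
        dS=d_s, dQ=d_q, t_scalar=t_scalar, gene_class=gene_class,
        reason=reason, source_genome=s1.source_genome,
        source_gene=s1.source_gene, source_taxon=s2.source_taxon,
    )


def threshold_table(
    genes_x: Sequence[SequenceRecord],
    member_genomes: Sequence[tuple[str, Sequence[SequenceRecord]]],
    outgroup_z: Sequence[SequenceRecord],
    params: SearchParams | None = None,
    componentwise: bool = False,
    self_genome_id: str | None = None,
) -> list[GeneThreshold]:
    """Full two-step threshold computation for every gene, in gene order."""
    if params is None:
        params = SearchParams()
    ones = step1_within_taxon(genes_x, member_genomes, params,
                              self_genome_id=self_genome_id)
    twos = step2_outgroup(genes_x, outgroup_z, params)
    return [
        compute_threshold(s1, s2, params.weights, componentwise=componentwise)
        for s1, s2 in zip(ones, twos)
    ]


def thresholds_to_frame(thresholds: Iterable[GeneThreshold]) -> pd.DataFrame:
    rows = []
    for t in thresholds:
        rows.append({
            "gene_id": t.gene_id,
            "S1": t.S1, "Q1": t.Q1, "S2": t.S2, "Q2": t.Q2,
            "dS": t.dS, "dQ": t.dQ, "t_scalar": t.t_scalar,
            "gene_class": t.gene_class, "reason": t.reason,
            "source_genome": t.source_genome or "",
            "source_gene": t.source_gene or "",
            "source_taxon": t.source_taxon or "",
        })
    return pd.DataFrame(rows, columns=THRESHOLD_COLUMNS)


def write_threshold_tsv(thresholds: Iterable[GeneThreshold],
                        path: str | Path) -> None:
    """Write the per-gene threshold table (floats at 2 decimals)."""
    df = thresholds_to_frame(thresholds)
    df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def read_threshold_tsv(path: str | Path) -> list[GeneThreshold]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str},
                     keep_default_na=False)
    missing = set(THRESHOLD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing threshold columns {sorted(missing)}")
    out: list[GeneThreshold] = []
    for row in df.itertuples(index=False):
        out.append(GeneThreshold(
            gene_id=row.gene_id,
            S1=float(row.S1), Q1=float(row.Q1),
            S2=float(row.S2), Q2=float(row.Q2),
            dS=float(row.dS), dQ=float(row.dQ),
            t_scalar=float(row.t_scalar),
            gene_class=row.gene_class, reason=row.reason,
            source_genome=row.source_genome or None,
            source_gene=row.source_gene or None,
            source_taxon=row.source_taxon or None,
        ))
    return out
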