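"""Score metagenomic hits against per-gene thresholds and aggregate evidence.

A hit to gene with threshold T = (dS, dQ) has informativity
I = (S_H - dS, Q_H - dQ), collapsed to I_scalar = w_S*I_S + w_Q*I_Q.  A hit
at or above the gene's threshold (I_scalar >= 0; the boundary is "equivalent
to the threshold" and counts as informative) to a gene that is itself
informative supports the presence of the taxon of interest or a close
relative; the larger I, the stronger the support, up to 100 in the limiting
case T = (0, 0) with a perfect hit.  Hits to uninformative genes are kept in
the output with class ``gene_uninformative`` — they are still real homology
and belong in displays — but never count toward presence.

Samples are scanned by six-frame translating their contigs into an ORF
protein database and querying each reference gene against it, so coverage
Q_H is coverage *of the gene*, not of the contig, and fragmentary contigs
carrying the gene in any frame or orientation are found.  Per gene only the
single best hit in a sample is assessed.  Aggregation is deliberately
descriptive — counts, fraction of informative genes detected, mean and max
I — leaving probabilistic interpretation to the user.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .homology import HomologyHit, SearchParams, best_hit, search
from .seqio import SequenceRecord, orf_database
from .thresholds import INFORMATIVE, GeneThreshold

#: hit_class values
HIT_INFORMATIVE = "informative"
HIT_UNINFORMATIVE = "uninformative"
HIT_GENE_UNINFORMATIVE = "gene_uninformative"

#: matrix sentinels (strings, so the TSV stays self-describing)
NO_HIT = "no_hit"
GENE_UNINFORMATIVE = "gene_uninformative"

HITS_COLUMNS = ["sample_id", "gene_id", "contig_id", "frame",
                "S_H", "Q_H", "I_S", "I_Q", "I_scalar", "hit_class"]
SUMMARY_COLUMNS = ["sample_id", "n_genes_informative", "n_hit",
                   "n_informative_hits", "mean_I", "max_I", "fraction_detected"]


@dataclass(frozen=True)
class HitAssessment:
    """One sample hit qualified against its gene's taxonomic signal threshold."""

    sample_id: str
    gene_id: str
    contig_id: str
    frame: int | None
    S_H: float
    Q_H: float
    I_S: float
    I_Q: float
    I_scalar: float
    hit_class: str


@dataclass(frozen=True)
class SampleSummary:
    """Descriptive aggregate of one sample's informative-gene evidence."""

    sample_id: str
    n_genes_informative: int
    n_hit: int  # informative genes with any hit, whatever its class
    n_informative_hits: int
    mean_I: float | None  # over informative hits; None when there are none
    max_I: float | None
    fraction_detected: float


def _orf_contig_and_frame(subject_id: str) -> tuple[str, int | None]:
    """Recover contig id and frame from an ORF database header."""
    parts = subject_id.rsplit("|", 2)
    if len(parts) == 3:
        try:
            return parts[0], int(parts[1])
        except ValueError:
            pass
    return subject_id, None


def assess_hit(hit: HomologyHit, thr: GeneThreshold,
               weights: tuple[float, float] = (0.5, 0.5),
               sample_id: str = "", componentwise: bool = False
               ) -> HitAssessment:
    """Qualify one hit against its gene's threshold.

    The informativity pair is always computed; the class is
    ``gene_uninformative`` whenever the gene itself is uninformative,
    otherwise ``informative`` iff the hit is at or above the threshold.
    """
    if hit.query_id != thr.gene_id:
        raise ValueError(
            f"hit query {hit.query_id!r} does not match threshold gene "
            f"{thr.gene_id!r}"
        )
    w_s, w_q = weights
    i_s = hit.pct_identity - thr.dS
    i_q = hit.qcov - thr.dQ
    i_scalar = w_s * i_s + w_q * i_q
    if thr.gene_class != INFORMATIVE:
        hit_class = HIT_GENE_UNINFORMATIVE
    else:
        above = (i_s >= 0 and i_q >= 0) if componentwise else i_scalar >= 0
        hit_class = HIT_INFORMATIVE if above else HIT_UNINFORMATIVE
    contig_id, frame = _orf_contig_and_frame(hit.subject_id)
    return HitAssessment(
        sample_id=sample_id, gene_id=thr.gene_id, contig_id=contig_id,
        frame=frame, S_H=hit.pct_identity, Q_H=hit.qcov,
        I_S=i_s, I_Q=i_q, I_scalar=i_scalar, hit_class=hit_class,
    )


def scan_sample(
    genes_x: Sequence[SequenceRecord],
    thresholds: Sequence[GeneThreshold],
    contigs: Sequence[SequenceRecord],
    params: SearchParams | None = None,
    sample_id: str = "sample",
    min_orf_aa: int = 20,
    componentwise: bool = False,
    table: int = 1,
) -> list[HitAssessment]:
    """Assess one metagenomic sample against the reference gene set.

    Contigs are six-frame translated into an ORF protein database; each gene
    is searched against it and its single best hit in the sample is
    assessed.  Genes with no hit are omitted (absence is recoverable from the
    summary).  Every gene must have a threshold.
    """
    if params is None:
        params = SearchParams()
    thr_by_gene = {t.gene_id: t for t in thresholds}
    missing = [g.id for g in genes_x if g.id not in thr_by_gene]
    if missing:
        raise ValueError(f"no threshold for gene(s): {missing[:5]}")
    if not contigs:
        return []
    db = orf_database(contigs, min_orf_aa=min_orf_aa, table=table)
    if not db:
        return []
    hits = search(genes_x, db, params)
    by_query: dict[str, list[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    assessments: list[HitAssessment] = []
    for gene in genes_x:
        bh = best_hit(by_query.get(gene.id, []), params.weights)
        if bh is None:
            continue
        assessments.append(assess_hit(bh, thr_by_gene[gene.id], params.weights,
                                      sample_id=sample_id,
                                      componentwise=componentwise))
    return assessments


def summarize_sample(assessments: Sequence[HitAssessment],
                     thresholds: Sequence[GeneThreshold],
                     sample_id: str | None = None) -> SampleSummary:
    """Collapse a sample's assessments into presence/absence evidence."""
    ids = {a.sample_id for a in assessments}
    if len(ids) > 1:
        raise ValueError(f"mixed sample ids: {sorted(ids)}")
    if sample_id is None:
        sample_id = next(iter(ids)) if ids else ""
    informative_genes = {t.gene_id for t in thresholds
                         if t.gene_class == INFORMATIVE}
    n_inf = len(informative_genes)
    n_hit = sum(1 for a in assessments if a.gene_id in informative_genes)
    inf_hits = [a for a in assessments if a.hit_class == HIT_INFORMATIVE]
    n_inf_hits = len(inf_hits)
    mean_i = (sum(a.I_scalar for a in inf_hits) / n_inf_hits
              if inf_hits else None)
    max_i = max((a.I_scalar for a in inf_hits), default=None)
    fraction = n_inf_hits / n_inf if n_inf else 0.0
    return SampleSummary(
        sample_id=sample_id, n_genes_informative=n_inf, n_hit=n_hit,
        n_informative_hits=n_inf_hits, mean_I=mean_i, max_I=max_i,
        fraction_detected=fraction,
    )


def informativity_matrix(
    per_sample: Sequence[tuple[str, Sequence[HitAssessment]]],
    thresholds: Sequence[GeneThreshold],
) -> pd.DataFrame:
    """Samples x genes matrix of best-hit I_scalar values.

    Columns follow the gene order of the threshold table.  Cells hold the
    I_scalar of the sample's best hit to the gene, the sentinel ``no_hit``
    when the gene produced no hit in the sample, or ``gene_uninformative``
    when the gene itself carries no taxonomic signal (hits to it, if any,
    still appear in the hits table).
    """
    sample_ids = [sid for sid, _ in per_sample]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in matrix input")
    gene_order = [t.gene_id for t in thresholds]
    uninformative = {t.gene_id for t in thresholds
                     if t.gene_class != INFORMATIVE}
    rows = []
    for sid, assessments in per_sample:
        by_gene = {a.gene_id: a for a in assessments}
        row: dict[str, object] = {"sample_id": sid}
        for gid in gene_order:
            a = by_gene.get(gid)
            if gid in uninformative:
                row[gid] = GENE_UNINFORMATIVE
            elif a is None:
                row[gid] = NO_HIT
            else:
                row[gid] = f"{a.I_scalar:.2f}"
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *gene_order])


def hits_to_frame(assessments: Iterable[HitAssessment]) -> pd.DataFrame:
    rows = [{
        "sample_id": a.sample_id, "gene_id": a.gene_id,
        "contig_id": a.contig_id,
        "frame": "" if a.frame is None else a.frame,
        "S_H": a.S_H, "Q_H": a.Q_H, "I_S": a.I_S, "I_Q": a.I_Q,
        "I_scalar": a.I_scalar, "hit_class": a.hit_class,
    } for a in assessments]
    return pd.DataFrame(rows, columns=HITS_COLUMNS)


def write_hits_tsv(assessments: Iterable[HitAssessment],
                   path: str | Path) -> None:
    hits_to_frame(assessments).to_csv(path, sep="\t", index=False,
                                      float_format="%.2f")


def read_hits_tsv(path: str | Path) -> list[HitAssessment]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str,
                                            "contig_id": str},
                     keep_default_na=False)
    out: list[HitAssessment] = []
    for row in df.itertuples(index=False):
        frame = None if row.frame in ("", None) else int(float(row.frame))
        out.append(HitAssessment(
            sample_id=row.sample_id, gene_id=row.gene_id,
            contig_id=row.contig_id, frame=frame,
            S_H=float(row.S_H), Q_H=float(row.Q_H),
            I_S=float(row.I_S), I_Q=float(row.I_Q),
            I_scalar=float(row.I_scalar), hit_class=row.hit_class,
        ))
    return out


def write_summary_tsv(summaries: Iterable[SampleSummary],
                      path: str | Path) -> None:
    rows = [{
        "sample_id": s.sample_id,
        "n_genes_informative": s.n_genes_informative,
        "n_hit": s.n_hit,
        "n_informative_hits": s.n_informative_hits,
        "mean_I": "" if s.mean_I is None else f"{s.mean_I:.2f}",
        "max_I": "" if s.max_I is None else f"{s.max_I:.2f}",
        "fraction_detected": f"{s.fraction_detected:.4f}",
    } for s in summaries]
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t",
                                                       index=False)
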