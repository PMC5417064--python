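"""Hit assessment against thresholds, sample summaries, and the matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from informativity.homology import HomologyHit
from informativity.informativity import (GENE_UNINFORMATIVE, NO_HIT,
                                         HitAssessment, assess_hit,
                                         hits_to_frame, informativity_matrix,
                                         read_hits_tsv, scan_sample,
                                         summarize_sample, write_hits_tsv)
from informativity.seqio import SequenceRecord
from informativity.synthdata import (CommunitySpec, make_community,
                                     simulate_contigs)
from informativity.thresholds import (GeneThreshold, StepOneScore,
                                      StepTwoScore, compute_threshold,
                                      threshold_table)

percents = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


def _thr(gene_id="g", S1=0.0, Q1=0.0, S2=0.0, Q2=0.0, **kw):
    return compute_threshold(StepOneScore(gene_id, S1, Q1),
                             StepTwoScore(gene_id, S2, Q2), **kw)


def _hit(query_id="g", S=100.0, Q=100.0, subject="ctg1|+1|0-50"):
    return HomologyHit(query_id=query_id, subject_id=subject,
                       pct_identity=S, qcov=Q, aln_len=50, q_start=0,
                       q_end=50, s_start=0, s_end=50, bitscore=100.0,
                       evalue=1e-20)


def _assessment(gene_id, sample_id="s1", I=50.0, hit_class="informative"):
    return HitAssessment(sample_id=sample_id, gene_id=gene_id,
                         contig_id="c", frame=1, S_H=90.0, Q_H=90.0,
                         I_S=I, I_Q=I, I_scalar=I, hit_class=hit_class)


class TestAssessHit:
    def test_perfect_hit_against_zero_threshold_scores_100(self):
        a = assess_hit(_hit(S=100, Q=100), _thr(S1=0, Q1=0, S2=0, Q2=0))
        assert a.I_scalar == 100.0
        assert (a.I_S, a.I_Q) == (100.0, 100.0)

    def test_hit_exactly_at_threshold_scores_0_and_is_informative(self):
        thr = _thr(S1=60, Q1=40)  # T = (60, 40), informative gene
        a = assess_hit(_hit(S=60, Q=40), thr)
        assert a.I_scalar == 0.0
        assert a.hit_class == "informative"

    def test_hit_below_threshold_is_uninformative(self):
        thr = _thr(S1=60, Q1=60)
        a = assess_hit(_hit(S=50, Q=50), thr)
        assert a.I_scalar == -10.0
        assert a.hit_class == "uninformative"

    def test_uninformative_gene_overrides_any_score(self):
        thr = _thr(S1=0, Q1=0, S2=80, Q2=90)  # outgroup-dominant gene
        a = assess_hit(_hit(S=100, Q=100), thr)
        assert a.hit_class == "gene_uninformative"
        assert a.I_scalar == pytest.approx(0.5 * (100 + 80) + 0.5 * (100 + 90))

    def test_componentwise_mode(self):
        thr = _thr(S1=60, Q1=20)
        # scalar I = 0.5*(70-60) + 0.5*(10-20) = 0 -> informative
        assert assess_hit(_hit(S=70, Q=10), thr).hit_class == "informative"
        assert assess_hit(_hit(S=70, Q=10), thr,
                          componentwise=True).hit_class == "uninformative"

    def test_orf_provenance_is_decoded(self):
        a = assess_hit(_hit(subject="ctg7|-2|10-60"), _thr())
        assert (a.contig_id, a.frame) == ("ctg7", -2)

    def test_gene_threshold_mismatch_raises(self):
        with pytest.raises(ValueError):
            assess_hit(_hit(query_id="g1"), _thr(gene_id="g2"))

    @given(percents, percents, st.floats(min_value=0.1, max_value=99.9))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_informativity_is_monotone_in_hit_quality(self, s, q, bump):
        thr = _thr(S1=70, Q1=70, S2=10, Q2=10)
        base = assess_hit(_hit(S=s, Q=q), thr)
        better_s = assess_hit(_hit(S=min(s + bump, 100.0), Q=q), thr)
        better_q = assess_hit(_hit(S=s, Q=min(q + bump, 100.0)), thr)
        if s + bump <= 100.0:
            assert better_s.I_scalar > base.I_scalar
        if q + bump <= 100.0:
            assert better_q.I_scalar > base.I_scalar

    @given(percents, percents, st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reweighting_consistency(self, s, q, w):
        thr = _thr(S1=80, Q1=90, S2=20, Q2=10)
        a = assess_hit(_hit(S=s, Q=q), thr, weights=(w, 1 - w))
        assert a.I_scalar == pytest.approx(w * a.I_S + (1 - w) * a.I_Q)

    def test_informative_hit_bounded_by_100_minus_threshold(self):
        thr = _thr(S1=80, Q1=90)
        a = assess_hit(_hit(S=100, Q=100), thr)
        assert a.I_scalar == pytest.approx(100.0 - thr.t_scalar)


@pytest.fixture(scope="module")
def scan_world():
    spec = CommunitySpec(seed=21, n_taxon_genomes=3, n_genes=6,
                         gene_len_aa=(90, 140), n_outgroup_genomes=2,
                         n_outgroup_genes=6, lgt_gene_ids=(1,),
                         contig_len=(600, 1200), n_contigs=30,
                         error_rate=0.0)
    c = make_community(spec)
    genes = list(c.type_species.cds_nucleotide)
    members = [(g.genome_id, list(g.proteins)) for g in c.relatives]
    thresholds = threshold_table(genes, members, c.outgroup_proteins())
    return spec, c, genes, thresholds


class TestScanSample:
    def test_verbatim_genome_contig_gives_perfect_hits(self, scan_world):
        _, c, genes, thresholds = scan_world
        whole_genome = [c.type_species.nucleotide]
        assessments = scan_sample(genes, thresholds, whole_genome,
                                  sample_id="s1")
        assert len(assessments) == len(genes)
        thr = {t.gene_id: t for t in thresholds}
        for a in assessments:
            assert a.S_H == 100.0
            assert a.Q_H == 100.0
            assert a.I_scalar == pytest.approx(100.0 - thr[a.gene_id].t_scalar)

    def test_empty_contig_set_gives_empty_assessments(self, scan_world):
        _, _, genes, thresholds = scan_world
        assert scan_sample(genes, thresholds, []) == []

    def test_lgt_only_community_yields_only_gene_uninformative(self, scan_world):
        spec, c, genes, thresholds = scan_world
        outgroup_contigs = simulate_contigs(list(c.outgroup_genomes), spec,
                                            seed=99)
        assessments = scan_sample(genes, thresholds, outgroup_contigs,
                                  sample_id="s2")
        lgt_genes = {gid for gid, flag in c.truth.items() if flag}
        assert {a.gene_id for a in assessments} <= lgt_genes
        assert all(a.hit_class == "gene_uninformative" for a in assessments)

    def test_missing_threshold_is_configuration_error(self, scan_world):
        _, c, genes, thresholds = scan_world
        with pytest.raises(ValueError, match="no threshold"):
            scan_sample(genes, thresholds[:-1], [c.type_species.nucleotide])


class TestSummarize:
    def test_no_informative_hits(self):
        thresholds = [_thr(f"g{i}", S1=90, Q1=90) for i in range(5)]
        s = summarize_sample([], thresholds, sample_id="empty")
        assert s.n_genes_informative == 5
        assert s.n_informative_hits == 0
        assert s.fraction_detected == 0.0
        assert s.mean_I is None and s.max_I is None

    def test_fraction_detected_arithmetic(self):
        thresholds = [_thr(f"g{i}", S1=90, Q1=90) for i in range(10)]
        assessments = [_assessment(f"g{i}", I=float(10 * i))
                       for i in range(4)]
        s = summarize_sample(assessments, thresholds)
        assert s.n_genes_informative == 10
        assert s.n_informative_hits == 4
        assert s.fraction_detected == pytest.approx(0.4)
        assert s.mean_I == pytest.approx(15.0)
        assert s.max_I == pytest.approx(30.0)

    def test_saturated_sample(self):
        thresholds = [_thr(f"g{i}") for i in range(3)]  # T=(0,0) limit
        assessments = [_assessment(f"g{i}", I=100.0) for i in range(3)]
        # T=(0,0) genes are classed uninformative (unique to type species),
        # so force informative thresholds instead
        thresholds = [_thr(f"g{i}", S1=100, Q1=100) for i in range(3)]
        assessments = [_assessment(f"g{i}", I=0.0) for i in range(3)]
        s = summarize_sample(assessments, thresholds)
        assert s.fraction_detected == 1.0

    def test_mixed_sample_ids_raise(self):
        with pytest.raises(ValueError, match="mixed"):
            summarize_sample([_assessment("g1", sample_id="a"),
                              _assessment("g2", sample_id="b")], [])


class TestMatrix:
    def test_sentinels_and_single_numeric_cell(self):
        thresholds = [_thr("g1", S1=90, Q1=90),
                      _thr("g2", S1=90, Q1=90),
                      _thr("g3", S1=0, Q1=0, S2=50, Q2=50)]  # uninformative
        per_sample = [("s1", [_assessment("g1", I=42.5)]), ("s2", [])]
        df = informativity_matrix(per_sample, thresholds)
        assert list(df.columns) == ["sample_id", "g1", "g2", "g3"]
        assert df.loc[0, "g1"] == "42.50"
        assert df.loc[1, "g1"] == NO_HIT
        assert df.loc[0, "g2"] == NO_HIT
        assert (df["g3"] == GENE_UNINFORMATIVE).all()

    def test_duplicate_sample_ids_raise(self):
        with pytest.raises(ValueError, match="duplicate"):
            informativity_matrix([("s1", []), ("s1", [])], [])


class TestHitsTsv:
    def test_round_trip(self, tmp_path):
        assessments = [_assessment("g1", I=12.345),
                       _assessment("g2", I=-3.0, hit_class="uninformative")]
        p = tmp_path / "hits.tsv"
        write_hits_tsv(assessments, p)
        back = read_hits_tsv(p)
        assert [a.gene_id for a in back] == ["g1", "g2"]
        assert back[0].I_scalar == pytest.approx(12.35)  # 2-decimal format
        assert back[1].hit_class == "uninformative"

    def test_column_order(self):
        df = hits_to_frame([_assessment("g1")])
        assert list(df.columns) == ["sample_id", "gene_id", "contig_id",
                                    "frame", "S_H", "Q_H", "I_S", "I_Q",
                                    "I_scalar", "hit_class"]
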