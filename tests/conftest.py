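"""Shared fixtures: small synthetic worlds sized for fast unit tests."""

import pytest

from informativity import (CommunitySpec, SearchParams, make_community,
                           simulate_contigs, threshold_table)


@pytest.fixture(scope="session")
def small_spec() -> CommunitySpec:
    """A scaled-down community: quick to build, same structure as default."""
    return CommunitySpec(seed=7, n_taxon_genomes=3, n_genes=8,
                         gene_len_aa=(80, 120), n_outgroup_genomes=2,
                         n_outgroup_genes=8, lgt_gene_ids=(2,),
                         contig_len=(400, 900), n_contigs=40)


@pytest.fixture(scope="session")
def small_community(small_spec):
    return make_community(small_spec)


@pytest.fixture(scope="session")
def small_thresholds(small_community):
    c = small_community
    genes = list(c.type_species.cds_nucleotide)
    members = [(g.genome_id, list(g.proteins)) for g in c.relatives]
    return threshold_table(genes, members, c.outgroup_proteins())


@pytest.fixture(scope="session")
def default_params() -> SearchParams:
    return SearchParams()
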