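# Methods

## Model

The package treats taxonomic assignment from homology as a per-gene
signal-detection problem. For a taxon of interest with annotated coding
sequences *X*, relative genomes *G* of the same user-defined group, and an
out-group *Z* (the assayed domain minus the group), each gene receives a
taxonomic signal threshold

    T = (dS, dQ) = (S1 − S2, Q1 − Q2)

where (S1, Q1) are percent identity and query coverage of the gene's *most
dissimilar* within-group homolog (the per-genome best hit with the lowest
weighted score, minimized over genomes that contain a homolog) and
(S2, Q2) those of its single *best* out-group hit. Zeros are reserved for
"no homolog at all" on either side. A metagenomic hit (S_H, Q_H) to the
gene scores

    I = (S_H − dS, Q_H − dQ).

Identity and coverage are collapsed with weights (w_S, w_Q), equal by
default; both components are always emitted so any re-weighting can be
recomputed exactly from the output tables.

Assumptions worth making explicit:

* Within-group conservation is measured against the genomes the user
  supplies; if they do not span the group's diversity, S1/Q1 overstate
  conservation and thresholds are too optimistic. Choice of group and
  relatives is deliberately left to the user (it sets the granularity of
  the call: strain, species, genus, ...).
* The out-group must not contain members of the group; an id collision
  between *X* and *Z* is rejected, but semantic contamination (a group
  member hiding in *Z* under another name) is undetectable and deflates
  thresholds.
* Coverage is computed in protein space over the query (the annotated
  gene), BLAST `qcovs`-style: percent of query residues spanned by the
  single best local alignment. Per (query, subject) pair only that one
  alignment is kept, so S and Q are well-defined per match; there is no
  HSP tiling.

## Classification rules

* Gene informative ⇔ t_scalar = w_S·dS + w_Q·dQ > 0 (the threshold pair is
  compared to zero through the same weighting used everywhere else). A
  strict componentwise mode (dS > 0 AND dQ > 0) sits behind a flag; it is
  never weaker than the scalar rule.
* Uninformative genes carry a machine-readable reason: `unique_to_type`
  (no homology on either side, all four scores zero) or
  `outgroup_dominant` (out-group homology at or above within-group).
* A hit is informative ⇔ its gene is informative AND I_scalar ≥ 0. The
  boundary I = 0 ("equivalent to the threshold") counts as informative.
  Hits to uninformative genes are retained with class
  `gene_uninformative` rather than dropped, so per-gene displays remain
  complete; they never count toward presence.
* For an informative gene, I_scalar of any physical hit is bounded above
  by 100 − t_scalar; the global [0, 100] range is attained only in the
  T = (0, 0) limit.

Per sample, the aggregate is deliberately descriptive: counts of
informative genes, genes hit, informative hits, mean/max I, and
fraction_detected = informative hits / informative genes. No probability
model is imposed; turning these into a presence call is interpretation,
and any threshold on fraction_detected would be arbitrary.

## Homology backends

The built-in backend is full Smith–Waterman (affine gaps) via Biopython's
PairwiseAligner: BLOSUM62, gap open 11, extend 1, under the convention
that a gap of length k costs 11 + k. Identity is counted over aligned
columns (gap columns in the denominator). Acceptance of a database hit
requires:

* positive optimal score;
* at least 15 aligned columns (suppresses micro-alignments);
* approximate E-value ≤ `evalue_max` (default 1e-3), with
  E = K·m·n·exp(−λ·score), λ = 0.267, K = 0.041 (the standard gapped
  BLOSUM62/11/1 parameters), n = total database residues and no
  effective-length corrections. This is *not* calibrated to BLAST's
  reported E-values — it is accurate to roughly an order of magnitude —
  but it is monotone in score within a search and it reproduces the
  qualitative behavior that matters: unrelated random proteins of typical
  gene length do not produce reported hits. Without this filter, long weak
  local alignments of unrelated sequences (~22 % identity over >100
  columns, raw score ~50) pass a bare positive-score test, which a
  cross-check against NCBI blastp showed reports nothing for such pairs
  even at E = 10.
* pairs are only aligned at all if they share an exact 4-residue word
  (configurable; disable with `word_size=None`). Any homolog that could
  clear the 15-column floor shares such a word with near-certainty; the
  seeding exists purely to skip the quadratic bulk of unrelated pairs and
  changes results only for hits the E-value filter would reject anyway.

`align_protein_pair` (the single-pair surface) applies none of the
database filters and returns the optimal local alignment whenever its
score is positive; the test suite holds its scores equal to an independent
brute-force dynamic program.

Precomputed BLAST tabular files are the second backend. The standard 12
columns are accepted, optionally extended with `qlen` and `qcovs`;
coverage requires one of `qcovs`, `qlen`, or an explicit query-length
mapping. Coordinates convert between BLAST's 1-based inclusive convention
and the package's 0-based half-open convention only at this boundary.

## ORF calling

Contigs are translated in all six frames and split at stop codons;
every stop-free segment ≥ 20 aa (default) is an ORF. No start codon is
required — fragmentary contigs routinely truncate genes — and codons with
unresolvable ambiguity codes translate to 'X', which cannot score
positively. The standard genetic code is the default with table 11
available. Output order (frames +1,+2,+3,−1,−2,−3, left-to-right) is
deterministic, and the ORF database headers `contig|frame|start-end`
carry provenance through to the hit tables.

## Synthetic communities

The generator states a world in which the metric's behavior is forced and
checkable: a type-species genome of random proteins; relatives derived by
substituting exactly round((1 − identity/100)·L) positions per protein
(positional identity is exact by construction); out-group genomes of
unrelated random proteins except for verbatim planted copies of selected
genes (the lateral-transfer truth); contigs as uniform random genome
substrings on either strand with independent per-base substitution
errors. Defaults: 5 taxon genomes, 30 genes of 100–250 aa, 85 %
within-taxon identity, 5 out-group genomes of 30 genes, 3 planted
transfers, 200 contigs of 1–4 kb at error rate 0.005.

Parameters not dictated by the evaluation setting were chosen once on
domain grounds: gene lengths cover typical phage CDS; contigs are
assembly-scale (1–4 kb), long enough that single contigs usually span
whole genes — necessary because an informative hit must reach
S_H + Q_H ≥ dS + dQ, which for a well-conserved gene absent from the
out-group (t ≈ 92) requires near-full gene coverage; the out-group
amino-acid background is uniform, which if anything *overstates* spurious
alignability relative to natural composition. Back-translation uses
uniform synonymous codons; codon bias is irrelevant downstream because
all comparisons are protein-space.

What a green synthetic test does establish: threshold arithmetic,
most-dissimilar/best-hit selection, planted-transfer discrimination,
frame/strand handling, and end-to-end determinism. What it does not: real
phage gene families (the generator's "unrelated" genes share no remote
homology, unlike real proteomes), indels and chimeric contigs (errors are
substitution-only), database incompleteness, or annotation errors. Real
S2 values in particular sit on a continuum rather than the near-binary
0/100 the planted world produces.

## Numerical choices

* All internal coordinates 0-based half-open; floats written at 2
  decimals in TSVs (tables are the interchange format, not a precision
  archive).
* Best-hit ties break deterministically: weighted score, then bitscore,
  then lower E-value, then lexicographically smallest subject id.
  Most-dissimilar (step-one) ties break toward the smallest genome id.
* Degenerate inputs: empty contig sets and contigs < 3 nt yield empty
  results, not errors; empty gene sets, empty databases, and id
  collisions raise.
* Determinism: a single integer seeds every generator (numpy
  `default_rng`); identical inputs and parameters reproduce byte-identical
  outputs, which the test suite asserts.

## Known limitations

* The built-in E-value is approximate (no length corrections, fixed
  gapped λ/K); analyses needing calibrated statistics should run real
  BLAST and feed the tabular output in.
* Best-hit-per-sample scoring ignores multiple independent hits to the
  same gene within one sample; abundance is out of scope.
* The threshold inherits the reference database's blind spots: as new
  genomes are published, thresholds should be recomputed (they are cheap,
  and deliberately decoupled from sample scanning for this reason).
* Six-frame ORF extraction, chosen for sensitivity, inflates the search
  space roughly sixfold relative to a gene caller; with large samples the
  word-seeding prefilter keeps this tractable, at the cost of departing
  from exhaustive Smith–Waterman for pairs with no shared 4-mer.
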