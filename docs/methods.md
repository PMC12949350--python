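# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limitations of `lgtfate`.

## The fate decision

The unit of analysis is a *triplet*: a laterally acquired (LGT) gene, its
vertically inherited homolog from the same accession, and a donor ortholog
from a representative of the donor lineage. Expression enters all tests as
log₂(TPM + 1); the +1 offset maps absence to 0 and keeps the transform
monotone, and the base is configurable (`log_base`). A gene counts as
*expressed* when it reaches ≥ 0.5 TPM in at least one sample (the threshold
is inclusive and configurable). Genes whose vertical homolog or donor
ortholog is absent or never expressed are reported but excluded from fate
calling, since both comparators are required.

Two tests feed the call: a paired Wilcoxon signed-rank test against the
vertical homolog (paired by RNA-seq sample, so shared tissue and library
effects cancel) and an unpaired Wilcoxon rank-sum test against the donor
ortholog (donor samples come from a different species). Each p-value family
is Benjamini–Hochberg adjusted across all genes in the run — the FDR family
is the run, with all accessions pooled; the scope is configurable. A gene is
*degenerating* iff both adjusted p-values fall below α (default 0.05) and
its median log-expression is below both comparators' medians. The direction
gate uses medians because rank tests are location tests on the median;
"significantly different but higher" genes remain putatively stable.

Zero paired differences use Pratt handling: zeros are included when ranking
absolute differences but dropped from the statistic, with Cureton's
adjustment to the normal approximation. The exact sign-permutation
distribution is used below 26 pairs when no zeros or ties are present;
otherwise the tie-corrected normal approximation (no continuity correction)
applies. The rank-sum test likewise uses the exact distribution for small
tie-free samples and the tie-corrected normal approximation otherwise. All
of these are validated against scipy to 1e-8 in the test suite, with scipy
as the independent oracle and the package's own implementations as the
system under test.

## Paralog handling

Recent paralogs are defined on the gene tree: every maximal clade whose
leaves all belong to recipient taxa is one paralog group (singletons
otherwise). Taxon membership comes from an explicit leaf → taxon map rather
than gene-id prefixes, because id conventions vary. Unrooted trees are
midpoint-rooted before the monophyly scan. Because expression records only
exist within an accession's own sample set, the pipeline refines
tree-derived groups by accession before aggregation: copies of the same
clade living in different genomes are never summed. Aggregation mode `sum`
adds TPM per sample (primary analysis); mode `max` keeps the per-sample
values of the member with the highest mean TPM (sensitivity analysis), with
ties broken toward the lexicographically smallest gene id. The detection
gate is applied after aggregation by default (configurable). The aggregated
record carries the lexicographically smallest member id, which is also the
id convention the synthetic catalog uses.

## Expression categories and enrichment

Putatively stable genes (after the truncation override) are categorised by
a Kruskal–Wallis test across the three groups, BH-adjusted across genes.
Non-significant omnibus tests give *no_difference*. Otherwise Dunn's post
hoc z-tests (pooled mid-ranks, tie-corrected variance, two-sided normal
p-values at raw α) decide: both pairwise tests significant → *higher* or
*intermediate* by median ordering (a gene below both comparators belongs to
the degenerating fate by construction; if it surfaces here it is recorded
as intermediate and flagged); only the vertical contrast significant →
*donor_like*; only the donor contrast significant → *recipient_like*;
neither → *no_difference*. The decision table is exhaustive and mutually
exclusive, which the tests check on random inputs.

Two exact binomial tests summarise the category counts: whether
no-difference genes form a majority (null p₀ = 0.5) and, among the
remaining genes, whether donor-like genes exceed a uniform share of the
four informative categories (null p₀ = 0.25). The null proportions are this
package's explicit choices; the two-sided p-value sums all outcome
probabilities not exceeding the observed one, with the standard 1 + 1e-7
relative guard against floating-point noise in the point masses.

## Mixed models

Gaussian contrasts use statsmodels `MixedLM` fitted by REML with a random
intercept per gene family and a nested variance component for accession
within family; p-values are Wald z tests on the fixed effects. The nested
component is dropped (and flagged) whenever it is unidentifiable: when
accession never varies within a family, or when every family × accession
cell holds a single observation (the component would be confounded with the
residual). A singular or non-converging nested fit falls back to the
family-only model, flagged. The optimizer retries L-BFGS, BFGS and CG in
that order before giving up.

Binary contrasts (truncation ~ type, fate ~ truncation) use the variational
Bayes fit of statsmodels' `BinomialBayesMixedGLM` with sparse one-hot
variance components; the reported z and p derive from the approximate
posterior mean and SD of the fixed effect. Variance components whose groups
are all singletons carry no estimable variance for a single Bernoulli draw
per group and are dropped with a flag (this is the fate of the
type-within-family term when each family contributes one gene per type). A
degenerate response (one class) is skipped with a flag; complete separation
falls back to Fisher's exact test on the 2 × 2 table. The VB routine draws
Monte Carlo samples from NumPy's legacy global RNG; the wrapper pins that
state so identical inputs give identical reports.

## Truncation

Lengths are ungapped CDS lengths, not alignment columns. Rule (i) requires
the focal CDS to be shorter than 0.70 × the length of *each* reference (the
boundary itself is not truncated); rules (ii)/(iii) require the missing
feature to be present in *all* references under the default strict gate,
with a `majority` gate available. The stop-codon set is {TAA, TAG, TGA}
(standard nuclear code). Reclassification flips a putatively stable gene to
degenerating only when every copy in its paralog group is truncated.

## Methylation

Per-cytosine records (Bismark coverage dialect; the percentage column is
ignored and recomputed from counts) are filtered to 10 ≤ coverage ≤ 50,
bounds inclusive. A site is methylated iff at least 50% of its reads are
methylated. Region summaries count covered and methylated sites in the gene
body, the exon union (a site overlapping two exons counts once), and
strand-aware 1 kb flanks clipped at contig edges; regions with no covered
sites are flagged undefined and excluded from models. Cytosines on the two
strands of a CpG are treated as separate sites (the input is assumed
CpG-context, pre-filtered). Group contrasts model the region proportion
with the Gaussian LMM above; the group coefficient is directly a difference
in proportion of methylated sites.

## Pairwise dN/dS

The Nei–Gojobori (1986) counting estimator with Jukes–Cantor correction is
implemented directly; it is a deliberate methodological choice of a
transparent counting estimator over likelihood machinery, and the
downstream contrasts depend on relative rather than absolute rates.
Conventions: single-nucleotide changes that would create a stop codon count
as nonsynonymous in site counting, so S + N = 3 × codons exactly; observed
multi-position codon differences are averaged over all shortest mutational
pathways with equal weight, excluding pathways through stop codons (if all
pathways are blocked, all are used, with stop steps counted
nonsynonymous); a terminal codon column is trimmed when either sequence
ends in a stop; p ≥ 3/4 is flagged saturated and the rate left undefined;
ω = dN/dS is undefined and flagged when dS = 0. Gap columns are stripped in
whole-codon units. The pipeline pairs each family's representative vertical
homolog (longest CDS, ties toward the smallest id) with the representative
donor ortholog and trims both to the common codon length when a planted 3'
truncation makes them unequal — the sequences are otherwise indel-free by
construction. The implementation is checked against an independent
exhaustive-pathway oracle to 1e-9.

Note one subtlety the tests encode: a synonymous-only mutation process
yields dN = 0 exactly only when codons are hit at most once; two synonymous
hits in the same codon can force the pathway average through nonsynonymous
intermediates.

## Transfer ages

Expression (mean log₂ TPM per gene by default; per-sample values are an
option) is regressed on age twice: a naive OLS and the mixed model with
family and accession-within-family intercepts. Both are reported side by
side because the naive model treats the same transfer observed in several
accessions as independent and over-rejects, which the test suite
demonstrates by simulation. Fate classes are compared on age with the
rank-sum test. Age bins are half-open ([0,2), [2,4), [4,6), ≥6 Ma), with
2.0 Ma falling in the second bin.

## The synthetic cohort

The generator plants every effect the pipeline is meant to detect, at
defaults chosen once as the emulated study conditions: 5 accessions × 40
gene families, 4 tissues × 3 replicates (12 recipient samples per
accession, 12 donor samples), 65% of families degenerating, truncation
probabilities 0.33 (LGT) vs 0.16 (vertical), a +0.027 gene-body
methylated-site probability delta on transferred genes (a further +0.03 for
degenerating ones), cytosine coverage uniform on 5–60 so the 10–50 filter
discards sites on both sides, 200-codon CDSs, and ages uniform on 0–8 Ma
shared within a family.

Expression is log-normal on the log₂ scale: per-family baseline
Normal(4, 1.5), accession jitter SD 0.3, per-family tissue offsets SD 1.0
shared by all three gene copies, replicate noise SD 0.5, TPM = 2^x − 1
truncated at zero. Degenerating LGT genes sit `degeneration_log2fc`
(default 2.0) log₂ units below the *nearer* of their two comparators, hence
below both. Stable genes follow one of five planted modes
(donor_like 0.35, recipient_like 0.10, higher 0.05, intermediate 0.05,
no_difference 0.45). The planted donor–vertical divergence is Normal with
SD 2.0 for stable and 1.0 for degenerating families, so the expected
absolute divergence (≈ 0.8 × SD) lands near the ratio the pipeline should
detect. Paralogs (probability 0.25 per recipient copy) split the group
total TPM by a fixed dominant-copy weight, so sum-aggregation recovers the
planted signal exactly. Donor samples are a separate species with unpaired
samples. Fate, mode, divergence and age are drawn per family so that the
same transfer is correlated across accessions — exactly the
nonindependence the mixed models must absorb.

CDS evolution: a random ancestor (ATG ... stop, no internal stops) accrues
Poisson point substitutions per branch that avoid creating stops;
truncation is planted by one of three mechanisms chosen uniformly — 3'
deletion to 60% length, start-codon mutation, or stop-codon loss. Five
full-length reference orthologs per family serve the truncation rules.
Methylation sites get Bernoulli methylation status at the region's planted
probability and read counts Binomial(coverage, 0.9) for methylated vs 0.05
for unmethylated sites, so the ≥50% call recovers status with small,
symmetric error.

What the generator does *not* emulate: read-level noise and mapping bias,
bisulfite conversion error, tissue-specific regulatory divergence between
species, indels (beyond whole-tail truncation), selection on sequences, or
correlation between age and fate (independent by default; an
`age_expression_slope` knob exists for power studies). Passing tests
therefore show that the decision procedure recovers effects of the planted
size under log-normal noise with family structure — not that it would
recover them under every real-data pathology.

Lightweight per-model generators (`simulate_difference_table`,
`simulate_interaction_table`, `simulate_truncation_table`,
`simulate_methylation_table`, `simulate_age_records`) produce just the long
table a single model consumes; calibration and power loops use them at
30–100 seeds with the effect sizes above, sized so the whole suite runs in
a few minutes on one CPU.

## Determinism and outputs

All randomness flows from a single integer seed through
`numpy.random.default_rng`; iteration orders are fixed; output tables have
deterministic column and row order; the run log excludes paths and
timestamps. Two runs with the same seed and configuration are byte
identical. Exit codes: 0 success, 2 validation error, 3 I/O error.

## Known limitations

- The binary GLMMs are variational approximations; their posterior-SD-based
  p-values are approximate (they are validated by calibration and power
  simulations, not by exactness).
- Wald z p-values for LMM fixed effects have no small-sample df correction;
  with few families they are mildly anticonservative.
- The NG86 estimator ignores transition/transversion bias and codon
  frequency bias; rates are comparable within a run, not with
  likelihood-based estimates.
- The five-way category truth is only recoverable when the planted mode is
  separated from the noise floor; `intermediate` with a small
  donor–vertical gap is intrinsically ambiguous.
- CLI subcommands other than `simulate` run the full pipeline and echo the
  relevant section; stages are not independently resumable.
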