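# lgtfate

Deciding the evolutionary fate of laterally acquired genes in a plant
pangenome.

When a gene moves between species by lateral gene transfer (LGT) it usually
lands in a genome that already carries a vertically inherited homolog. Most
such transfers are expected to decay — silenced, truncated, methylated and
eventually lost — while a minority integrate and persist. `lgtfate`
implements the comparative decision procedure that separates the two fates
from post-quantification data products: a gene × sample TPM expression
table, a catalog linking each transferred gene to its vertical homolog(s)
and donor ortholog(s), gene trees, CDS sequences, gene models, per-cytosine
bisulfite coverage, and molecular transfer ages. It is aimed at comparative
genomicists working on grass (or other plant) pangenomes with recurrent
grass-to-grass transfers.

## The decision procedure

For each transferred gene *g* with vertical homolog *v* (same accession,
paired RNA-seq samples) and donor ortholog *d* (donor species samples,
unpaired), on log₂(TPM + 1) expression with recent paralogs summed
(paralogs = maximal recipient-only clades in the gene tree):

1. **Fate call.** Paired Wilcoxon signed-rank test of *g* vs *v* and
   Wilcoxon rank-sum test of *g* vs *d*; both p-value families are
   Benjamini–Hochberg adjusted across genes. *g* is **degenerating** iff
   both adjusted p < α (default 0.05) *and* its median log-expression lies
   below both comparators; otherwise **putatively stable**.
2. **Truncation override.** A CDS is truncated if it is <70% of the length
   of every reference ortholog, lacks an ATG start, or lacks a terminal
   stop (feature present in all references). A putatively stable gene whose
   paralog copies are *all* truncated is reclassified as degenerating.
3. **Expression category.** Putatively stable genes are placed into
   {no_difference, higher, intermediate, recipient_like, donor_like} by a
   BH-adjusted Kruskal–Wallis test followed by Dunn's post hoc pairwise
   z-tests; exact binomial tests ask whether no-difference genes form a
   majority and whether donor-like genes are over-represented among the
   rest.
4. **Supporting contrasts.** Linear mixed models with random intercepts for
   gene family and accession-within-family quantify the overall expression
   deficit (`logTPM_difference ~ 1 + (1|family/accession)`), the gene-type
   effect (`logTPM ~ type + (1|family/accession)`), and the fate × type
   interaction on vertical-donor expression divergence; mixed logistic
   models contrast truncation rates by gene type and fate; gene-region CpG
   methylation (coverage-filtered 10–50×, site methylated iff ≥50% of
   reads) is contrasted between gene classes; pairwise dN/dS between
   vertical homolog and donor ortholog uses Nei–Gojobori (1986) counting
   with Jukes–Cantor correction; transfer-age associations are reported
   from a naive linear model and the mixed model side by side.

A seeded synthetic-cohort generator (`lgtfate.synth`) emulates the full
data structure with planted ground truth — fates, categories, truncations,
methylation deltas, ages — so the whole pipeline is testable end to end
without any sequencing data.

## Worked example

```bash
lgtfate simulate --seed 1 --out bundle/
lgtfate report --input bundle/ --out report/
```

The report run prints the per-accession summary (abridged):

```
accession  n_lgt_genes  pct_expressed  pct_degenerating_pre_reclass  pct_degenerating
     ACC1           40           95.0                          67.5              80.0
     ACC2           40           95.0                          67.5              77.5
     ACC3           40           95.0                          65.0              72.5
     ACC4           40           95.0                          67.5              80.0
     ACC5           40           92.5                          67.5              75.0
```

Reading: each of the five synthetic accessions carries 40 transferred
genes, 92–95% of which reach the 0.5 TPM detection threshold in at least
one sample. The expression tests call 65–67.5% degenerating (the generator
planted 65% at the family level), and folding in fully truncated stable
genes raises the final degenerating share to 72.5–80%. `report/` also
contains per-gene fate and category tables, truncation calls, methylation
summaries, dN/dS records, the fitted model coefficients (`models.tsv`) and
the enrichment/divergence/age statistics (`statistics.json`).

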