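# Methods

This note records the models, conventions and numerical choices behind
`halotribes`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic validation does and
does not establish.

## Ortholog tribes

Within-genus tribe construction treats orthology as reciprocal best
hitting. For every gene and every *other* genome of the genus, the best
hit is the highest bit score; ties are resolved by lower E-value, then
lexicographically smaller subject id, so the graph is deterministic.
Tribes are the connected components of the resulting undirected RBH
graph; genes with no partner become singleton tribes, and same-genome
hits and self hits are discarded before any computation (self hits
carry no orthology signal and would inflate averaged scores).
Connected-component transitivity means one spurious RBH edge can fuse
two tribes; this is the standard fragility of single-linkage orthology
graphs and is why the exactness guarantees below are stated for the
noiseless regime.

Cross-genus joining scores a tribe pair by the arithmetic mean of the
bit scores of *all* cross hits between their members, pooling both
search directions. Pairs with no hits have no score and are never join
candidates (no imputation: the mean of an empty set is undefined). A
join requires mutual best partnership; score ties are broken by higher
mean hit coverage, then lexicographically smaller partner id. Joined
tribes take the scope label `joined`; consensus function labels are the
modal member product, ties to the lexicographically smallest.

## Presence/absence matrix

Profile-hit filtering is strict on both boundaries — E-value strictly
below 1e-4, both coverages strictly above 0.80 — because the procedure
is defined with "below"/"greater than" wording and equality is taken at
face value. Multi-profile genes keep only their best-E-value hit (ties:
higher profile coverage, then gene coverage, then profile id), making
assignment independent of row order. Tribes with no surviving
assignment keep all-zero rows so matrix dimensions are reproducible
across runs and genome sets.

Clustering is complete-linkage agglomeration under Manhattan distance.
The agglomeration is implemented in-package rather than delegated so
that tie handling is pinned: at each step the minimum-distance pair is
merged, ties resolved toward the smallest (i, j) pair of cluster
indices, and the smaller-index child is placed on the left of each
merge. This makes leaf orders — and therefore the exported
CDT/GTR/ATR files — bit-reproducible. On tie-free (continuous) data the
merges provably coincide with scipy's complete linkage, which the test
suite uses as an independent cross-check; complete linkage is monotone,
and the `Dendrogram` type asserts non-decreasing merge heights on every
construction. The written CDT uses GID/NAME/GWEIGHT columns, AID and
EWEIGHT rows, unit weights, and integer formatting for binary matrices
(Java TreeView-compatible); GTR/ATR node heights are raw Manhattan merge
heights.

## Enrichment test

Per-genome category fractions use the full CDS count as denominator —
genes without any COG assignment stay in the denominator — and a gene
carrying several category letters contributes to each of them, so
fractions need not sum to one.

The genus comparison is a two-sided Wilcoxon rank-sum test. For pooled
sizes m + n ≤ 12 the p-value is exact: mid-ranks are assigned to the
pooled data, and all C(m+n, m) assignments of those (possibly tied)
ranks to the first group are enumerated; p is the fraction of
assignments whose rank sum deviates from its mean m(m+n+1)/2 at least
as much as observed. Conditioning on the observed tie pattern makes
degenerate inputs behave sensibly (complete ties give p = 1). Above 12
observations a normal approximation with continuity correction and the
standard tie-corrected variance is used; the package's own use cases
(4–5 genomes per genus) always take the exact path. Two-sidedness is a
deliberate choice — no direction is privileged a priori. Raw
per-category p-values are reported without multiple-testing correction,
mirroring how such category tables are conventionally reported; users
screening many categories should interpret the family-wise error
accordingly.

## Screens

* Annotation screens are case-insensitive substring matches over product
  strings — deliberately simple text matching over annotation output,
  not ontology reasoning — returning dense per-genome count tables.
* Clade-differential detection is strict: a tribe qualifies only if
  present in *every* in-clade genome and absent from *every* out-clade
  genome. A majority rule would be less brittle to single-genome
  assembly gaps but is not what "present in one clade, absent in the
  other" states; the strict rule was kept.
* The multi-domain filter treats per-domain E-values as approximate
  probabilities of chance occurrence and multiplies them; a homolog with
  individually insignificant domain matches is retained when the product
  falls below the same 0.001 threshold used per domain. This is a
  statistical approximation (E-values are expectations, not
  probabilities), applied as-is because it is the procedure being
  reproduced, and it is only used as a screen, not as a calibrated test.
* Repeat conservation is the per-column frequency of the modal symbol
  over an equal-length alignment (alphabet ACGTU-). At ties the
  fraction is the tied maximum; which symbol is displayed is resolved
  lexicographically and affects display only.

## Genome statistics

Contig counts use a strict > 200 bp floor; assembled bp always sums
*all* contigs regardless of that display filter. The genus comparison
reports (1 − mean_bp(A)/mean_bp(B)) × 100, the absolute and relative
CDS difference against group B's mean, and the contig-count ratio
mean(B)/mean(A); percentages and ratios are rounded to one decimal and
gene counts to integers, matching reporting convention. The
resequencing-control rate is the mean of the control and reference
assembly lengths divided by the discrepancy count, reported to the
nearest Kbp — using the mean of the two lengths, since the discrepancies
are a property of the *pair* of assemblies. Region-length medians use
the conventional definition (mean of the middle pair for even counts).
The bundled `datasets` module carries the published per-assembly table
and worked-example constants these comparisons consume; the groupings
used for each comparison (e.g. fragment assemblies only for the contig
ratio, reference genomes included for the size comparison) are spelled
out there as named constants.

## Synthetic pangenome generator

The generator emulates a two-genus study — by default five genomes in
one genus and four in the other on a fixed topology: a two-leaf cherry
against a ladder within each genus, genera joined at the root (a
user Newick can override it). Core tribes are present at the root;
genus-specific tribes arrive deterministically on their genus stem.
Evolution is the simplest process matching the qualitative phenomenon
being modelled: independent per-tribe Bernoulli presence toggles on each
branch — loss with probability `loss_rate` (multiplied by
`clade_loss_boost` on every branch inside one designated clade, by
default the three-genome subclade of the first genus, emulating a
lineage with a burst of gene loss), gain with probability `gain_rate`.
The event log records every toggle, so leaf presence always equals root
presence XOR the parity of toggles on the root-to-leaf path — an
invariant the tests verify. No richer gain/loss model (e.g. a compound
Poisson process over genome segments) is attempted: the published data
offer no generative parameterisation, so all distributional choices
here are explicit stand-ins.

Defaults are chosen to mimic the study's scale and effects: 2,600 core
plus 900 + 900 genus tribes give ≈ 3,500 genes per genome (the real
assemblies carry 3,400–4,600); the default COG effect injects
signal-transduction (T) fractions of 3.0% vs 4.2%; loss/gain rates of
0.02/0.005 per branch with a 5× clade boost produce visible
clade-differential blocks. With ≈ 3,500 genes per genome, binomial
sampling alone gives a between-genome fraction standard deviation of
≈ 0.003, which is the regime in which the enrichment power analysis is
run.

Derived tables are pure functions of (truth, params), each drawn from
its own fixed-seed substream, so identical `SimParams` reproduce
byte-identical files. Within-tribe similarity bit scores are ≈ 2 bits
per aligned residue (tribe lengths 150–600 aa, so ≥ 300 bits) plus
Gaussian noise of `score_noise_sd`; cross-tribe decoy pairs draw from
30–70 bits, so with `score_noise_sd = 0` the two distributions cannot
overlap. E-values are a fixed monotone transform of the bit score
(only ordering and threshold behaviour matter downstream). Profile
hits give true members E < 1e-7 and coverages > 0.9, while decoy
gene-profile pairs straddle both filter thresholds (E in [1e-6, 1],
coverage in [0.5, 1.0]); a decoy can therefore survive filtering but can
never out-compete a true hit in best-E-value assignment, which is why
matrix recovery is exact even with profile decoys present.

"Noiseless" for the similarity path means `score_noise_sd = 0` *and*
`decoy_fraction = 0`: the decoys are exactly the cross-tribe noise
pairs, and with random noise edges present two tribes orphaned in
opposite genera could be spuriously joined through a decoy-only pair
score. COG letters are assigned per gene, independently per target
category with the genus-mean probability (so per-genome expected
fractions hit their targets exactly), plus one background letter with
probability 0.62 — roughly the fraction of genes with a COG match in
real haloarchaeal annotation. Product strings come from a small
controlled vocabulary with 0.85 fidelity (otherwise "hypothetical
protein"), giving annotation screens known truth counts.

What the synthetic validation does *not* show: real proteomes have
paralogs within genomes, domain shuffling, unequal gene lengths within
an ortholog set, and score distributions that overlap; the generator
emits one gene per tribe per genome with fully separated (or
parametrically noisy) scores. Passing the exact-recovery tests
therefore certifies the correctness of the pipeline's logic, not the
biological error rate of RBH orthology on real data.

## Problem sizes

The test suite and the acceptance script run the full pipeline at nine
genomes and 2,000 tribes (1,200 core + 400 + 400) — the scale at which
every stage, including clustering of the 2,000-row matrix and CDT
export, completes in well under five minutes on one CPU. Operating
characteristics of the enrichment stage use 200 seeded replicates at
the default (paper-like) generator scale; oracle-equivalence checks run
on small instances (≤ 12 items) where exhaustive enumeration is exact.
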