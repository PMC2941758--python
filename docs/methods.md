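# Methods

## The counting model

The screen treats each EST as one draw from the transcript pool of its
library, pooled per anatomical system and condition. For one entity
(a gene, or one splice-site pair) in one tissue, the observed tumor
count among its supporting ESTs is compared with the tissue's pooled
library sizes by an exact one-sided hypergeometric test in each
direction. The hypergeometric (rather than a normal approximation)
matters because entity counts are small — often tens — while library
totals are large. The two one-sided p-values for the same margins
satisfy `p_tumor + p_normal >= 1`, so at any alpha <= 0.5 at most one
direction can be significant; the significant direction assigns the
label, and a zero count in the other condition upgrades it to the
exclusive class (`TT`/`NN`). Exclusive classes additionally require
directional significance, so a 1/0 split is `E`, not `TT`.

Gene-level counts use all gene-mapped ESTs; intron support counts only
junction-spanning ESTs (both flanking alignment blocks present), since
an EST ending inside an exon says nothing about splicing. Introns of
genes exclusively expressed in one condition (`TT`/`NN`) are excluded:
for such genes any intron would inherit the gene's expression contrast
rather than reveal a splicing one.

### Thresholds (defaults)

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | per-test significance, both one-sided directions |
| `min_gene_ests` | 10 | minimum ESTs for a gene to be classifiable in a tissue |
| `min_tissue_ests` | 30,000 | minimum ESTs per condition for a tissue to enter the analysis |
| Bonferroni family | per tissue, per entity type | `m_tests` = entities actually tested in that tissue; `family="global"` pools tissues |
| `min_tissues` (concordance) | 5 | tissues with a directional label for an intron to enter the cross-tissue concordance summary |

Whether the Bonferroni family should span tissues, or genes and
introns jointly, is not determined by the screen's published
description; the per-tissue, per-entity-type family is the minimal
consistent reading and the knob is exposed. Uncorrected and corrected
labels are always emitted side by side; event detection anchors on the
corrected labels by default (`event_label_field`).

### The exact kernel

`hypergeom_upper_tail` computes the tail with big-integer arithmetic:
unnormalised pmf terms follow an integer recurrence, the shorter tail
is summed, the complement (when taken) is an exact integer
subtraction, and the final division of two Python integers rounds
correctly to the nearest double. The result is exact to the last bit
for any margins — stronger than the 12-significant-digit target that a
log-space implementation would give — at negligible cost for the
sample sizes this method sees (draws up to a few thousand). The GO
stage's one-sided Fisher test is the same function by construction.

## Event detection

Detection is purely combinatorial over labelled intron coordinates.
"Alternative" means exact sharing of the outer splice boundaries
between the skipping intron and the inclusion chain — not mere
overlap — which excludes alternative-donor/acceptor configurations
that do not define a clean cassette. Chains of two introns give a
single cassette exon, chains of three give two adjacent exons skipped
together; longer chains are not emitted by default (`max_chain`).
Mixed readings of one locus are all emitted without deduplication: a
planted double cassette therefore also yields the outer-pair
single-cassette reading (its "exon" spans both exons and the middle
intron). Equivalence with a brute-force enumeration of all <= 4-intron
subsets is asserted property-wise in the tests.

For mutually exclusive pairs the two 2-intron chains must share both
outer boundaries and have non-overlapping internal exons. Events are
reported in a canonical orientation: inclusion = tumor-side chain,
skipping = normal-side chain, condition "T". Detection is per (gene,
tissue); the inclusion chain and skipping intron must be significant
in the same tissue.

## The synthetic cohort generator

The generator emulates the screen's data substrate: multi-exon gene
models (6–8 exons of 90–200 bp, introns of 300–800 bp by default), EST
libraries per (tissue, condition), and ESTs sampled by picking a gene,
an isoform (Bernoulli with the planted PSI for the library's
condition; the differential exists only in the event's target tissue),
and a contiguous transcript window (normal, mean 600 bp, sd 150 bp,
floor 150 bp) mapped back to genomic blocks. Windows reproduce the
partial, uneven junction coverage of real ESTs: an EST supports an
intron only if its window crosses the junction.

EST counts are negative-binomial per (library, gene) —
`est_count_mean` 250, `est_count_dispersion` 20, i.e. ~23% CV, a
realistic between-library expression heterogeneity — drawn from keyed
RNG substreams (seed, stream, library, gene), so adding genes or
libraries never perturbs existing ones and equal seeds give
byte-identical cohorts. The reference study conditions (defaults) are
one tissue, 4 libraries per condition, PSI 0.9 vs 0.1, which puts
well over 300 junction-spanning ESTs per condition on every planted
junction.

What the generator does **not** emulate: sequencing error, chimeric
ESTs, library normalisation, multi-gene mappings, strand effects, and
the orders-of-magnitude size range of real EST libraries. Passing
recovery tests therefore show the statistical machinery works under
its stated sampling model, not that real EST corpora are this clean.

### Negative control and a known anticonservativeness

`shuffle_conditions` reassigns condition labels among each tissue's
libraries. The default is a *stratified* permutation — each
pseudo-condition receives an equal random draw from true-normal and
true-tumor libraries — because a naive permutation does not null a
strong planted signal: any unbalanced split leaves a large EST-count
differential that the test will detect. Stratification nulls the
expected differential exactly.

Even so, the pooled test retains a small false-positive rate under
shuffling (~0.14 events per cohort against 4 planted, measured over
100 seeds): per-(gene, library) depth over-dispersion is
condition-correlated with isoform content at planted loci, and no
relabelling of whole libraries can remove that variance component.
This is the price of pooling libraries and discarding replicate
structure — the same reason the per-intron type-I rate under an
over-dispersed null (~12% one-sided at alpha 0.05) exceeds the nominal
level, while under Poisson library depths (where the test's
conditioning model holds exactly) it is calibrated. Users applying the
screen to heterogeneous libraries should read uncorrected `T`/`N`
labels accordingly; Bonferroni labels are far quieter but not immune.

## qPCR arithmetic

The relative expression ratio is computed in log space,
`exp(Ct_wo·log(1+E_wo) − Ct_w·log(1+E_w))`, exact to ~1e-15 relative
for Ct <= 50; replicate Cts are averaged first. A non-finite Ct
(target never crossed threshold) censors the ratio in the
corresponding direction instead of producing a number. No
normalisation gene enters: both targets come from the same cDNA.

Efficiency estimation fits log10(fluorescence) against cycle over a
detected exponential window and returns `10^slope − 1`, clipped to
[0, 1] with a warning. Window detection: cycle-to-cycle log10 ratios
must exceed `min_growth` (0.02, excluding baseline and plateau); if
the curve plateaus (median of the last five ratios below
`min_growth`), only cycles between 0.002% and 2% of the plateau
fluorescence are considered (three decades clear of both the baseline
noise floor and the saturation shoulder); the window is the longest
contiguous stretch with ratio spread <= `tol` (0.10), with trailing
ratios more than `shoulder_tol` (0.04) below the window median trimmed
as residual saturation. The estimator is exact on noise-free geometric
series for any per-cycle ratio in (1, 2] and recovers E within ±0.02
on simulated 50-cycle curves with 2% multiplicative noise; curves with
no qualifying window raise an error rather than guess. User-supplied
efficiencies bypass estimation entirely, which is how the rER formula
is normally applied.

Group comparisons use Welch's unequal-variance one-tailed t-test
(group sizes in validation settings are small and unequal, e.g. a few
normal controls against eight tumors); a pooled-variance variant is
not provided. Zero variance in both groups with equal means returns
p = 0.5 by convention, logged.

## Reference tables

The package bundles the published aggregate tables of the screen it
models (per-tissue event counts, the 46-gene list, validated exon
coordinates, intron-concordance counts) as fixed inputs for report
aggregation and worked examples. Two internal inconsistencies of the
printed tables are preserved rather than silently repaired: the
normal-introns column sums to 110 while its printed total is 109 (the
TES row is consistent only with 9, not the printed 10), and the
concordance percentages imply a denominator slightly above the sum of
the three printed counts (62.25% rounds to 62.3, not the printed
62.2). The package reports percentages over the printed counts.

## Degenerate inputs and tie-breaks

Empty GFF3 files read as empty gene lists; a tissue with zero
background in either condition yields `UNCLASSIFIED` entities with the
reason recorded; an empty event set produces an all-zero summary with
a `Total` row; precision over an empty detection set is NaN;
`percent()` refuses a zero denominator. Intron support deduplicates
EST records by id, and all outputs are sorted on stable keys so reruns
are byte-identical.
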