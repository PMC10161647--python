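# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic-data generators do and do not emulate, and
the design choices made where the procedure was genuinely open.

## Region calling

Windows are a fixed, genome-anchored 50-bp tiling starting at coordinate
0; windows do not slide. Within a window, methylated and total read
counts of one context are pooled over all covered cytosines on both
strands (for the symmetric CG and CHG contexts the two strand records are
kept separate on disk and pooled here, which maximizes the counts
available to the exact test). The window is tested one-sided ("sample
more methylated than baseline") against the matched demethylated
baseline: CG against a *met1*-like sample, CHG and CHH against a
*ddcc*-like (*drm1 drm2 cmt2 cmt3*-like) sample. Testing against a
near-zero baseline makes the question directional by construction, which
is why the one-sided tail is the default; sidedness is exposed in
`gbmscan.stats.fisher_exact` for other uses.

Parameters (defaults in `ClassThresholds`):

| parameter | default | meaning |
|---|---|---|
| `p_cg` / `p_chg` / `p_chh` | 1e-14 / 1e-4 / 1e-8 | per-context window significance cutoffs |
| `merge_gap` | 500 bp | same-context windows with gap strictly below this merge |
| `tem_*_min` | CG 0.10, CHG 0.05, CHH 0.02 | level floors for TEM-like regions |
| `gbm_cg_min`, `gbm_*_max` | CG 0.10; CHG 0.05, CHH 0.02 | level floor / caps for GBM-like regions |
| `min_sites` | 2 | covered cytosines of the tested context required per window |

`min_sites` guards against single-site artifacts: a lone deeply covered
cytosine can reach an arbitrarily small Fisher p, but one site is not a
methylated region. The merge "distance" is the gap between one interval's
end and the next one's start, with strict inequality; touching or
overlapping intervals always merge. Region-level methylation is computed
from pooled counts (Σ meth / Σ total over the region), not from the mean
of window means, so long regions are weighted by coverage; a region with
zero covered reads in a context has undefined level, reported as 0 with a
zero-weight flag and never treated as evidence. Classification drops CG
regions that pass neither level rule; the TEM-like and GBM-like sets are
therefore disjoint by construction. No minimum number of significant
windows per merged region is imposed beyond the windows that created it.

## Differential methylation

Hypomethylation is assessed per context on pooled counts with three
jointly required criteria: loss Δ = level(mutant) − level(reference)
below a negative threshold, a one-sided Fisher exact p ≤ 0.001
(reference more methylated), and a residual cap on the mutant level. The
residual cap is what separates "strongly demethylated" from "lost some
methylation": a region going 0.6 → 0.2 has lost plenty but is not
considered strongly demethylated (residual 0.2 > 0.15). Modes: `gbm`
(CG only: Δ ≤ −0.1, residual ≤ 0.15), `tem` (all three contexts must
pass: CG as above, CHG Δ ≤ −0.05 residual ≤ 0.1, CHH Δ ≤ −0.02 residual
≤ 0.05), `drm2_chh` (CHH only). For `tem` we require every context's
p-value individually; the joint requirement is the stricter reading and
matches the all-context demethylation the mode is meant to capture.
Gene-level calls pool methylated/unmethylated counts across all of a
gene's regions first and then apply the same criteria, so one retained
region can (correctly) keep a gene out of the strongly demethylated set
even when another region is fully lost. A required context with zero
coverage in either sample yields a conservative WEAK call with a flag,
never a strong call.

## Gene features and categories

Feature zones are derived from each gene's strand-aware TSS: promoter =
1,000 bp upstream of the TSS point, TSS window = TSS ± 200 bp, body =
gene span minus the TSS window. The widths are conventional values for
the compact Arabidopsis genome, are configuration parameters
(`FeatureConfig`), and are echoed into output headers. Note the promoter
and TSS windows overlap on the 200 bp immediately upstream of the TSS; a
region confined there hits two features and excludes its gene as
ambiguous, which mirrors how aggressively the published-style exclusive
groups prune multi-feature genes. Categorization: one class in exactly
one feature gives pTEM/tssTEM/gbTEM (TEM-like) or pGBM/tssGBM/GBM
(GBM-like); same-class hits in several features give EXCLUDED_MULTI;
both classes on one gene give EXCLUDED_MIXED. A GBM-like region lying in
the body but touching the TSS window is reassigned to tssGBM rather than
dropped — "GBM" is reserved for body methylation clear of the TSS.
Regions are unstranded and contribute independently to every gene they
overlap.

## Differential expression

The statistic follows the two-component microarray recipe on
quantile-normalized log₂ intensities: Welch (unequal-variance) t and the
log₂ median difference, each referred to an empirical null built from
random permutations of all sample labels of the contrast
(`n_perm` = 1000 by default), with both statistics recomputed for every
gene in every permutation. Nulls are pooled across genes and
permutations: with 2–3 replicates per group a per-gene null would have
only 10–20 distinct values, while pooling gives a fine-grained grid; the
trade-off is exchangeability across genes, which the quantile-normalized
scale makes reasonable. Empirical p-values are two-sided on absolute
values and use the pseudocount rule p = (1 + k)/(1 + N), so p = 0 cannot
occur and Φ⁻¹(1 − p) is always finite. The two p-values are combined
with the equal-weight Liptak–Stouffer method.

A caveat the acceptance suite measures directly: the t and
median-difference statistics are computed on the same six numbers and
are strongly correlated (r ≈ 0.8 at n = 3 + 3), so the
independence-assuming combination is anti-conservative under a global
null — the fraction of null genes with combined p ≤ 0.05 comes out near
0.10–0.11 rather than 0.05 (the per-statistic empirical p-values, by
contrast, are uniform). This is a property of the published recipe
itself, not of this implementation. In practice the strict DEG
definition (combined p ≤ 0.01 AND t-test p ≤ 0.1 AND |MD| ≥ 0.58)
restores specificity: on the planted-truth benchmark the strict calls
reach ≥ 95% recall at an empirical FDR below 1%. Treat the loose set
(combined p ≤ 0.01 alone) as a sensitivity-oriented screen.

Priming categories are assigned from the mock and BAsubDC
mutant-vs-wildtype contrasts: strict DEGs under mock are BASAL_UP/DOWN by
the sign of MD, and basal status takes precedence; genes not DEG under
mock but strict DEGs under BAsubDC are DDM1_HYPER/DDM1_SUP. Subtle
activation/suppression groups use the wild-type BAsubDC-vs-mock
contrast with the loose p criterion and a mean-difference log₂
fold-change estimator (0 < FC ≤ 1 up, −1 ≤ FC < 0 down); the estimator
is a configuration knob (`fc_estimator`), with medians available.

## Population GBM stability

States are called per gene × accession from mean gene-body levels: UM
requires mCG ≤ 0.05, GBM requires mCG ≥ 0.1, both require mCHG ≤ 0.05
and mCHH ≤ 0.02; intermediate CG (0.05–0.1), elevated nonCG, or missing
values give UNCLASSIFIED. Class thresholds are absolute accession
counts, matching the fixed 700/100 cutoffs on a 927-accession panel:
GBM^NV needs strictly more than 700 GBM accessions, UM^NV strictly more
than 700 UM accessions, IM^NV needs 100–700 GBM accessions inclusive.
The stable classes are checked before IM^NV; a gene that qualifies as
both IM (by GBM count) and UM^NV (by UM count) is UM^NV. Missing data
simply reduce the attainable counts; no rescaling is applied.

## Enrichment, profiles, clustering

Overlap enrichment reports observed overlap, expected |A||B|/|U|, their
ratio, and a one-sided Fisher p for over-representation; the universe
defaults to the genes actually measured (e.g. the expression platform),
and is always explicit. Term enrichment is the hypergeometric upper tail
per term with Benjamini–Hochberg control across terms, filtered at
q ≤ 0.01 and fold ≥ 2; the annotation is user-supplied (no ontology
semantics are implied). Metaprofiles use fixed-width flanks (1 kb, 20
bins) and length-scaled body bins (40), oriented 5'→3' with minus-strand
genes flipped; bin levels are pooled counts across genes and samples
rather than per-gene means, so deeply covered cytosines carry their
evidence (a per-gene-averaged variant would weight short, sparse genes
equally). Chromatin-feature clustering centers and unit-scales each
feature, then cuts a Ward/Euclidean hierarchical tree at k = 2; labels
are renumbered by first appearance in sorted row-label order so the
assignment is independent of input row order, and an all-identical
matrix short-circuits to a single cluster.

## Synthetic data

The methylome generator is the minimal generative model consistent with
bisulfite count data: per cytosine, depth ~ Poisson(coverage) and
methylated reads ~ Binomial(depth, true level). Cytosines are placed
with context-typical mean spacing (CG 15 bp, CHG 20 bp, CHH 8 bp,
uniform jitter); CG and CHG sites are symmetric strand pairs, CHH sites
are single-stranded. The genome is organized into 10-kb slots, one gene
(3 kb) per slot, with at most one planted element per slot so planted
regions never merge across elements: GBM regions sit inside gene bodies
clear of the TSS window, TEM-like regions sit intergenic by default or,
on request, strictly inside the promoter-only, TSS-only, or body-only
zone, which makes the planted gene category unambiguous. True levels:
TEM (0.80, 0.40, 0.10), GBM (0.60, 0.01, 0.005), background
(0.02, 0.005, 0.005). Genotype operators: met1-like sets CG to 0.01
genome-wide; ddcc-like sets CHG/CHH to 0.005; ddm1-like drops all
contexts at TEM regions and CG at the DDM1-dependent half of GBM regions
to a residual of 0.05 (CG). A bisulfite conversion-failure term is off
by default and available as `conversion_failure` (0.005 mimics > 99%
conversion). Not emulated: read-level data, sequence content, TE
families, chromosomal methylation gradients, or correlated noise between
neighboring cytosines — so recovery rates here speak to the statistical
machinery at the stated coverage and effect sizes, not to performance on
real genomes with borderline regions.

The expression generator emits log₂ values = baseline (8.0) + planted
effects + N(0, sd) noise, with hyper/sup genes carrying a ±1 log₂
genotype × condition interaction confined to BAsubDC, and optional basal
main-effect genes; defaults are 2,200 genes, 100 hyper + 100 sup, sd
0.2, 3 replicates per cell. It does not emulate probe effects,
intensity-dependent variance, or array batch structure; quantile
normalization is therefore exercised as an operation, not stressed.

The population generator draws stable-GBM gene levels from a Beta
centered at 0.30, stable-UM at 0.01, and "other" genes at 0.075
(deliberately between the UM and GBM cutoffs); interchangeable genes
flip state per accession with a gene-specific rate θ ~ U(0.15, 0.7).
NonCG levels are Beta centered at 0.005. Note a consequence of the θ
range: genes with θ below ≈ 0.25 are UM in more than 700 of 927
accessions, and the stable-class precedence correctly labels them UM^NV
even though they were planted as interchangeable — this bounds the
achievable class-recovery accuracy at roughly 97% and is a property of
the planted model, not an error. Desk-scale sizes (2,000 genes rather
than a full annotation) keep the panel in memory; thresholds are counts,
so the class logic is size-independent.

## Numerical and reproducibility choices

Degenerate 2×2 tables (any zero margin) carry no evidence and return
p = 1. The vectorized window test uses the hypergeometric survival
function directly and is held to exact agreement with the scalar Fisher
path (and with brute-force enumeration) in the test suite. Quantile
normalization resolves within-column ties by averaging the rank-mean
values the tied block spans, which makes the operation idempotent.
Every stochastic component takes an explicit seed through
`numpy.random.default_rng`; the full pipeline derives per-stage seeds
from one master seed and embeds the package version, a configuration
hash, and the seed in every output header, so a rerun with the same
configuration is bit-identical.

## Known limitations

- The combined DEG p-value is anti-conservative under the null (see
  above); use the strict definition or interpret the loose set as a
  screen.
- Fisher windows against a demethylated baseline conflate "methylated in
  the sample" with "more methylated than the baseline"; with the
  prescribed near-zero baselines this is the intent, but the caller is
  not a general two-sample DMR tool.
- Gene categorization ignores isoforms and intron/exon structure; the
  promoter/TSS widths are conventions, not inferred quantities.
- Population classes assume accessions are independent; relatedness or
  population structure is not modeled, in the generator or the
  classifier.
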