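# Methods

This note documents the statistical procedures implemented in `gliatrap`,
the choices made where the design was genuinely open, and what the
synthetic-data suite does and does not establish.

## Count model and differential expression

Counts are modelled as negative binomial with mean μ and variance
μ + αμ² (gene-wise dispersion α).  The DE test between two genotypes is a
deliberately simple NB Wald test:

* **Size factors**: median-of-ratios — per-gene geometric-mean reference
  over the contrast's samples (genes with all-positive counts), sample
  factor = median count/reference ratio.  Factors are computed from the
  contrast's samples only, because contrasts in this kind of study are run
  pairwise per comparison.  A degenerate matrix with no all-positive gene
  falls back to depth-proportional factors.
* **Dispersion**: method of moments pooled across the two groups,
  `α = Σ(nᵍ−1)(vᵍ−mᵍ) / Σ(nᵍ−1)mᵍ²` on normalised counts, floored at
  1e-8.  No shrinkage: the goal is calibrated set-level behaviour, not
  per-gene agreement with shrinkage-based estimators, and per-gene numbers
  will differ from such tools.
* **Effect and test**: log₂FC of normalised group means (means floored at
  0.5 to guard empty groups), delta-method standard error
  `SE² = [(1/m₁+α)/n₁ + (1/m₂+α)/n₂] / ln²2`, and the Wald statistic
  referred to a **Student t with n₁+n₂−2 degrees of freedom**.  A plain
  normal reference is markedly anticonservative at this design's n = 4 per
  group (raw-p rate ≈ 0.10 at the 0.05 level under the null simulator)
  because the dispersion is estimated from so few replicates; the t
  reference restores calibration (≈ 0.053, verified in the test suite).
  Genes with zero counts across the contrast are flagged `low_count` and
  excluded from the BH adjustment.
* **Selection**: fold threshold on the point estimate (`2^log2fc`), BH
  p_adj threshold, and an expression floor interpreted as *maximum
  genotype-group mean FPKM ≥ threshold* — the permissive reading that
  keeps genes expressed in either condition.  Provenance records all
  thresholds.

FPKM is `count · 10⁹ / (length_bp · library size)` with library size the
raw column sum.

## Reactive-set classification

Input is a probe-level table of fold changes under two acute stimuli.
Probes without a gene symbol are dropped.  Multi-probe genes are collapsed
by the arithmetic mean fold change per stimulus; the averaging rule is
stated for genes featuring in the provisional top 250 of either stimulus,
and is applied uniformly to all multi-probe genes — this leaves the
ranking of the top genes unchanged while giving every gene a single value,
and it removes an order-of-operations ambiguity (average before or after
restricting to the top set).  Genes are then ranked per stimulus by
descending fold change, ties broken lexicographically by symbol so the
order is total.

Classification rules (defaults: top_specific = 100, top_pan = 250,
separation = 50, all comparisons inclusive):

* specific to stimulus X: rank_X ≤ 100 and rank_other − rank_X ≥ 50;
* pan-reactive: both ranks ≤ 250 and |rank difference| ≤ 50, **and** not
  already specific.  At the exact boundary (difference = 50 with one rank
  ≤ 100) a gene satisfies both rules; specific sets take precedence,
  which keeps the three sets disjoint and matches the published handling
  of a gene 55 ranks apart being classed specific.

A structural consequence worth knowing: with inclusive boundaries, *every*
gene ranked ≤ top_specific in either stimulus is necessarily assigned to
some set.  The synthetic stimulus-table generator therefore verifies each
emitted table by running the classifier and comparing with the planted
labels, and refuses compositions that cannot tile the top ranks (e.g. few
planted responders plus many null genes).

Interrogating a dataset with these sets uses a strict expression filter:
FPKM > threshold in **every** condition group.  Marker scoring reports
(k, m): m markers above the expression floor, k of them significantly
upregulated; the fraction is undefined (an error) when m = 0.

## Enrichment statistics

2×2 overlap tables use the two-sided Fisher exact test
(minimum-likelihood rule, as in standard implementations) and report fold
enrichment as the sample odds ratio (ad)/(bc) with a 95% Woolf interval
`exp(ln OR ± 1.96·√Σ1/cell)`.  Zero cells: Haldane–Anscombe +0.5 on all
cells for the OR and CI only; the exact p is never corrected.  The ratio
of observed to expected overlap is exposed alongside
(`fold_vs_expected`) since "fold enrichment" is sometimes read that way;
the odds ratio is the default because the intervals quoted with it are
odds-ratio CIs.  Two enrichments are compared by
`z = (ln OR₁ − ln OR₂)/√(SE₁²+SE₂²)` with a two-sided normal p.

The GWAS risk sweep takes the universe to be genes above the expression
floor that have a gene-level association p value, and tests the induced
set against risk sets defined at sequentially relaxed cutoffs; the "auto"
grid is `[0.05/|universe|, 5e-5, 5e-4, 5e-3, 5e-2]`, the first being the
Bonferroni rule.  Over-representation against GMT annotations is
one-sided hypergeometric (over-representation only, unlike the two-sided
2×2 test), with glob-based term exclusion, a minimum-overlap rule
(default ≥ 5), BH across tested terms, and a `reported` flag marking the
top-10-or-significant display subset without discarding the rest.

## Signatures, precocity, concordance, rescue

Core signatures are intersections of per-model significant sets
(p_adj < 0.05, same direction) with Fisher overlap significance on the
jointly tested universe.  Human-to-mouse transfer keeps only strict 1:1
ortholog pairs and genes above 10 FPKM in either model (single-nucleus
source data preferentially detects highly expressed genes); per-gene
significance categories are tallied at raw p < 0.05 (as such scatters are
usually drawn) and at p_adj < 0.05, both reported.

"Ratio paired t-test" is implemented once and used for precocity,
baseline and rescue: a one-sample t on per-gene log₂ ratios of
genotype-group mean FPKMs, with pseudocount 0.1 added to both means to
guard zeros.  df = n_genes − 1 (one-sample convention; published df
values of this form are occasionally n − 2 under other conventions, so df
is always reported alongside t).  The fixed pseudocount means exact
invariance to uniform FPKM rescaling holds only approximately for genes
near zero expression; tests assert invariance at a 2% tolerance.
Rescue attenuation is `1 − mean(log2FC intervention)/mean(log2FC
primary)`, defined only when the primary mean is nonzero; the paired test
operates on group-mean FPKMs (gene-paired), not per-animal values.
Regional concordance is Pearson r plus an OLS slope (B on A) with
normal-theory 95% CI on the shared expressed universe.

Allele scoring is exact forward-strand substring matching of two
equal-length motifs (e.g. the wild-type vs Swedish KM/NL APP codons);
reads containing neither or both motifs are reported as unscored, and the
percent mutant carries a Wilson 95% CI.  Horizontal-bar trials map time
(floored to whole seconds — the published bands are specified in whole
seconds) to a 0–10 score: falling at 0–5/6–10/11–20/21–40/41–59/60 s
scores 0/1/2/3/4/5; reaching the platform at 0–5/6–10/11–20/21–30/31–59/
60 s scores 10/9/8/7/6/5; a session score is the mean of its three
trials.

## Synthetic data: what it emulates and what it does not

Defaults mirror the study design being emulated: 4 replicates per
genotype; 5% induced and 5% repressed genes at |log₂FC| = 1; NB dispersion
α = 0.05; per-gene baseline expression log-uniform over 1.5 decades; gene
lengths log-uniform in 0.5–10 kb; library sizes log-normal (σ = 0.15)
around 10⁷ so FPKM spans a realistic range.  The rescue factorial plants
the full signature in TG vs WT, `(1 − rescue_factor)` of it in TG×NRF2 vs
NRF2, and nothing in NRF2 vs WT (an intact baseline).  The stimulus-table
defaults plant 70 + 70 specific and 42 shared responders among 1000
genes, the scale of the published derivation.  GWAS tables plant risk
genes (base rate 2%) whose odds are multiplied by a configurable bias
among induced genes, with risk p values below any Bonferroni cutoff.
Reads embed one motif in 40 nt of i.i.d. flanking sequence per side,
rejection-sampled so each read contains exactly one motif.

One global seed drives named per-generator sub-streams, so outputs are
bit-identical under a fixed seed and adding a generator never perturbs
another's draws.

Not emulated: batch effects, GC/length biases beyond the explicit length
term, correlated genes, multi-region correlation structure, probe-level
microarray noise beyond mean-preserving jitter, sequencing qualities, and
per-animal biological variability beyond the NB dispersion.  Passing
calibration on these simulations therefore shows internal correctness and
statistical calibration under the assumed model — not robustness to the
real data's unmodelled structure.

## Problem sizes

Calibration checks use 2000-gene × 10-seed null simulations for the DE
type-I rate, 2000 simulated tables for CI coverage, 100 random planted
compositions for classifier recovery, and 10 seeds × 1000 genes for
rescue-attenuation recovery; these sizes give Monte-Carlo error well
inside the asserted tolerances while keeping the whole suite fast.

## Known limitations

* The DE test is per-gene and two-group only: no shrinkage, no multi-factor
  designs, no independent filtering.
* The classifier's behaviour at rank boundaries follows the inclusive
  reading of "at least 50 places lower" / "no more than 50 positions";
  other readings shift a handful of boundary genes.
* Over-representation treats annotation terms as flat sets (no ontology
  topology).
* The rescue statistics are group-mean-based; per-animal paired designs
  and mixed-effects longitudinal models are out of scope.
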