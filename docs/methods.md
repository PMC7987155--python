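# Methods

This note documents the models and procedures implemented in
`regulon_rewire`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate.

## Coordinates and promoter windows

All internal coordinates are 0-based half-open on the forward strand; GFF3
input/output converts at the boundary (1-based inclusive ↔ half-open is an
exact bijection, property-tested). The translational start of a
minus-strand gene is the end-most base of its annotated interval. Three
windows, all anchored on the translational start and all configurable, are
used in their respective contexts:

| context                    | window (upstream, downstream) |
|----------------------------|-------------------------------|
| conservation scanning      | (200, 100)                    |
| CcrM direct-target rule    | (200, 0)                      |
| ChIP peak overlap          | (100, 100)                    |

Windows are taken irrespective of other annotated features and truncated at
contig edges. Overlap tests use half-open interval intersection, so a peak
ending exactly where a window begins does not overlap.

Operons are predicted by a distance rule: consecutive same-strand genes on
one contig with intergenic gap ≤ 50 bp (default) share an operon, and the
5′-most member is the lead whose promoter represents the operon. This is a
deliberate, simple stand-in for a full operon predictor; an explicit operon
assignment in the annotation overrides it.

## Motif model

A PSSM is built from n aligned sites with per-base pseudocount α = 0.25
(Laplace smoothing proportional to the uniform background):
`freq[pos][b] = (count + α) / (n + 4α)`. A word scores
`Σ_pos log2(freq/background)` in bits; a zero frequency (possible only at
α = 0) yields the −∞ sentinel, which propagates through sums and never
becomes a threshold. The information content is
`IC = Σ_pos Σ_b freq · log2(freq/background_b)` with 0·log 0 := 0. The
background defaults to uniform and may be estimated from genome
mononucleotide frequencies; the synthetic genomes default to GC = 0.5 so
that the scanning background matches the motif model's default exactly.

Site collections from multiple species combine into a mixture motif with
weights proportional to collection size. The mixture score is the
log-sum-exp of component scores, `log2(Σ λ_m 2^{s_m})`, which keeps the
score a log likelihood ratio of the site mixture versus background; the
mixture IC is the weight-averaged component IC. Both rules are explicit
design choices — no closed-form mixture IC exists, and the combination rule
is not otherwise determined — and both are configurable.

### Threshold calibration

The exact distribution of the score of a background word is computed either
by exhaustive enumeration of all 4^L words (L ≤ 12; the only exact route
for a mixture, whose score is not position-additive) or by per-position
convolution of binned score distributions (additive PSSMs, any length).
Scores are binned at δ = 0.01 bits; the two routes agree within one bin
(property-tested for L ≤ 8). The calibrated threshold is the smallest
support value t* with −log2 FPR(t*) ≥ IC, where FPR(t) = P(score ≥ t); ties
at the threshold count as passing, which makes the FPR well defined at
support points. If the motif's IC is 0 the minimum support is returned
(everything passes); if no support point reaches the IC the maximum support
is returned with a `saturated` flag rather than an error.

Because scanning uses unbinned scores while the achieved FPR is computed on
the binned distribution, observed spurious-hit counts sit a hair below
`2 · positions · FPR` (words whose true score falls within half a bin below
t* are counted by the binned FPR but rejected by the scan); the effect is
well inside the 3σ band asserted by the tests.

### Scanning conventions

Genome-wide enumeration of a fixed IUPAC motif reports forward and reverse
matches separately: a palindromic motif such as GANTC therefore counts
twice per interval, matching the genome-census convention of doubling
forward-strand counts. Within a single promoter's significant-hit list the
forward/reverse pair reading one palindromic interval is one biological
site and is collapsed to the higher-scoring strand, so ⟨|sites|⟩ in the
conservation statistic is not inflated. Windows containing N never match.

## Methylation calling

A strand is methylated iff its IPD ratio exceeds 1.0 **and** its QV passes
(default min QV 30); a failing QV conservatively counts the strand as
unmethylated, as does an IPD ratio of exactly 1.0 (the published rule
defines only < 1 and > 1). Both strands methylated → full; exactly one →
hemimethylated naming the strand; neither → unmethylated. Motif-level
summaries count occurrences with ≥ 1 methylated strand and report the
fraction truncated — not rounded — to the requested decimals, computed by
exact integer arithmetic (`n·10^p // total`); truncation is the convention
under which the published per-motif fractions (e.g. 7765/7800 → 0.99,
150/455 → 0.329) reproduce. Per-site read-level consensus is assumed to
have happened upstream: one IPD ratio per site and strand.

## Regulon set logic

Differential filtering keeps genes with raw p-value < max_p (strict) and
|log2fc| ≥ log2(min_fold) (non-strict), optionally one direction. "P" is
the raw p-value column by design (an adjusted column can be supplied
instead); ">2-fold" is read as ≥ on the fold scale. Direct-target flags are
computed on the operon lead's annotation and inherited by members.
Cross-species cascades apply ordered predicates to the ortholog image of a
regulon; nesting (each stage ⊆ the previous) holds by construction and is
property-tested. Ortholog pairing is one-to-one (reciprocal best hits on a
similarity table; any tie for best disqualifies the pair), so paralog
ambiguity must be resolved upstream.

## Conservation scoring

For an ortholog group, `<WSmax> = <s_max> · (Sp_site/Sp_orth) · <|sites|>`.
⟨s_max⟩ and ⟨|sites|⟩ average over **site-bearing** species only; averaging
over all ortholog-bearing species would penalize absence twice, since the
pervasiveness ratio already carries that information. (Averaging over all
members is available as an alternative reading.) A group with no sites
scores 0. Ranking sorts by ⟨WSmax⟩ descending with ties broken by group id;
exported tables add min-max normalized ⟨WSmax⟩ and ortholog counts over the
retained groups (all-equal columns normalize to 0), and per-species
posterior columns in which an absent ortholog is an empty cell, distinct
from a posterior of 0.

The posterior probability of regulation treats every scanned position
(both strands) as an independent potential site with prior density q
(default 1/window length, one expected site per promoter): the promoter
likelihood ratio is `L = Π_j [(1−q) + q·2^{s_j}]` (−∞ scores contribute
1−q) and the posterior is `πL / (πL + 1 − π)` with prior π = 0.5. A
promoter with no score signal posts exactly π. This per-position
independent-mixture form is this package's own explicit model of the
stated assumptions (sites contribute independently; position within the
promoter is ignored); it is monotone in every position score and bounded
in [0, 1], both property-tested.

Rank agreement with ChIP enrichment uses Spearman ρ on midranks and a
two-sided permutation test with the add-one rule
`p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (1 + n_perm)`, permuting y with a PCG64
generator whose seed is recorded in the result. Per-group enrichment
aggregates member genes' promoter-window peak enrichment by max (mean
available).

## Synthetic data: what it emulates and what it does not

The generators produce every input format the pipeline reads, with ground
truth, under one seeded configuration; identical configurations give
byte-identical output. Defaults are the study conditions the analyses are
tested under:

- **Ortholog promoters**: 23 species × 200 groups, presence 0.95, promoter
  300 bp (−200..+100), first 20 groups regulated with conservation 0.9
  versus background 0.05, site count max(1, Poisson(1)) per planted
  promoter, sites sampled letter-wise from the extended-GANTC PWM (so
  sub-threshold sites arise naturally; a consensus-sampling mode plants
  only max-scoring words). The default planting PWM is the YGAKTCK
  consensus expanded to its 8 words with α = 0.25 (IC 7.89 bits).
- **Expression**: 2000 genes, lognormal baseline around mean 500, negative
  binomial with dispersion 0.05 (a realistic overdispersion for
  well-expressed bacterial RNA-seq genes, and the level at which the
  default filter attains its documented ≥ 70% recovery at ≤ 5% false
  discoveries with 3 replicates), 5% DE genes with |log2fc| ~ U(1, 3). The
  emitted p-value is a two-sided t-test on log2(count+1) — a documented
  stand-in for a count-model fit, chosen so no test depends on external
  differential-expression machinery.
- **ChIP/IPD**: peaks of width 200 centred on planted sites ± 20 bp jitter
  with lognormal enrichment; spurious peaks at 10⁻⁴/bp; IPD ratios
  LogNormal(ln 2.0, 0.15) for methylated and LogNormal(ln 0.85, 0.10) for
  unmethylated strands (well separated at the 1.0 threshold; the
  unmethylated law still crosses 1.0 about 5% of the time, so per-strand
  calls on the rare unmethylated strands carry that error), QV fixed at 40,
  and true site states drawn at the genome-wide frequencies
  7765 : 19 : 16 / 7800 (full : hemi : unmethylated).

What passing these tests shows: the scanning, calibration, set-logic and
conservation machinery recover known truth at realistic signal-to-noise.
What it does not show: robustness to phylogenetic correlation between
species (members are independent here), to non-uniform genome composition
(GC-rich Caulobacterales genomes shift the background and, with it,
thresholds), to operon-structure errors, or to the count-model differences
between the t-test stand-in and a real differential-expression fit.

## Numerical choices and degenerate inputs

Score binning δ = 0.01 bits; ties at thresholds pass; −∞ carries
probability mass in score distributions but is skipped as a threshold
candidate; posterior computed in log space with saturation beyond ±60 bits
of log-odds; min-max normalization of an all-equal column is 0 by
convention; RBH ties pair nobody; constant vectors make Spearman ρ an
error rather than a NaN. Empty site collections, ragged sites, non-ACGT
words, nonpositive IPD ratios, and p-values outside [0, 1] are rejected
with informative errors.

## Problem sizes in the test suite

The stochastic suites run at the sizes stated above (200 ortholog groups ×
23 species for ranking recovery; 200 site-free promoters for the
spurious-hit budget; 500 replicates × 199 permutations at n = 30 for
type-I calibration; 3000 sites for methylation recovery), which keeps the
whole suite within a few seconds while leaving the binomial/permutation
error bars the assertions rely on comfortably tight.
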