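# regulon-rewire

Comparative analysis of DNA-methylation-based bacterial regulons.

In many Alphaproteobacteria the cell cycle is steered by an epigenetic pair:
the orphan methyltransferase CcrM, which methylates the adenine of the
palindromic motif **GANTC** on both strands, and the activator GcrA, which
is thought to stimulate transcription at promoters carrying methylated
extended GANTC sites (consensus **YGAKTCK**). Whether orthologous copies of
these regulators control the same genes in related species — or whether
binding sites have been gained and lost so that the regulon has been
*transcriptionally rewired* — is a quantitative question about methylation
states, promoter motif content, expression changes, ChIP binding evidence,
and cross-species conservation. This package implements that analysis
end-to-end for anyone comparing methylation-driven regulons across bacterial
genomes: methylome accounting from SMRT kinetics, calibrated PSSM promoter
scanning, regulon set logic, and ortholog-group conservation scoring, plus a
fully seeded synthetic-data generator so every stage is testable without any
external download.

## What it computes

**Methylation calls** (`methylation_calls`). A strand of a motif occurrence
is methylated iff its SMRT interpulse-duration ratio exceeds 1 and its
quality value passes (QV ≥ 30); occurrences are classified fully
methylated / hemimethylated / unmethylated and summarized per motif with
the fraction methylated *truncated* to the reported precision.

**Calibrated motif scanning** (`motif_model`, `genome_scan`). Binding sites
build a PSSM (pseudocount α = 0.25); words score the summed per-position
log₂ likelihood ratio versus background. Site collections from several
species combine into a mixture motif scored by log-sum-exp. The significance
threshold *t\** is calibrated on the exact background score distribution
(exhaustive enumeration for L ≤ 12, per-position convolution otherwise) as
the smallest score satisfying

    -log2 FPR(t*) >= IC,

i.e. a hit must be at least as surprising under background as the motif is
informative. Promoters are the −200..+100 window around the translational
start of each operon-lead gene (operons by a ≤ 50 bp same-strand gap rule).

**Regulon definition and comparison** (`regulon_sets`). Misregulated genes
pass P < 0.01 (strict) and ≥ k-fold change (non-strict; default k = 2, with
the alternative 1.75-fold lower-expression rule supported); direct-target
flags record a GANTC site in the CcrM window (−200..0), a ChIP peak in the
regulator window (−100..+100), and whether the peak itself contains a site.
Cross-species comparisons are nested cascades
(regulon → orthologs → peak+site → P cutoff → fold cutoff), and RT-qPCR
checks use the 2^−ΔΔCt rule.

**Conservation scoring** (`conservation_scoring`). Orthologs are paired by
reciprocal best similarity. Each ortholog group gets

    <WSmax> = <s_max> * (Sp_site / Sp_orth) * <|sites|>

— mean best site score across site-bearing species, times the fraction of
ortholog-bearing species with a site, times the mean site count — plus a
per-species posterior probability of regulation under an independent-sites
model (prior π = 0.5, per-position site density q = 1/window). Agreement
with ChIP enrichment is tested by Spearman rank correlation with a seeded
permutation test.

## Worked example

```python
from regulon_rewire import (
    calibrate_threshold, scan_promoter_hits, group_statistics, wsmax_score,
    OrthologGroup, SimConfig, generate_ortholog_promoter_set,
)
from regulon_rewire.synthetic_data import default_planting_pssm

motif = default_planting_pssm()
thr = calibrate_threshold(motif)
print(f"motif length {motif.length}, IC = {motif.ic:.2f} bits")
print(f"calibrated threshold t* = {thr.t:.2f} bits (FPR = {thr.achieved_fpr:.2e})")

cfg = SimConfig(seed=42, n_groups=3, n_regulated=1, n_species=4,
                conservation_regulated=1.0, site_sampling="consensus")
promoters, truth = generate_ortholog_promoter_set(cfg)
members, hits = {}, {}
for (group, sp), prom in promoters.items():
    members.setdefault(group, {})[sp] = prom.gene_id
    hits.setdefault(group, {})[sp] = scan_promoter_hits(prom, motif, thr)
for group in sorted(members):
    s = group_statistics(OrthologGroup(group, members[group], hits[group]))
    star = " <- planted" if group in truth.regulated_groups else ""
    print(f"{group}: <s_max> = {s.mean_smax:.2f}, pervasiveness = {s.pervasiveness:.2f}, "
          f"<|sites|> = {s.mean_nsites:.2f}, <WSmax> = {wsmax_score(s):.2f}{star}")
```

prints

```
motif length 7, IC = 7.89 bits
calibrated threshold t* = 6.16 bits (FPR = 1.95e-03)
grp0000: <s_max> = 10.25, pervasiveness = 1.00, <|sites|> = 2.25, <WSmax> = 23.06 <- planted
grp0001: <s_max> = 10.25, pervasiveness = 1.00, <|sites|> = 1.25, <WSmax> = 12.81
grp0002: <s_max> = 6.16, pervasiveness = 0.75, <|sites|> = 1.00, <WSmax> = 4.62
```

The extended-GANTC model carries 7.89 bits, so the calibrated threshold
admits roughly one background hit per 500 scanned positions — short motifs
are everywhere, which is exactly why mere site presence is a weak signal.
The group with sites planted in every member still ranks first because
⟨WSmax⟩ rewards jointly high score, pervasiveness, and site count.

## Command line

A thin CLI (`regulon-rewire`) orchestrates the stages from one YAML config:
`simulate`, `calibrate`, `scan`, `methylome`, `regulon`, `compare`,
`conserve`, `correlate`. Each subcommand writes its tables plus a JSON run
log of the effective parameters and seed; `--seed`/`--out` override the
config.

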