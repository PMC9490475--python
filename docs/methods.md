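# Methods

This note documents the models and procedures implemented in
`haploloop`, the choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Coordinates and variant scope

All internal coordinates are 1-based and fully inclusive, matching the
convention in which the locus's hg19 coordinates are printed (E1
chr8:11,387,781–11,392,710; E2 chr8:11,393,832–11,397,791; E3
chr8:11,402,260–11,405,263; scan window chr8:11,331,000–11,474,000).
BED input is 0-based half-open and converted at the boundary. Only
biallelic SNVs are used anywhere: multiallelic and indel records are
skipped with a warning on VCF load. This generalizes the credible-set
treatment at the locus, where a single rare indel was dropped to work
with the 11 SNPs; how indels elsewhere should be handled is not
specified by the source analyses, so the SNV-only rule is this
package's convention.

The packaged region fixture carries the published E1/E2/E3 and scan
coordinates. The promoter (P) and REST-site windows are *synthetic
placements*: only their approximate extents and positions relative to
the promoter are known (a ~13 kb promoter block; a repressor-binding
site ~115 kb downstream), and the fixture says so in its header. The
packaged credible set spells the two published promoter haplotypes,
`CCCCTTAAACA` (risk) and `TGTACCGGGTG` (non-risk), over 11 synthetic
SNP ids: the member rs numbers live in supplementary material only, so
any real-data use must supply its own credible-set TSV.

## Allelic Hi-C

Reads covering phased heterozygous SNPs vote for a parent: all votes
for haplotype 1 → M, all for haplotype 2 → P, no informative site → UA.
Reads whose covered SNPs disagree are labeled CONFLICT — the source
grouping never lists them, and we exclude likely mapping or genotyping
errors conservatively. Pairs group as parent-1 ({M,M}, {M,UA}),
parent-2 ({P,P}, {P,UA}), UNASSIGNED ({UA,UA}) or DISCORDANT (any
CONFLICT, or {M,P}, which cannot be attributed to one homolog).
Grouping is symmetric in the two ends, and the tallies satisfy
parent1 + parent2 + unassigned + discordant + skipped = total on every
run. Binning uses the leftmost mapped position of each end and
window-relative bin indices (capture Hi-C is confined to the target
window, and window-relative indices keep fixtures small); a base at
position p falls in bin floor((p − window.start)/resolution). A read
end carrying a third (non-ref, non-alt) base at a het site is treated
as uninformative. Genome masking replaces every heterozygous and
homozygous-alternative position of the cell line with N, which removes
the reference-mapping advantage of the reference allele.

## Differential loop calling

The caller compares n parent-1 against n parent-2 replicate matrices
(design M,…,M,P,…,P) per 5 kb bin pair:

1. **Filter** — keep a bin pair iff its zero-count fraction across all
   samples is ≤ `zero_p` (0.8) and its mean count is ≥ `a_min` (5).
   Self-pairs (i = j) are never tested; they are dominated by technical
   signal and the analysis concerns interactions between distinct loci.
2. **Normalize** — library sizes are equalized by median-ratio size
   factors computed on rows with all-positive counts (so a pure scalar
   library-size difference is removed exactly), then for 3 cycles over
   all unordered sample pairs a loess of M = log₂((a+0.5)/(b+0.5)) on
   log₁₀(distance + resolution) (span 0.2) is fitted and half the fit
   moved from one sample to the other in log space. Each pairwise step
   preserves the per-bin-pair geometric mean of (count + 0.5); the
   predictor offset of one resolution unit and the 0.5 pseudocount
   avoid log 0 at zero distance and zero counts. Cyclic loess is
   order-dependent, so exactly identical groups normalize to values
   that are numerically close, not bit-identical. The cycle count (3)
   is this package's choice; the published parameterization fixes only
   the span.
3. **Test** — the common NB dispersion φ is a pooled method-of-moments
   estimate, mean over bin pairs and replicated groups of
   max(0, (s² − m)/m²). When φ = 0 the test is the exact conditional
   binomial: given rounded group sums A and B, A ~ Binomial(A+B,
   n₁/(n₁+n₂)) under the null, two-sided by summing outcomes with point
   probability ≤ the observed (ties included — the standard,
   conservative exact-test convention). When φ > 0, a seeded parametric
   bootstrap draws `bootstrap_draws` resamples from the fitted null NB
   with common mean and compares |log₂FC|; p = (1 + #extreme)/(draws+1),
   so the attainable minimum is 1/(draws+1). logFC =
   log₂((mean₂+0.5)/(mean₁+0.5)); logCPM is the average log₂
   counts-per-million over samples.
4. **Threshold** — Benjamini–Hochberg over all tested pairs;
   significant ⇔ FDR ≤ 0.05 ∧ |logFC| ≥ 0.5 ∧ logCPM ≥ 0.5.

The statistical engine is implemented here directly (exact binomial +
bootstrap NB) rather than wrapping the replicate Hi-C comparison
package whose parameterization the thresholds mirror: the published
description fixes parameters, not internals, and the package's
acceptance surface is calibration on synthetic data with known truth,
not bit-agreement with another implementation.

## Allelic qPCR

Known mixes of DNA from the two homozygous genotypes give measured
log₂(VIC/FAM) values; the standard curve is the OLS line of those
measurements on the log₂ non-risk allelic odds log₂(f/(1−f)). The
predictor transform is a design choice — the source text does not state
it — made so that the noiseless curve is exactly linear and invertible,
consistent with the worked endpoint operating on odds. Replicate
measurements are averaged on the log₂-ratio scale before inversion
(aggregation over the three ChIP experiments is otherwise unstated).
The normalized enhancer-activity readout is the ratio of allelic odds
in ChIP over input DNA: fractions 57.5% (input) and 92% (ChIP) give
(92/8)/(57.5/42.5) = 8.5. The ratio is reciprocal
(ratio(a,b)·ratio(b,a) = 1) and strictly monotone in each fraction.

## Haplotype classification and risk dosage

Promoter haplotype strings over the credible-set SNPs are classified by
exact match: risk, non-risk, or idiosyncratic (anything else).
Idiosyncratic chromosomes are excluded from all downstream dosage
analyses. Conditioning on the promoter class defines enhancer local
haplotypes: the modal string among prom-R chromosomes is that
enhancer's R haplotype, the modal string among prom-N chromosomes its N
haplotype, everything else A. Modal ties are broken lexicographically
and logged loudly; identical R and N definitions are a hard error
(degenerate conditioning). Composite per-chromosome labels over
(P, E1, E2, E3) combine into canonical unordered multilocus genotypes
(lexicographically sorted, e.g. `NNNN/RNRN`), optionally projected to
promoter–enhancer pairs. Risk dosage is the total R count over both
chromosomes (0–8 for four regions). Group comparisons use the Welch
(unequal-variance) one-sided t-test with the declared direction that
the lower-dosage group has the higher mean; the source analyses state
only "one-sided Student's t-test", so Welch is the robust default and
the pooled test is available behind `equal_var=True`. The direction is
declared per contrast in configuration rather than inferred, because it
encodes a biological expectation, not a property of the statistic.
Percentages are reported rounded to the nearest integer with raw
fractions alongside. A re-labeling mode (`relabel_a_as_n`) supports the
robustness check of treating alternative (A) local haplotypes as N.

## Interaction scan and enrichment

For each unordered SNP pair, OLS fits of the linear and interaction
models give Gaussian profile log-likelihoods
ll = −n/2·(log(2π·RSS/n) + 1); the LRT statistic 2Δll is referred to
χ²₁. Rank-deficient interaction designs — routine under the locus's
strong LD, e.g. x₂ = 2 − x₁ — are flagged `degenerate` and excluded
from enrichment rather than assigned p = 1. Both model spaces are
closed under the allele recoding x → 2 − x, so the choice of counted
allele cannot change any statistic. No multiple-testing correction is
applied inside the scan: the enrichment question compares the raw
p-value *distributions* of GRE-GRE pairs (both SNPs in a regulatory
element) against non-GRE-GRE pairs, via a one-sided two-sample
Kolmogorov–Smirnov test with the alternative that GRE-GRE p-values are
stochastically smaller, plus a Q-Q table of sorted −log₁₀ p quantiles
at min(group sizes) probability points. Expression is used untransformed
by default; a declared transform can be applied upstream.

Under block LD, statistically tied proxies of a causal pair are
expected: the scan localizes an interaction to an LD block, not to a
unique SNP pair. The power check therefore asks whether the scan's top
hit is a near-perfect proxy (|r| ≥ 0.9 per SNP) of the planted pair.

## Synthetic-data generators

All generators are deterministic given their spec (explicit integer
seed required).

**Panel.** Defaults emulate the European reference panel at the locus:
503 diploids; 11 promoter + 24/13/8 enhancer SNPs; promoter haplotype
frequencies 72% N / 24% R with the ~4% remainder idiosyncratic (the N
string with one random substitution — idiosyncratic haplotypes are rare
variants of the majors). Each enhancer copies the promoter's N/R label
with probability `ld_coupling` and otherwise draws from its own
marginal frequencies. The observed data constrain only conditional
frequencies (E1/E2/E3-R on 87%/85%/54% of prom-R chromosomes; E-N on
25%/70%/50% of prom-N), which a single coupling scalar cannot all
reproduce; the defaults (coupling 0.55 with the marginals in
`PanelSpec`) approximate the risk-side conditionals, which drive the
dosage analyses. An 11-SNP promoter region is spelled with the real
credible-set alleles and ids so synthetic panels classify against the
packaged credible set. Region names X1/X2 place non-GRE filler SNPs in
the intergenic gaps of the scan window.

**Expression.** y = μ + Σ β_region·(R copies) + Σ γ·x₁x₂ + N(0, σ²),
with defaults μ = 10, β negative per region, σ = 1 and n = 344,
emulating an expression cohort in which each risk haplotype copy lowers
expression.

**Hi-C.** Expected count for bin pair (i,j) on haplotype h is
baseline·(|i−j|·res + res)^(−α)·2^lfc, with lfc nonzero only for loops
planted on h. The single power law with a one-bin additive offset is
the simplest decay giving the loess step a realistic mean–distance
trend without a singularity at distance zero. Counts are NB(mean, φ)
(Poisson at φ = 0). Pair expansion records the true haplotype of origin
even when an end reads UA (labeled with probability `informative_rate`
per end), enabling exact conservation checks.

**qPCR.** Known mixes at non-risk fractions 0.1–0.9 with
log₂(VIC/FAM) = slope·log₂odds + intercept + N(0, sd²), plus replicate
input/ChIP measurements at planted true fractions (defaults 57.5% and
92%).

What the generators do *not* emulate: read sequences, mappability,
restriction-fragment structure, trans contacts, population structure or
recombination within regions, and expression covariates. Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under the assumed models, not robustness to those
real-data complications.

## Calibration checks and problem sizes

The differential caller is checked on 20 seeded null simulations (4+4
replicates, NB dispersion 0.05, 20-bin window, no planted loops): the
mean fraction of significant calls stays ≤ 1%. Power uses six balanced
2-fold loops (three per haplotype, all at 4-bin separation where the
unplanted mean is 100 counts) and requires detection of ≥ 80% of
loop × seed combinations; 20,000 bootstrap draws are used there so the
attainable p-value floor (1/(draws+1)) sits well below the BH threshold
at 190 tested pairs. These problem sizes — a 100 kb window at 5 kb
resolution, 344-sample expression cohorts, 500-pair null batteries —
are the package's chosen desk-scale study conditions; genome-scale call
counts from hundreds of millions of read pairs are outside its scope.

## Known limitations

* The exact normalization cycle count and filter ordering of the
  replicate Hi-C comparison package are not published; this
  implementation's chain is calibrated but need not match it bin-pair
  for bin-pair.
* The bootstrap NB test's p-values are granular at 1/(draws+1); very
  small FDR thresholds need correspondingly many draws.
* Enhancer N/R definitions depend on modal strings and can be unstable
  in small conditioning classes; ties are logged.
* The interaction scan's Gaussian LRT assumes homoscedastic residuals
  and no covariates, as in the source analyses.
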