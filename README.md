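# haploloop

Haplotype-resolved analysis of a disease-associated regulatory locus —
the *FAM167A-BLK* region of human 8p23.1, where systemic lupus
erythematosus risk variants sit in the *BLK* promoter and distal
enhancer variants modulate their effect on expression through 3D
chromatin looping.

The package provides, as a tested reusable pipeline:

* **Allelic capture Hi-C** — labeling of read pairs by parental
  haplotype via phased heterozygous SNPs (M / P / UA per read; M-M,
  M-UA, UA-M pairs grouped as parent-1 and the P analogues as parent-2),
  per-replicate 5 kb contact matrices, and the SNP-masking step that
  removes reference mapping bias.
* **Differential loop calling** between the parent-1 and parent-2
  replicate groups: bin-pair filtering (zero-fraction ≤ 0.8, mean ≥ 5),
  cyclic loess normalization of distance-dependent log-ratio trends
  (span 0.2), an exact conditional binomial test of the group sums for
  Poisson counts (parametric-bootstrap negative binomial test when the
  moment estimate of the common dispersion is positive), and
  Benjamini–Hochberg FDR with |log₂FC| ≥ 0.5, logCPM ≥ 0.5, FDR ≤ 0.05
  significance thresholds.
* **Allele-specific ChIP-qPCR calibration** — an OLS standard curve of
  measured log₂(VIC/FAM) on the log₂ non-risk allelic odds, inverted to
  allelic fractions, and the normalized enhancer-activity ratio
  (N/R)_ChIP / (N/R)_Input; e.g. (92/8)/(57.5/42.5) = 8.5.
* **Haplotype risk dosage** — classification of promoter haplotypes
  against the 11-SNP credible set (risk `CCCCTTAAACA` / non-risk
  `TGTACCGGGTG`), promoter-conditioned definition of enhancer N/R/A
  local haplotypes at E1/E2/E3, multilocus genotypes such as
  `NNNN/RNRN`, and one-sided t-tests of the expectation that expression
  falls as the total count of risk haplotypes rises.
* **Genetic-interaction scan** — for every SNP pair in the 143 kb scan
  window, a likelihood-ratio test of y = b₀ + b₁x₁ + b₂x₂ against
  y = b₀ + b₁x₁ + b₂x₂ + b₁₂x₁x₂ (x coded 0/1/2, Gaussian likelihood,
  χ²₁ reference), partitioned into GRE-GRE vs non-GRE-GRE pairs with a
  one-sided two-sample Kolmogorov–Smirnov enrichment test and Q-Q data.
* **Synthetic data generators** for every input modality — a phased
  diploid panel with two dominant promoter haplotypes and LD-coupled
  enhancer haplotypes, an additive risk-dosage expression model with
  optional pairwise interactions, replicate allelic contact matrices
  with power-law distance decay and planted differential loops, and
  allelic qPCR standard curves — so the whole pipeline runs and is
  tested without any data download.

## Worked example

Simulate a European-scale phased panel (503 diploids; promoter
haplotype frequencies 72% N / 24% R), classify promoter haplotypes,
condition enhancer haplotypes, and compare expression between promoter
genotype groups:

```python
from haploloop import PanelSpec, ExpressionSpec, simulate_panel, simulate_expression
from haploloop.haplotype_dosage import (
    load_blk_cs11, load_blk_regions, promoter_classes,
    condition_enhancer_labels, composite_haplotypes,
    multilocus_genotypes, risk_dosage_analysis, haplotype_frequencies,
)

panel, truth = simulate_panel(PanelSpec(seed=1))
cs11 = load_blk_cs11()
print(haplotype_frequencies(panel, cs11))

expr = simulate_expression(truth, ExpressionSpec(
    seed=2, mu=10.0, beta={"P": -0.8, "E1": -0.3, "E2": -0.3, "E3": -0.4},
    sigma=1.0))

pclasses = promoter_classes(panel, cs11)
labels, _ = condition_enhancer_labels(
    panel, pclasses, load_blk_regions().by_role("enhancer"))
comp = composite_haplotypes(pclasses, labels, ["P", "E1", "E2", "E3"])
prom = {panel.samples[s]: g
        for s, g in multilocus_genotypes(comp, panel.n_samples,
                                         projection=(0,)).items()}
res = risk_dosage_analysis(prom, expr.set_index("sample")["expression"],
                           contrasts=[("N/N", "R/R")])
print(res.groups)
print(res.contrasts)
```

Output:

```
        class  count  fraction  percent
         Risk    233  0.231610       23
      NonRisk    734  0.729622       73
Idiosyncratic     39  0.038767        4

group   n     mean       sd   median
  N/N 269 9.623620 1.057555 9.526177
  N/R 175 8.251388 1.022966 8.211533
  R/R  23 6.949320 1.074646 7.249477

group_low group_high  n_low  n_high         t  p_one_sided
      N/N        R/R    269      23 11.469212 6.335223e-12
```

Of the 1,006 simulated chromosomes, 73% carry the non-risk and 23% the
risk promoter haplotype (close to the planted 72/24), and expression
drops by about 1.3 units per risk haplotype copy, with the one-sided
Welch test strongly favoring higher expression in the N/N group — the
risk-dosage pattern the dosage model plants.

The same stages are scriptable through the `haploloop` CLI
(`simulate-panel`, `simulate-expression`, `simulate-hic`,
`simulate-qpcr`, `mask-genome`, `assign`, `diff`, `haplotypes`,
`dosage`, `scan`, `qpcr`); every randomized subcommand requires an
explicit integer seed in its YAML config.

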