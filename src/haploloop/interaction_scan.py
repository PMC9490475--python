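"""Pairwise SNP x SNP genetic-interaction scan with regulatory enrichment.

For every unordered pair of SNPs in a scan window, expression y is fitted
with a linear model y = b0 + b1*x1 + b2*x2 and an interaction model
adding b12*x1*x2 (x coded 0/1/2 by alt-allele count).  The likelihood
ratio statistic 2 * (ll_int - ll_lin) with the Gaussian profile
log-likelihood ll = -n/2 * (log(2*pi*RSS/n) + 1) is referred to
chi-square with 1 df.  Pairs whose interaction design matrix is rank
deficient — routine under the strong local linkage disequilibrium of the
locus — are flagged degenerate and excluded from enrichment.

Pairs are partitioned by whether both SNPs fall in gene regulatory
elements (GRE-GRE) or not (non-GRE-GRE); enrichment of small interaction
p-values among GRE-GRE pairs is assessed with a one-sided two-sample
Kolmogorov-Smirnov test, with a Q-Q table of the two groups' sorted
-log10 p quantiles for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval, HaplotypePanel, log_kv

GRE_GRE = "GRE-GRE"
NON_GRE_GRE = "nonGRE-GRE"


@dataclass(frozen=True)
class InteractionTestResult:
    snp1: str
    snp2: str
    ll_linear: float
    ll_interaction: float
    lrt: float
    pvalue: float
    group: str
    status: str  # ok | degenerate


def _gaussian_profile_ll(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def _fit_ll(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Least-squares fit; returns (profile log-likelihood, design rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)
    return _gaussian_profile_ll(rss, len(y)), rank


def lrt_pair(
    y: Sequence[float],
    x1: Sequence[int],
    x2: Sequence[int],
    snp1: str = "snp1",
    snp2: str = "snp2",
    group: str = NON_GRE_GRE,
) -> InteractionTestResult:
    """Likelihood-ratio test of the interaction term for one SNP pair."""
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (len(y) == len(x1) == len(x2)):
        raise ValueError("y, x1, x2 must be aligned")
    if len(y) < 10:
        raise ValueError("need >= 10 samples")
    if not np.isfinite(y).all():
        raise ValueError("non-finite expression values")
    ones = np.ones_like(y)
    X_lin = np.column_stack([ones, x1, x2])
    X_int = np.column_stack([ones, x1, x2, x1 * x2])
    ll_int, rank = _fit_ll(y, X_int)
    if rank < 4:
        return InteractionTestResult(
            snp1, snp2, float("nan"), float("nan"), float("nan"),
            float("nan"), group, "degenerate",
        )
    ll_lin, _ = _fit_ll(y, X_lin)
    lrt = max(0.0, 2.0 * (ll_int - ll_lin))
    pvalue = float(stats.chi2.sf(lrt, df=1))
    return InteractionTestResult(
        snp1, snp2, ll_lin, ll_int, lrt, max(pvalue, 5e-324), group, "ok"
    )


def _in_any(regions: Sequence[GenomicInterval], chrom: str, pos: int) -> bool:
    return any(r.contains(chrom, pos) for r in regions)


def scan_region(
    expression: pd.DataFrame | pd.Series,
    panel: HaplotypePanel,
    window: GenomicInterval,
    gre_regions: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Test every unordered SNP pair in the window against expression.

    ``expression`` is a Series indexed by sample id or a DataFrame with
    columns sample/expression; samples are matched to the panel by id.
    A pair is GRE-GRE iff both SNPs fall in some regulatory interval.
    """
    if isinstance(expression, pd.DataFrame):
        expression = expression.set_index("sample")["expression"]
    sub = panel.subset(region=window)
    if sub.n_variants < 2:
        raise ValueError("fewer than 2 panel SNPs in the scan window")
    order = [panel.samples.index(s) for s in expression.index]
    y = expression.values.astype(float)
    codes = {
        v.id: sub.genotype_codes(v.id)[order] for v in sub.variants
    }
    in_gre = {
        v.id: _in_any(gre_regions, v.chrom, v.pos) for v in sub.variants
    }
    rows = []
    for v1, v2 in combinations(sub.variants, 2):
        group = GRE_GRE if in_gre[v1.id] and in_gre[v2.id] else NON_GRE_GRE
        res = lrt_pair(y, codes[v1.id], codes[v2.id], v1.id, v2.id, group)
        rows.append(res)
    df = pd.DataFrame(
        [
            (r.snp1, r.snp2, r.group, r.ll_linear, r.ll_interaction,
             r.lrt, r.pvalue, r.status)
            for r in rows
        ],
        columns=[
            "snp1", "snp2", "group", "ll_linear", "ll_interaction",
            "lrt", "pvalue", "status",
        ],
    )
    log_kv(
        "scan_done",
        n_pairs=len(df),
        n_degenerate=int((df["status"] == "degenerate").sum()),
        n_gre_gre=int((df["group"] == GRE_GRE).sum()),
    )
    return df


@dataclass
class EnrichmentResult:
    ks_statistic: float
    pvalue: float
    n_gre: int
    n_nongre: int
    qq: pd.DataFrame


def ks_enrichment(results: pd.DataFrame, min_group: int = 5) -> EnrichmentResult:
    """One-sided KS test that GRE-GRE interaction p-values are smaller.

    Degenerate pairs are excluded.  The alternative is that the GRE-GRE
    p-value distribution is stochastically smaller (its CDF lies above);
    the Q-Q table pairs the two groups' sorted -log10 p quantiles at
    min(group sizes) probability points.
    """
    ok = results[results["status"] == "ok"]
    p_gre = ok.loc[ok["group"] == GRE_GRE, "pvalue"].to_numpy()
    p_non = ok.loc[ok["group"] == NON_GRE_GRE, "pvalue"].to_numpy()
    if len(p_gre) < min_group or len(p_non) < min_group:
        raise ValueError(
            f"need >= {min_group} ok pairs per group "
            f"(got {len(p_gre)} GRE-GRE, {len(p_non)} non-GRE-GRE)"
        )
    # alternative='greater': CDF of the first sample exceeds the second's,
    # i.e. GRE-GRE p-values are stochastically smaller
    ks = stats.ks_2samp(p_gre, p_non, alternative="greater")
    m = min(len(p_gre), len(p_non))
    q = (np.arange(1, m + 1) - 0.5) / m
    qq = pd.DataFrame(
        {
            "quantile": q,
            "neglog10p_gre": np.quantile(-np.log10(p_gre), q),
            "neglog10p_nongre": np.quantile(-np.log10(p_non), q),
        }
    )
    log_kv(
        "ks_enrichment",
        ks=round(float(ks.statistic), 6),
        p=float(ks.pvalue),
        n_gre=len(p_gre),
        n_nongre=len(p_non),
    )
    return EnrichmentResult(
        float(ks.statistic), float(ks.pvalue), len(p_gre), len(p_non), qq
    )
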