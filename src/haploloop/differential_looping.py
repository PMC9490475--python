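"""Differential haplotype-specific interaction calling.

Given per-replicate parent-1 and parent-2 contact matrices, the caller
re-implements the standard replicate Hi-C comparison chain on count data
with design {M, ..., M, P, ..., P}:

1. filter weak bin pairs (zero fraction <= ``zero_p``, mean >= ``a_min``);
2. cyclic loess normalization of distance-dependent log-ratio trends
   between all sample pairs, after median-ratio library-size scaling;
3. a per-bin-pair count test between the two parental groups — an exact
   conditional binomial test of the group sums when the common negative
   binomial dispersion is zero, otherwise a seeded parametric bootstrap
   from the fitted null NB;
4. Benjamini-Hochberg FDR across tested pairs, with significance defined
   as fdr <= fdr_cutoff AND |logFC| >= logfc_cutoff AND logCPM >=
   logcpm_cutoff (defaults 0.05 / 0.5 / 0.5, matching standard usage of
   this analysis at FDR 5%).

Self-interacting bin pairs (i == j) are excluded from testing; they are
dominated by technical signal and the analysis concerns interactions
between distinct loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .allelic_hic import PARENT1, PARENT2, AllelicContactSet
from .core_io import log_kv


@dataclass
class FilterParams:
    """Bin-pair retention rule: zero fraction and minimum average count."""

    zero_p: float = 0.8
    a_min: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_p <= 1.0:
            raise ValueError("zero_p must be in [0, 1]")
        if self.a_min < 0:
            raise ValueError("a_min must be >= 0")


@dataclass
class CallParams:
    loess_span: float = 0.2
    logfc_cutoff: float = 0.5
    logcpm_cutoff: float = 0.5
    fdr_cutoff: float = 0.05
    n_loess_cycles: int = 3
    bootstrap_draws: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must be in (0, 1]")
        for name in ("logfc_cutoff", "logcpm_cutoff", "fdr_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def build_count_table(
    cs: AllelicContactSet,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Flatten a contact set into a bin-pair x sample count table.

    Columns are ordered parent-1 replicates then parent-2 replicates
    (the {M..M P..P} design).  Diagonal pairs (i == j) are dropped here.
    Returns (table indexed by (bin_i, bin_j), group label per column).
    """
    reps1 = cs.replicates(PARENT1)
    reps2 = cs.replicates(PARENT2)
    if not reps1 or not reps2:
        raise ValueError("need at least one replicate per parental group")
    columns = [(r, PARENT1) for r in reps1] + [(r, PARENT2) for r in reps2]
    keys = sorted(
        {
            ij
            for key in columns
            for ij in cs.matrices.get(key, {})
            if ij[0] != ij[1]
        }
    )
    data = np.zeros((len(keys), len(columns)), dtype=float)
    index = {ij: k for k, ij in enumerate(keys)}
    for c, key in enumerate(columns):
        for ij, count in cs.matrices.get(key, {}).items():
            if ij[0] != ij[1]:
                data[index[ij], c] = count
    table = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(keys, names=["bin_i", "bin_j"]),
        columns=[f"{r}:{g}" for r, g in columns],
    )
    groups = np.array([g for _, g in columns])
    return table, groups


def filter_bin_pairs(table: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Retain bin pairs passing both the zero-fraction and mean-count rules."""
    if table.shape[0] == 0:
        raise ValueError("empty contact table")
    zero_frac = (table.values == 0).mean(axis=1)
    mean_count = table.values.mean(axis=1)
    keep = (zero_frac <= params.zero_p) & (mean_count >= params.a_min)
    log_kv("bin_pairs_filtered", n_in=len(table), n_kept=int(keep.sum()))
    return table.loc[keep]


def _median_ratio_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Equalize library sizes by median-ratio (size factor) scaling.

    Factors come from rows with all-positive counts (no pseudocount), so a
    pure scalar library-size difference is removed exactly; rows with
    zeros fall back to a 0.5 pseudocount when nothing else is available.
    """
    counts = table.values
    positive = (counts > 0).all(axis=1)
    ref_counts = counts[positive] if positive.any() else counts + 0.5
    log_ref = np.log(ref_counts).mean(axis=1)
    factors = np.exp(np.median(np.log(ref_counts) - log_ref[:, None], axis=0))
    return table / factors


def cyclic_loess_normalize(
    table: pd.DataFrame,
    params: CallParams,
    resolution: int,
) -> pd.DataFrame:
    """Remove distance-dependent log-ratio trends between all sample pairs.

    For ``n_loess_cycles`` passes over all unordered sample pairs (a, b),
    a loess of M = log2((a+0.5)/(b+0.5)) on log10(distance + resolution)
    is fitted with the stated span and half of the fit is subtracted from
    a and added to b in log space, so each pairwise step preserves the
    per-bin-pair geometric mean of (count + 0.5).
    """
    if table.shape[1] < 2:
        raise ValueError("cyclic loess needs at least two samples")
    table = _median_ratio_scale(table)
    dist = (
        table.index.get_level_values("bin_j")
        - table.index.get_level_values("bin_i")
    ).to_numpy() * resolution
    x = np.log10(dist + resolution)
    logc = np.log2(table.values + 0.5)
    n = logc.shape[1]
    import warnings

    for _ in range(params.n_loess_cycles):
        for a, b in combinations(range(n), 2):
            m = logc[:, a] - logc[:, b]
            with warnings.catch_warnings():
                # heavy distance ties trigger benign 0/0 warnings inside lowess
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = lowess(m, x, frac=params.loess_span, return_sorted=False)
            fit = np.where(np.isfinite(fit), fit, 0.0)
            logc[:, a] -= fit / 2.0
            logc[:, b] += fit / 2.0
    normalized = np.maximum(np.exp2(logc) - 0.5, 0.0)
    return pd.DataFrame(normalized, index=table.index, columns=table.columns)


class TestResult(NamedTuple):
    pvalue: float
    logFC: float
    logCPM: float


def test_bin_pair(
    group1: Sequence[float],
    group2: Sequence[float],
    dispersion: float = 0.0,
    *,
    draws: int = 2000,
    rng: np.random.Generator | None = None,
    lib_sizes: Sequence[float] | None = None,
) -> TestResult:
    """Two-group count test for one bin pair.

    With ``dispersion == 0`` (Poisson counts) the exact conditional
    binomial test is used: conditioned on the total A + B of the rounded
    group sums, A is Binomial(A + B, n1/(n1+n2)) under the null, and the
    two-sided p-value sums all outcomes with point probability <= the
    observed one.  With positive dispersion a seeded parametric bootstrap
    from the fitted null NB (common mean) compares |logFC| of ``draws``
    null resamples with the observed |logFC|.

    logFC = log2((mean2 + 0.5)/(mean1 + 0.5)); logCPM is the average
    log2 counts-per-million over all samples when ``lib_sizes`` is given.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if (g1 < 0).any() or (g2 < 0).any():
        raise ValueError("negative counts")
    n1, n2 = len(g1), len(g2)
    mean1, mean2 = g1.mean(), g2.mean()
    logfc = float(np.log2((mean2 + 0.5) / (mean1 + 0.5)))
    if lib_sizes is not None:
        lib = np.asarray(lib_sizes, dtype=float)
        cpm = (np.concatenate([g1, g2]) + 0.5) / lib * 1.0e6
        logcpm = float(np.log2(cpm).mean())
    else:
        logcpm = float("nan")

    if dispersion == 0:
        a = int(round(g1.sum()))
        b = int(round(g2.sum()))
        if a + b == 0:
            return TestResult(1.0, logfc, logcpm)
        p = stats.binomtest(a, a + b, n1 / (n1 + n2)).pvalue
        return TestResult(float(min(p, 1.0)), logfc, logcpm)

    if rng is None:
        rng = np.random.default_rng(0)
    m = (g1.sum() + g2.sum()) / (n1 + n2)
    if m <= 0:
        return TestResult(1.0, logfc, logcpm)
    r = 1.0 / dispersion
    p_nb = r / (r + m)
    sims = rng.negative_binomial(r, p_nb, size=(draws, n1 + n2))
    sim_logfc = np.log2(
        (sims[:, n1:].mean(axis=1) + 0.5) / (sims[:, :n1].mean(axis=1) + 0.5)
    )
    n_extreme = int(np.sum(np.abs(sim_logfc) >= abs(logfc) - 1e-12))
    pvalue = (1.0 + n_extreme) / (draws + 1.0)
    return TestResult(pvalue, logfc, logcpm)


def estimate_common_dispersion(
    table: pd.DataFrame, groups: np.ndarray
) -> float:
    """Pooled method-of-moments NB dispersion over bin pairs.

    For each group with replication and each bin pair with positive
    within-group mean m and variance s^2, the moment estimate is
    max(0, (s^2 - m)/m^2); the common value is their plain mean.  Returns
    0 with a warning when no group has >= 2 replicates.
    """
    vals: list[np.ndarray] = []
    for g in np.unique(groups):
        sub = table.values[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        vals.append(np.maximum(0.0, (v[ok] - m[ok]) / m[ok] ** 2))
    if not vals:
        log_kv("dispersion_no_replication", estimate=0.0)
        return 0.0
    est = float(np.concatenate(vals).mean())
    log_kv("dispersion_estimated", estimate=round(est, 6))
    return est


def call_differential(
    cs: AllelicContactSet,
    filter_params: FilterParams | None = None,
    call_params: CallParams | None = None,
) -> pd.DataFrame:
    """Full filter -> normalize -> test -> BH chain on a contact set.

    Returns one row per tested bin pair with columns bin_i, bin_j,
    distance, logFC (log2 parent2/parent1), logCPM, pvalue, fdr,
    significant, sorted by (bin_i, bin_j).
    """
    filter_params = filter_params or FilterParams()
    call_params = call_params or CallParams()
    table, groups = build_count_table(cs)
    table = filter_bin_pairs(table, filter_params)
    if table.shape[0] == 0:
        return pd.DataFrame(
            columns=[
                "bin_i", "bin_j", "distance", "logFC", "logCPM",
                "pvalue", "fdr", "significant",
            ]
        )
    dispersion = estimate_common_dispersion(table, groups)
    normalized = cyclic_loess_normalize(table, call_params, cs.resolution)
    lib_sizes = normalized.values.sum(axis=0)
    in1 = groups == PARENT1
    in2 = groups == PARENT2

    seeds = np.random.SeedSequence(call_params.seed).spawn(len(normalized))
    rows = []
    for k, ((i, j), counts) in enumerate(normalized.iterrows()):
        res = test_bin_pair(
            counts.values[in1],
            counts.values[in2],
            dispersion,
            draws=call_params.bootstrap_draws,
            rng=np.random.default_rng(seeds[k]),
            lib_sizes=lib_sizes,
        )
        rows.append((i, j, (j - i) * cs.resolution, res.logFC, res.logCPM, res.pvalue))
    calls = pd.DataFrame(
        rows, columns=["bin_i", "bin_j", "distance", "logFC", "logCPM", "pvalue"]
    )
    calls["fdr"] = multipletests(calls["pvalue"].values, method="fdr_bh")[1]
    calls["significant"] = (
        (calls["fdr"] <= call_params.fdr_cutoff)
        & (calls["logFC"].abs() >= call_params.logfc_cutoff)
        & (calls["logCPM"] >= call_params.logcpm_cutoff)
    )
    calls = calls.sort_values(["bin_i", "bin_j"]).reset_index(drop=True)
    log_kv(
        "differential_called",
        n_tested=len(calls),
        n_significant=int(calls["significant"].sum()),
        dispersion=round(dispersion, 6),
    )
    return calls


def write_calls(
    calls: pd.DataFrame,
    cs: AllelicContactSet,
    path,
    arc_path=None,
) -> None:
    """Write the calls TSV (bit-stable column order) and an optional arc track."""
    out = calls.copy()
    spans1 = [cs.bin_interval(i) for i in out["bin_i"]]
    spans2 = [cs.bin_interval(j) for j in out["bin_j"]]
    out["start1"] = [s for s, _ in spans1]
    out["end1"] = [e for _, e in spans1]
    out["start2"] = [s for s, _ in spans2]
    out["end2"] = [e for _, e in spans2]
    cols = [
        "bin_i", "bin_j", "start1", "end1", "start2", "end2",
        "distance", "logFC", "logCPM", "pvalue", "fdr", "significant",
    ]
    out[cols].to_csv(path, sep="\t", index=False)
    if arc_path is not None:
        arcs = pd.DataFrame(
            {
                "chrom1": cs.window.chrom,
                "start1": out["start1"] - 1,
                "end1": out["end1"],
                "chrom2": cs.window.chrom,
                "start2": out["start2"] - 1,
                "end2": out["end2"],
                "score": -np.log10(np.maximum(out["fdr"], 1e-300)),
            }
        )
        arcs.to_csv(arc_path, sep="\t", index=False, header=False)
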