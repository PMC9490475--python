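"""Allelic ChIP-qPCR calibration and the normalized N/R activity ratio.

A TaqMan assay at a heterozygous SNP reports two fluorophores (VIC for
the non-risk allele, FAM for the risk allele).  Known mixes of DNA from
the two homozygous genotypes give a standard curve of measured
log2(VIC/FAM) against the log2 allelic odds, which is inverted to turn a
measured ratio into a non-risk allele fraction.  The enhancer-activity
readout is the ratio of allelic odds in ChIP over input DNA:

    (N/R)_ChIP / (N/R)_Input

e.g. a ChIP non-risk fraction of 92% over an input fraction of 57.5%
gives (92/8)/(57.5/42.5) = 8.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import log_kv


def _log2_odds(frac: float) -> float:
    if not 0.0 < frac < 1.0:
        raise ValueError(f"fraction {frac} outside the open interval (0, 1)")
    return float(np.log2(frac / (1.0 - frac)))


@dataclass(frozen=True)
class StandardCurve:
    """OLS line of measured log2(VIC/FAM) on log2 non-risk allelic odds."""

    slope: float
    intercept: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("standard curve needs >= 3 mixes")
        if self.slope == 0:
            raise ValueError("standard curve slope is zero")


@dataclass(frozen=True)
class AllelicFractionPair:
    """Non-risk allele fractions in input and ChIP DNA."""

    frac_input: float
    frac_chip: float

    def __post_init__(self) -> None:
        for f in (self.frac_input, self.frac_chip):
            if not 0.0 < f < 1.0:
                raise ValueError(f"fraction {f} outside (0, 1)")


def fit_standard_curve(mixes) -> StandardCurve:
    """Fit the standard curve from (non-risk fraction, measured log2 ratio) pairs.

    Accepts an iterable of 2-tuples or a DataFrame with columns
    ``frac_nonrisk`` and ``log2_vic_fam``.
    """
    if isinstance(mixes, pd.DataFrame):
        pairs = list(zip(mixes["frac_nonrisk"], mixes["log2_vic_fam"]))
    else:
        pairs = list(mixes)
    if len(pairs) < 3:
        raise ValueError("standard curve needs >= 3 known mixes")
    x = np.array([_log2_odds(f) for f, _ in pairs])
    y = np.array([m for _, m in pairs])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate standard curve: all mixes at one fraction")
    fit = stats.linregress(x, y)
    curve = StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(pairs),
    )
    log_kv(
        "standard_curve_fitted",
        slope=round(curve.slope, 6),
        intercept=round(curve.intercept, 6),
        r2=round(curve.r2, 6),
    )
    return curve


def estimate_fraction(measured_log2_ratio: float, curve: StandardCurve) -> float:
    """Invert the standard curve: measured log2(VIC/FAM) -> non-risk fraction."""
    odds = 2.0 ** ((measured_log2_ratio - curve.intercept) / curve.slope)
    return float(odds / (1.0 + odds))


def normalized_allelic_ratio(frac_input: float, frac_chip: float) -> float:
    """(N/R)_ChIP / (N/R)_Input from the two non-risk allele fractions."""
    pair = AllelicFractionPair(frac_input, frac_chip)
    odds_chip = pair.frac_chip / (1.0 - pair.frac_chip)
    odds_input = pair.frac_input / (1.0 - pair.frac_input)
    return odds_chip / odds_input


def calibrate_experiment(
    standards: pd.DataFrame, measurements: pd.DataFrame
) -> dict:
    """Full pipeline: fit curve, invert averaged replicate ratios, form the ratio.

    Replicate measurements are averaged on the log2-ratio scale per sample
    type ("input" / "chip") before inversion.
    """
    curve = fit_standard_curve(standards)
    means = measurements.groupby("sample_type")["log2_vic_fam"].mean()
    for required in ("input", "chip"):
        if required not in means.index:
            raise ValueError(f"no {required!r} measurements")
    frac_input = estimate_fraction(float(means["input"]), curve)
    frac_chip = estimate_fraction(float(means["chip"]), curve)
    return {
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r2": curve.r2,
        "frac_input": frac_input,
        "frac_chip": frac_chip,
        "normalized_ratio": normalized_allelic_ratio(frac_input, frac_chip),
    }
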