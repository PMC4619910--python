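"""Contingency-table chi-square tests and correlation power analysis.

Covers the two statistical side-computations the pipeline needs:

* Pearson chi-square tests of independence on small labeled count tables
  (no continuity correction), e.g. seed-mapping quality vs miRNA arm, or
  regulation direction vs arm;
* Fisher-z based power / sample-size calculation for detecting a Pearson
  correlation of a given magnitude, which motivates the r >= 0.9998 edge
  threshold for a three-replicate design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray


def pearson_chisq(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table.

    ``table`` is a 2-D array-like or DataFrame of nonnegative integers with
    positive row and column sums; expected counts come from the margins and
    no continuity correction is applied.  For df = 2 the upper-tail p has
    the closed form exp(-chi2/2).
    """
    frame = pd.DataFrame(table)
    observed = frame.to_numpy(dtype=float)
    if observed.ndim != 2 or observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("need a table of at least 2x2")
    if (observed < 0).any() or not np.allclose(observed, np.round(observed)):
        raise ValueError("table entries must be nonnegative integers")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("every row and column sum must be positive")
    chi2, p, df, expected = sps.chi2_contingency(observed, correction=False)
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p), expected=expected)


def fisher_z(rho: float) -> float:
    """Fisher variance-stabilizing transform C(rho) = 0.5*ln((1+rho)/(1-rho))."""
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    return float(np.arctanh(rho))


def sample_size_for_correlation(
    rho: float,
    alpha: float = 0.01,
    power: float = 0.8,
    sided: str = "one",
    rounding: str = "ceil",
) -> dict:
    """Samples needed to detect a correlation rho at the given level/power.

    Standard Fisher-z approximation: n = ((z_alpha + z_beta)/C(rho))^2 + 3,
    where z_alpha is the one- or two-sided normal quantile and
    C(rho) the Fisher transform.  Because the unrounded value is rarely an
    integer and conventions differ, both ``ceil`` and ``round`` are exposed;
    the returned dict reports the raw formula value, the rounded ``n`` and
    the conventions used.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    if rounding not in ("ceil", "round"):
        raise ValueError("rounding must be 'ceil' or 'round'")
    c = fisher_z(rho)
    if c == 0:
        raise ValueError("rho too small: Fisher transform is zero")
    z_alpha = sps.norm.ppf(1 - alpha / (1 if sided == "one" else 2))
    z_beta = sps.norm.ppf(power)
    raw = ((z_alpha + z_beta) / c) ** 2 + 3
    n = math.ceil(raw) if rounding == "ceil" else round(raw)
    return {
        "n": int(n),
        "raw": float(raw),
        "rho": rho,
        "alpha": alpha,
        "power": power,
        "sided": sided,
        "rounding": rounding,
        "z_alpha": float(z_alpha),
        "z_beta": float(z_beta),
        "fisher_z": c,
    }
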