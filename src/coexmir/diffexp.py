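"""Small-sample two-group differential expression.

Two tests suited to a 3-vs-3 design:

* a pooled-variance two-sample t-test (df = nA + nB - 2), and
* an exact Wilcoxon rank-sum (Mann-Whitney) test computed by full
  enumeration of every assignment of the pooled values to groups, with
  midranks for ties.

With three tie-free values per group the exact two-sided WRS p can never
fall below 2/C(6,3) = 0.1 — a floor that matters when filtering at
alpha = 0.1: Benjamini-Hochberg adjustment of many tests at the floor can
only leave them at 0.1 if essentially all tests sit there, so raw-p
filtering (``adjust='none'``) is also exposed.

Direction convention: ``down`` means lower mean in the overexpression
(mir142) condition than in the control (null); ``log2fc`` is the
difference of group means on the log2 scale (mir142 - null).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from coexmir.expression import ExpressionMatrix
from coexmir.network import adjust_pvalues

#: Largest enumeration size accepted by wilcoxon_exact: C(nA+nB, nA).
MAX_ENUMERATION = 50_000


def pooled_t_test(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sample t statistic and two-sided p.

    Degenerate conventions when the pooled variance is zero: equal means
    give (0, 1); unequal means give (+/-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if pooled_var == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff)) * float("inf"), 0.0
    se = np.sqrt(pooled_var * (1.0 / a.size + 1.0 / b.size))
    t = diff / se
    return float(t), float(2.0 * sps.t.sf(abs(t), df=df))


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def wilcoxon_exact(group_a, group_b) -> tuple[float, float]:
    """Exact Wilcoxon rank-sum test by full enumeration.

    Returns (W, p) where W is the midrank sum of ``group_a`` and p the
    exact two-sided p-value min(1, 2*min(P(W <= w), P(W >= w))) over all
    C(nA+nB, nA) equally likely assignments of the observed pooled values.
    Feasible for the small group sizes this package targets (up to ~8 per
    group); larger inputs are rejected.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    n_total, n_a = a.size + b.size, a.size
    if comb(n_total, n_a) > MAX_ENUMERATION:
        raise ValueError(
            f"C({n_total},{n_a}) assignments exceed the enumeration limit; "
            "use a normal-approximation rank-sum test instead"
        )
    ranks = _midranks(np.concatenate([a, b]))
    w_obs = float(ranks[:n_a].sum())
    sums = np.fromiter(
        (ranks[list(idx)].sum() for idx in combinations(range(n_total), n_a)),
        dtype=float,
        count=comb(n_total, n_a),
    )
    eps = 1e-9
    p_low = np.mean(sums <= w_obs + eps)
    p_high = np.mean(sums >= w_obs - eps)
    return w_obs, float(min(1.0, 2.0 * min(p_low, p_high)))


def de_table(
    matrix: ExpressionMatrix,
    test: str = "wrs",
    condition_a: str = "mir142",
    condition_b: str = "null",
    adjust: str = "bh",
) -> pd.DataFrame:
    """Per-gene differential expression over the whole matrix.

    Columns: gene, test, statistic, p_raw, p_adj, direction, log2fc.
    ``test`` is ``'wrs'`` (exact rank-sum) or ``'t'`` (pooled t);
    ``adjust`` is ``'bh'`` or ``'none'``.
    """
    if test not in ("wrs", "t"):
        raise ValueError(f"unknown test {test!r}")
    run = wilcoxon_exact if test == "wrs" else pooled_t_test
    values_a, values_b = matrix.group_arrays(condition_a, condition_b)
    rows = []
    for gene, va, vb in zip(matrix.genes, values_a, values_b):
        stat, p = run(va, vb)
        log2fc = float(va.mean() - vb.mean())
        rows.append((gene, test, stat, p, "down" if log2fc < 0 else "up", log2fc))
    table = pd.DataFrame(
        rows, columns=["gene", "test", "statistic", "p_raw", "direction", "log2fc"]
    )
    table["p_adj"] = adjust_pvalues(table["p_raw"].to_numpy(), adjust)
    return table[["gene", "test", "statistic", "p_raw", "p_adj", "direction", "log2fc"]]


def call_de(results: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """Flag genes with adjusted p <= alpha; attach up/down counts as attrs.

    ``results`` is a :func:`de_table` frame.  Returns the flagged subset,
    sorted by (p_adj, gene); ``.attrs['n_up']`` / ``.attrs['n_down']``
    carry the direction counts.
    """
    if alpha < 0 or alpha > 1:
        raise ValueError("alpha must lie in [0, 1]")
    flagged = (
        results.loc[results["p_adj"] <= alpha]
        .sort_values(["p_adj", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    flagged.attrs["n_up"] = int((flagged["direction"] == "up").sum())
    flagged.attrs["n_down"] = int((flagged["direction"] == "down").sum())
    return flagged
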