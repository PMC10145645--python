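"""Dependent-correlation comparisons and correlation summaries.

Implements the asymptotic z-test for two dependent correlations that share
one variable (two gaze-metric/cognitive-test correlations within the same
sample), with the Dunn-Clark covariance term evaluated at the individual
sample correlations, plus Fisher-z confidence intervals for forest-plot
tables.

The sign-ignored mode replaces the two compared correlations by their
absolute values before the Fisher transform (the correlation between the two
compared tests stays signed), matching the convention of comparing the
*strength* of association regardless of direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def pearson_matrix(table: pd.DataFrame, min_n: int = 4) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix over numeric columns.

    Raises on zero-variance columns; every pair must retain at least
    ``min_n`` complete rows.
    """
    numeric = table.select_dtypes("number")
    for col in numeric.columns:
        vals = numeric[col].dropna()
        if len(vals) and float(vals.std(ddof=1)) == 0.0:
            raise ValueError(f"zero-variance column {col!r}")
    for a, b in combinations(numeric.columns, 2):
        n_pair = int(numeric[[a, b]].dropna().shape[0])
        if n_pair < min_n:
            raise ValueError(f"pair ({a!r}, {b!r}) has only {n_pair} complete rows")
    return numeric.corr(method="pearson")


@dataclass
class SteigerResult:
    """One dependent-correlation comparison sharing variable j."""

    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    z: float
    p: float
    sign_ignored: bool


def steiger_test(
    r_jk: float, r_jh: float, r_kh: float, n: int, ignore_sign: bool = True
) -> SteigerResult:
    """z-test for r_jk vs r_jh when j is shared by both correlations.

    Fisher-z transforms the two (optionally absolute) correlations and
    scales their difference by the asymptotic covariance of dependent
    correlations (Dunn-Clark form at the sample values)::

        z = (z_jk - z_jh) * sqrt((n - 3) / (2 - 2 s)),
        s = psi / ((1 - r_jk^2)(1 - r_jh^2)),
        psi = r_kh (1 - r_jk^2 - r_jh^2)
              - r_jk r_jh (1 - r_jk^2 - r_jh^2 - r_kh^2) / 2.

    Two-tailed p from the standard normal. Antisymmetric in (k, h).
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if abs(r) >= 1.0:
            raise ValueError(f"{name} = {r} is not inside (-1, 1)")
    if n < 4:
        raise ValueError("n must be at least 4")
    a, b = (abs(r_jk), abs(r_jh)) if ignore_sign else (r_jk, r_jh)
    z1, z2 = np.arctanh(a), np.arctanh(b)
    psi = r_kh * (1 - a * a - b * b) - a * b * (1 - a * a - b * b - r_kh * r_kh) / 2.0
    s = psi / ((1 - a * a) * (1 - b * b))
    z = float((z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * s)))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r_jk=r_jk, r_jh=r_jh, r_kh=r_kh, n=n, z=z, p=max(p, np.finfo(float).tiny),
        sign_ignored=ignore_sign,
    )


@dataclass
class CorrelationCI:
    """A correlation with its Fisher-z confidence interval."""

    r: float
    n: int
    lo: float
    hi: float
    level: float = 0.95


def fisher_ci(r: float, n: int, level: float = 0.95) -> CorrelationCI:
    """Fisher-z interval: tanh(atanh(r) +/- z_crit / sqrt(n - 3))."""
    if abs(r) >= 1.0:
        raise ValueError("r must be inside (-1, 1)")
    if n < 4:
        raise ValueError("n must be at least 4")
    crit = stats.norm.ppf(0.5 + level / 2.0)
    half = crit / np.sqrt(n - 3)
    z = np.arctanh(r)
    return CorrelationCI(r=r, n=n, lo=float(np.tanh(z - half)), hi=float(np.tanh(z + half)), level=level)


def steiger_table(
    corr: pd.DataFrame,
    n: int,
    metrics: list[str],
    tests: list[str],
    ignore_sign: bool = True,
) -> pd.DataFrame:
    """All pairwise dependent-correlation comparisons, metric by test pair.

    For each gaze metric j and each unordered pair of cognitive tests (k, h),
    compares r_jk against r_jh.
    """
    rows = []
    for j in metrics:
        for k, h in combinations(tests, 2):
            res = steiger_test(corr.loc[j, k], corr.loc[j, h], corr.loc[k, h], n, ignore_sign)
            rows.append(
                {
                    "metric": j,
                    "test_k": k,
                    "test_h": h,
                    "r_jk": res.r_jk,
                    "r_jh": res.r_jh,
                    "r_kh": res.r_kh,
                    "n": n,
                    "z": res.z,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)


def forest_table(
    corr: pd.DataFrame, n: int, metrics: list[str], tests: list[str], level: float = 0.95
) -> pd.DataFrame:
    """Numeric content of a correlation forest plot (r with CI per pair)."""
    rows = []
    for j in metrics:
        for t in tests:
            ci = fisher_ci(float(corr.loc[j, t]), n, level)
            rows.append({"metric": j, "test": t, "r": ci.r, "lo": ci.lo, "hi": ci.hi, "n": n})
    return pd.DataFrame(rows)
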