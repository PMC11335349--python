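"""Proportion statistics for fraction-silenced phenotype tables.

RNAi assays score ``x`` silenced animals out of ``n``.  Point estimates
get Wilson score intervals with continuity correction; pairs of
genotypes are compared with a continuity-corrected two-proportion
chi-squared test (equivalent to R's ``prop.test`` with Yates
correction).  Significance is called at alpha = 0.05, with no
multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class SilencingCounts:
    """Animals scored (``n``) and silenced (``x``) for one genotype x target."""

    genotype: str
    target: str
    n: int
    x: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0 <= self.x <= self.n:
            raise ValueError(f"x must satisfy 0 <= x <= n, got x={self.x}, n={self.n}")


def wilson_interval(
    x: int,
    n: int,
    confidence: float = 0.95,
    continuity: bool = True,
) -> tuple[float, float, float]:
    """Wilson score interval for a binomial proportion.

    Returns ``(point, lower, upper)`` with ``point = x/n``.  With
    ``continuity=True`` (the default) the Newcombe continuity-corrected
    bounds are used; bounds are clipped to [0, 1], and the lower bound is
    exactly 0 at x = 0 (upper exactly 1 at x = n).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must satisfy 0 <= x <= n, got x={x}, n={n}")
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    phat = x / n
    if continuity:
        # Newcombe (1998), method 4
        denom = 2.0 * (n + z * z)
        if x == 0:
            lower = 0.0
        else:
            lower = (
                2.0 * x + z * z - 1.0
                - z * sqrt(z * z - 2.0 - 1.0 / n + 4.0 * phat * (n * (1.0 - phat) + 1.0))
            ) / denom
        if x == n:
            upper = 1.0
        else:
            upper = (
                2.0 * x + z * z + 1.0
                + z * sqrt(z * z + 2.0 - 1.0 / n + 4.0 * phat * (n * (1.0 - phat) - 1.0))
            ) / denom
    else:
        denom = 1.0 + z * z / n
        center = (phat + z * z / (2.0 * n)) / denom
        half = z * sqrt(phat * (1.0 - phat) / n + z * z / (4.0 * n * n)) / denom
        lower, upper = center - half, center + half
    return phat, max(lower, 0.0), min(upper, 1.0)


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided p-value for equality of two binomial proportions.

    Continuity-corrected chi-squared test on the 2x2 table (identical to
    R's ``prop.test`` default).  Degenerate tables in which both margins
    agree exactly (e.g., both proportions 0 or both 1) return p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1:
            raise ValueError(f"group sizes must be >= 1, got n={n}")
        if not 0 <= x <= n:
            raise ValueError(f"count out of range: x={x}, n={n}")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    # chi-squared is undefined when a margin is empty: both groups all
    # silenced or both all unsilenced -> proportions are identical
    if table.sum(axis=0).min() == 0:
        return 1.0
    res = sps.chi2_contingency(table, correction=True)
    return float(res.pvalue)


def score_table(
    rows: Sequence[SilencingCounts],
    comparisons: Sequence[tuple[int, int]] = (),
    confidence: float = 0.95,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Annotated fraction-silenced table.

    One output row per input row, with the Wilson CC interval; rows named
    in ``comparisons`` (pairs of indices into ``rows``) additionally get
    the pairwise p-value and an asterisk when p < ``alpha``.
    """
    n_rows = len(rows)
    for i, j in comparisons:
        if not (0 <= i < n_rows and 0 <= j < n_rows):
            raise ValueError(f"comparison ({i}, {j}) out of range for {n_rows} rows")
    records = []
    for r in rows:
        point, lo, hi = wilson_interval(r.x, r.n, confidence)
        records.append(
            {
                "genotype": r.genotype,
                "target": r.target,
                "n": r.n,
                "x": r.x,
                "fraction": point,
                "ci_low": lo,
                "ci_high": hi,
                "comparison": "",
                "p": np.nan,
                "significant": "",
            }
        )
    out = pd.DataFrame(records)
    for i, j in comparisons:
        p = compare_proportions(rows[i].x, rows[i].n, rows[j].x, rows[j].n)
        label = f"{rows[i].genotype} vs {rows[j].genotype}"
        out.loc[j, "comparison"] = label
        out.loc[j, "p"] = p
        out.loc[j, "significant"] = "*" if p < alpha else "ns"
    return out


def read_counts_tsv(path) -> list[SilencingCounts]:
    """Read a genotype/target/n/x TSV into count records."""
    df = pd.read_csv(path, sep="\t")
    required = {"genotype", "target", "n", "x"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing column(s): {sorted(missing)}")
    return [
        SilencingCounts(str(r.genotype), str(r.target), int(r.n), int(r.x))
        for r in df.itertuples()
    ]
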