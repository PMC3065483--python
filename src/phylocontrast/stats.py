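"""Correlations, group comparisons and summaries for trait tables.

Two correlation modes are provided: ordinary Pearson for raw species
values, and regression-through-the-origin correlation for standardized
contrasts (whose signs are arbitrary, so an intercept term is not
meaningful and the test gains a degree of freedom: t on n-1 df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phylo_io import TraitTable

__all__ = [
    "CorrelationResult",
    "pearson",
    "correlation_through_origin",
    "orient_contrasts",
    "group_compare",
    "group_summary",
]

INGROUP_CLADES = ("Passiflora", "Decaloba")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    mode: str  # "ordinary" | "through-origin"

    def __post_init__(self):
        if not -1.0000000001 <= self.r <= 1.0000000001:
            raise ValueError("correlation outside [-1, 1]")


def pearson(x, y) -> CorrelationResult:
    """Ordinary Pearson correlation with the exact t-based p-value.

    p is two-sided from t = r sqrt(n-2) / sqrt(1-r^2) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, _ = sps.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, n=n, p=p, mode="ordinary")


def orient_contrasts(cx, cy):
    """Flip each contrast pair so the first trait's contrast is >= 0.

    Contrast signs depend on an arbitrary ordering of sister lineages;
    flipping a pair in both traits simultaneously is a no-op for any
    through-origin statistic, and this convention makes reported values
    reproducible.
    """
    cx = np.asarray(cx, dtype=float).copy()
    cy = np.asarray(cy, dtype=float).copy()
    flip = cx < 0
    cx[flip] *= -1
    cy[flip] *= -1
    return cx, cy


def correlation_through_origin(cx, cy) -> CorrelationResult:
    """Correlation of two contrast vectors constrained through the origin.

    r = sum(cx*cy) / sqrt(sum(cx^2) sum(cy^2)); the two-sided p uses
    t = r sqrt(n-1) / sqrt(1-r^2) on n-1 df (no intercept estimated).
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    if cx.shape != cy.shape or cx.ndim != 1:
        raise ValueError("contrast vectors must be equal-length")
    n = cx.size
    if n < 2:
        raise ValueError("need at least 2 contrasts")
    sxx = float(cx @ cx)
    syy = float(cy @ cy)
    if sxx == 0 or syy == 0:
        raise ValueError("zero contrast vector")
    r = float(np.clip(cx @ cy / np.sqrt(sxx * syy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(n - 1) / np.sqrt(1.0 - r * r)
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return CorrelationResult(r=r, n=n, p=p, mode="through-origin")


def group_compare(table: TraitTable, trait: str, groups=INGROUP_CLADES) -> dict:
    """Between-clade tests: Welch t for means, F-ratio for variances.

    The variance comparison is a two-sided F test on the ratio of sample
    variances (a t-test on variances is nonstandard; the report flags
    the substitution).
    """
    a = table.data.loc[table.data["clade"] == groups[0], trait].to_numpy()
    b = table.data.loc[table.data["clade"] == groups[1], trait].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # identical constant groups: no evidence of any difference
        return {
            "mean_test": {"t": 0.0, "p": 1.0, "df": float(len(a) + len(b) - 2)},
            "variance_test": {"F": 1.0, "p": 1.0},
            "variance_test_method": "F-ratio (in place of a variance t-test)",
        }
    t, p_mean = sps.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite df
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    F = va / vb
    cdf = sps.f.cdf(F, na - 1, nb - 1)
    p_var = float(2.0 * min(cdf, 1.0 - cdf))
    return {
        "mean_test": {"t": float(t), "p": float(p_mean), "df": float(df)},
        "variance_test": {"F": float(F), "p": min(p_var, 1.0)},
        "variance_test_method": "F-ratio (in place of a variance t-test)",
    }


def group_summary(table: TraitTable, ingroup=INGROUP_CLADES) -> pd.DataFrame:
    """Per-clade and ingroup-total mean and sample SD for every trait.

    SDs use the n-1 denominator.  The "total" row pools the ingroup
    clades only (the outgroup is excluded, consistent with the pooled
    means the packaged table prints).  Single-member groups report a
    missing SD.
    """
    rows = []
    df = table.data
    groups = [(c, df[df["clade"] == c]) for c in sorted(df["clade"].unique())]
    groups.append(("total", df[df["clade"].isin(ingroup)]))
    for name, g in groups:
        row = {"group": name, "n": len(g)}
        for trait in table.trait_names:
            row[f"{trait}_mean"] = g[trait].mean() if len(g) else np.nan
            row[f"{trait}_sd"] = (
                g[trait].std(ddof=1) if len(g) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
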