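"""Genotype–phenotype and covariate–phenotype association testing.

Covers the nonparametric battery used for pharmacogenetic screens:
the Jonckheere–Terpstra trend test across allele-dose-ordered genotype
groups (with exact permutation p for small samples), the Mann–Whitney
U test, Bonferroni thresholding, multiple linear regression with dual
reporting (marginal Pearson r per factor plus joint OLS coefficients),
diet-score construction, and zygosity verification from a marker panel.

Conventions: the Mann–Whitney statistic is U = #(x < y) + ½·#ties for
group 1 vs group 2 (so the JT statistic for two groups equals it
exactly); normal approximations are tie-corrected and used without
continuity correction.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "jonckheere_terpstra",
    "mann_whitney",
    "bonferroni_threshold",
    "multiple_regression",
    "diet_scores",
    "verify_zygosity",
    "genotype_trend_table",
]

PROTEIN_ITEMS = ("meat", "sausage", "fish", "dairy_products", "eggs")
VEGETABLE_ITEMS = ("salad_raw_vegetable", "cooked_vegetable")


def _pair_count(x: np.ndarray, y: np.ndarray) -> float:
    """#(x_i < y_j) + ½·#(x_i == y_j) over all cross pairs."""
    less = np.sum(x[:, None] < y[None, :])
    ties = np.sum(x[:, None] == y[None, :])
    return float(less) + 0.5 * float(ties)


def _jt_statistic(groups: list[np.ndarray]) -> float:
    return sum(
        _pair_count(groups[i], groups[j])
        for i, j in combinations(range(len(groups)), 2)
    )


def _jt_exact_tail(groups: list[np.ndarray], observed: float) -> tuple[float, float]:
    """(P(JT >= observed), P(JT <= observed)) by full enumeration of all
    assignments of the pooled values to the group sizes."""
    pooled = np.sort(np.concatenate(groups))
    sizes = [len(g) for g in groups]
    n = len(pooled)
    total = 0
    ge = 0
    le = 0

    def rec(remaining_idx: tuple[int, ...], gi: int, assigned: list[np.ndarray]):
        nonlocal total, ge, le
        if gi == len(sizes) - 1:
            stat = _jt_statistic(assigned + [pooled[list(remaining_idx)]])
            total += 1
            if stat >= observed - 1e-9:
                ge += 1
            if stat <= observed + 1e-9:
                le += 1
            return
        for idx in combinations(remaining_idx, sizes[gi]):
            rest = tuple(i for i in remaining_idx if i not in idx)
            rec(rest, gi + 1, assigned + [pooled[list(idx)]])

    rec(tuple(range(n)), 0, [])
    return ge / total, le / total


def jonckheere_terpstra(
    groups: list[np.ndarray] | list[list[float]],
    alternative: str = "increasing",
    exact: bool | None = None,
) -> tuple[float, float, float]:
    """Jonckheere–Terpstra trend test across ordered groups.

    Returns (JT statistic, z, p).  JT is the sum over ordered group
    pairs i<j of the Mann–Whitney count #(x_i < x_j) with ½ credit for
    ties.  p uses the tie-corrected normal approximation, or full
    permutation enumeration when ``exact`` is True (default: exact for
    pooled n ≤ 12).

    alternative: 'increasing' (right tail), 'decreasing' (left tail) or
    'two-sided'.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two ordered groups")
    if any(len(g) == 0 for g in gs):
        raise ValueError("all groups must be non-empty")
    if alternative not in ("increasing", "decreasing", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    jt = _jt_statistic(gs)
    pooled = np.concatenate(gs)
    n = len(pooled)
    sizes = np.array([len(g) for g in gs], dtype=float)
    mean = (n * n - np.sum(sizes**2)) / 4.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(sizes * (sizes - 1) * (2 * sizes + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = 0.0
    if n > 2:
        term2 = (
            np.sum(sizes * (sizes - 1) * (sizes - 2))
            * np.sum(t * (t - 1) * (t - 2))
            / (36.0 * n * (n - 1) * (n - 2))
        )
    term3 = np.sum(sizes * (sizes - 1)) * np.sum(t * (t - 1)) / (8.0 * n * (n - 1))
    var = term1 + term2 + term3
    z = 0.0 if var <= 0 else (jt - mean) / np.sqrt(var)

    if exact is None:
        exact = n <= 12
    if var <= 0:  # complete ties: no evidence either way
        return jt, 0.0, 1.0
    if exact:
        p_ge, p_le = _jt_exact_tail(gs, jt)
        if alternative == "increasing":
            p = p_ge
        elif alternative == "decreasing":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        if alternative == "increasing":
            p = float(stats.norm.sf(z))
        elif alternative == "decreasing":
            p = float(stats.norm.cdf(z))
        else:
            p = float(2.0 * stats.norm.sf(abs(z)))
    return jt, float(z), float(p)


def mann_whitney(
    group1, group2, alternative: str = "two-sided", exact: bool | None = None
) -> tuple[float, float]:
    """Mann–Whitney U test; U = #(x<y) + ½·ties for group1 vs group2.

    'two-sided', 'greater' (group2 tends larger) or 'less'.  For the
    one-sided alternatives this is the Jonckheere–Terpstra test with
    two groups, which is how it is computed.
    """
    x, y = np.asarray(group1, float), np.asarray(group2, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    alt = {"two-sided": "two-sided", "greater": "increasing", "less": "decreasing"}[
        alternative
    ]
    u, _, p = jonckheere_terpstra([x, y], alternative=alt, exact=exact)
    return u, p


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha/n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def multiple_regression(
    phenotype: np.ndarray | pd.Series,
    factors: pd.DataFrame,
    marginal: str = "pearson",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Joint OLS of phenotype on factors with dual per-factor reporting.

    Per factor: the marginal Pearson correlation r with the phenotype
    (or the partial correlation with ``marginal='partial'``), its
    square, the joint OLS coefficient and its p-value.  Overall: the
    multiple correlation R, R², and the F-test p of the joint fit.
    """
    y = np.asarray(phenotype, dtype=float)
    X = factors.astype(float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > n_factors + 1 ({n} <= {k + 1})")
    if (X.std(axis=0) == 0).any():
        const = list(X.columns[X.std(axis=0) == 0])
        raise ValueError(f"constant factor(s): {const}")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
        raise ValueError(
            f"rank-deficient design; most collinear factors: "
            f"{corr.index[i]!r} and {corr.columns[j]!r}"
        )
    ols = sm.OLS(y, Xc).fit()
    rows = []
    for col in X.columns:
        if marginal == "partial":
            others = [c for c in X.columns if c != col]
            ry = sm.OLS(y, sm.add_constant(X[others])).fit().resid
            rx = sm.OLS(X[col].to_numpy(), sm.add_constant(X[others])).fit().resid
            r = float(np.corrcoef(rx, ry)[0, 1])
        else:
            r = float(np.corrcoef(X[col], y)[0, 1])
        rows.append(
            {
                "factor": col,
                "r": r,
                "r2": r * r,
                "coefficient": float(ols.params[col]),
                "p": float(ols.pvalues[col]),
            }
        )
    overall = {
        "R": float(np.sqrt(ols.rsquared)),
        "R2": float(ols.rsquared),
        "p": float(ols.f_pvalue),
        "n": int(n),
    }
    return pd.DataFrame(rows), overall


def diet_scores(covariates: pd.DataFrame) -> pd.DataFrame:
    """Protein score = mean(meat, sausage, fish, dairy products, eggs);
    vegetable score = mean(salad/raw vegetable, cooked vegetable)."""
    missing = [c for c in PROTEIN_ITEMS + VEGETABLE_ITEMS if c not in covariates]
    if missing:
        raise ValueError(f"missing diet item(s): {missing}")
    out = covariates.copy()
    out["protein_score"] = covariates[list(PROTEIN_ITEMS)].mean(axis=1)
    out["vegetable_score"] = covariates[list(VEGETABLE_ITEMS)].mean(axis=1)
    return out


def verify_zygosity(
    genotypes: pd.DataFrame,
    pairs: pd.DataFrame,
    zygosity_loci: list[str] | None = None,
) -> pd.DataFrame:
    """Infer zygosity per pair: MZ iff genotypes are identical at every
    zygosity locus; any mismatch ⇒ DZ; missing genotypes ⇒ indeterminate.

    ``genotypes`` is long (subject_id, locus, allele_count); ``pairs``
    maps subject_id → pair_id (and optionally a declared zygosity for
    the concordance column).
    """
    if zygosity_loci is None:
        zygosity_loci = sorted(
            l for l in genotypes["locus"].unique() if str(l).startswith("ZYG")
        )
    wide = genotypes.pivot_table(
        index="subject_id", columns="locus", values="allele_count", aggfunc="first"
    )
    rows = []
    for pid, g in pairs.groupby("pair_id"):
        sids = sorted(g["subject_id"])
        declared = g["zygosity"].iloc[0] if "zygosity" in g else None
        if len(sids) != 2:
            rows.append({"pair_id": pid, "inferred": "indeterminate",
                         "declared": declared, "concordant": None})
            continue
        try:
            g1 = wide.loc[sids[0], zygosity_loci]
            g2 = wide.loc[sids[1], zygosity_loci]
        except KeyError:
            g1 = g2 = pd.Series(np.nan, index=zygosity_loci)
        if g1.isna().any() or g2.isna().any():
            inferred = "indeterminate"
        else:
            inferred = "MZ" if (g1.to_numpy() == g2.to_numpy()).all() else "DZ"
        rows.append(
            {
                "pair_id": pid,
                "inferred": inferred,
                "declared": declared,
                "concordant": None
                if inferred == "indeterminate" or declared is None
                else bool(inferred == declared),
            }
        )
    return pd.DataFrame(rows)


def genotype_trend_table(
    phenotype: pd.DataFrame,
    genotypes: pd.DataFrame,
    value_col: str,
    loci: list[str] | None = None,
) -> pd.DataFrame:
    """Per-locus genotype groups (allele dose 0/1/2) with n, mean ± SD of
    the phenotype, and the Jonckheere–Terpstra trend p across doses."""
    if loci is None:
        loci = [l for l in genotypes["locus"].unique() if not str(l).startswith("ZYG")]
    merged = genotypes.merge(phenotype[["subject_id", value_col]], on="subject_id")
    rows = []
    for locus in loci:
        sub = merged[merged["locus"] == locus]
        groups = [
            sub.loc[sub["allele_count"] == dose, value_col].to_numpy()
            for dose in (0, 1, 2)
        ]
        present = [g for g in groups if len(g)]
        p = np.nan
        if len(present) >= 2:
            _, _, p = jonckheere_terpstra(present, alternative="two-sided")
        for dose, g in zip((0, 1, 2), groups):
            rows.append(
                {
                    "locus": locus,
                    "allele_count": dose,
                    "n": len(g),
                    "mean": float(np.mean(g)) if len(g) else np.nan,
                    "sd": float(np.std(g, ddof=1)) if len(g) > 1 else np.nan,
                    "trend_p": p,
                }
            )
    return pd.DataFrame(rows)
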