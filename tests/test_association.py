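"""Association battery: Jonckheere–Terpstra (exact and asymptotic),
Mann–Whitney conventions, Bonferroni, regression dual reporting,
diet scores, zygosity verification."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twinpk.association import (
    bonferroni_threshold,
    diet_scores,
    genotype_trend_table,
    jonckheere_terpstra,
    mann_whitney,
    multiple_regression,
    verify_zygosity,
)


def oracle_jt_stat(groups):
    s = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[j]:
                    s += (x < y) + 0.5 * (x == y)
    return s


def oracle_exact_p(groups, observed, tail="ge"):
    """Brute force: every distinct labelled permutation of the pooled
    values over the group sizes, equally weighted."""
    pooled = tuple(np.concatenate(groups))
    sizes = [len(g) for g in groups]
    hits = total = 0
    for perm in permutations(pooled):
        cut, gs = 0, []
        for s in sizes:
            gs.append(np.array(perm[cut : cut + s]))
            cut += s
        stat = oracle_jt_stat(gs)
        total += 1
        ok = stat >= observed - 1e-9 if tail == "ge" else stat <= observed + 1e-9
        hits += ok
    return hits / total


def test_jt_maximal_separation_worked_example():
    groups = [[1, 2], [3, 4], [5, 6]]
    jt, z, p = jonckheere_terpstra(groups, alternative="increasing", exact=True)
    assert jt == 12.0
    assert p == pytest.approx(1 / 90)
    assert p == pytest.approx(oracle_exact_p([np.array(g) for g in groups], jt))


def test_jt_exact_matches_enumeration_oracle_small_random():
    rng = np.random.default_rng(0)
    for _ in range(20):
        k = rng.integers(2, 4)
        sizes = rng.integers(1, 4, k)
        while sizes.sum() > 7:  # keep the factorial oracle cheap
            sizes = rng.integers(1, 4, k)
        groups = [rng.integers(0, 5, s).astype(float) for s in sizes]
        jt, _, p = jonckheere_terpstra(groups, alternative="increasing", exact=True)
        assert p == pytest.approx(oracle_exact_p(groups, jt), abs=1e-12)


def test_jt_two_groups_reduces_to_mann_whitney():
    rng = np.random.default_rng(1)
    for _ in range(10):
        x = rng.normal(0, 1, rng.integers(3, 8))
        y = rng.normal(0.5, 1, rng.integers(3, 8))
        jt, _, p_jt = jonckheere_terpstra([x, y], alternative="increasing")
        u, p_mw = mann_whitney(x, y, alternative="greater")
        assert jt == u
        assert p_jt == p_mw


def test_jt_complete_ties():
    jt, z, p = jonckheere_terpstra([[2.0, 2.0], [2.0], [2.0, 2.0]])
    assert z == 0.0 and p == 1.0


def test_jt_input_validation():
    with pytest.raises(ValueError, match="two ordered groups"):
        jonckheere_terpstra([[1.0, 2.0]])
    with pytest.raises(ValueError, match="non-empty"):
        jonckheere_terpstra([[1.0], []])


def test_jt_normal_approximation_against_scipy_mannwhitney():
    """For two groups the tie-corrected normal JT p must equal scipy's
    asymptotic Mann–Whitney p without continuity correction."""
    rng = np.random.default_rng(2)
    for _ in range(10):
        x = rng.integers(0, 6, 15).astype(float)
        y = rng.integers(1, 7, 12).astype(float)
        _, _, p = jonckheere_terpstra([x, y], alternative="increasing", exact=False)
        ref = stats.mannwhitneyu(
            y, x, alternative="greater", use_continuity=False, method="asymptotic"
        ).pvalue
        assert p == pytest.approx(ref, abs=1e-10)


def test_mann_whitney_worked_examples():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6], alternative="greater", exact=True)
    assert u == 9.0
    assert p == pytest.approx(1 / 20)
    _, p_same = mann_whitney([1.0, 2.0], [1.0, 2.0], alternative="two-sided")
    assert p_same == pytest.approx(1.0)
    u1, p1 = mann_whitney([1.0], [2.0], alternative="greater", exact=True)
    assert u1 == 1.0 and p1 == pytest.approx(0.5)


def test_mann_whitney_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(3)
    for _ in range(10):
        x = rng.permutation(20)[:5].astype(float)
        y = rng.permutation(40)[:6].astype(float) + 0.5
        u, p = mann_whitney(x, y, alternative="greater", exact=True)
        ref = stats.mannwhitneyu(y, x, alternative="greater", method="exact")
        assert u == ref.statistic  # scipy's U for (y, x) counts #(x<y) pairs
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_bonferroni_thresholds():
    assert bonferroni_threshold(0.05, 10) == pytest.approx(0.005)
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.05, 2) == 0.025
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


@given(st.integers(1, 50), st.integers(1, 50))
@settings(max_examples=30, deadline=None)
def test_bonferroni_monotone_nonincreasing(n1, n2):
    lo, hi = sorted((n1, n2))
    assert bonferroni_threshold(0.05, hi) <= bonferroni_threshold(0.05, lo)


def test_regression_perfect_single_factor():
    x = np.arange(10.0)
    table, overall = multiple_regression(2 * x, pd.DataFrame({"x": x}))
    row = table.iloc[0]
    assert row["r"] == pytest.approx(1.0)
    assert row["coefficient"] == pytest.approx(2.0)
    assert overall["R2"] == pytest.approx(1.0)


def test_regression_matches_normal_equations_oracle():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(rng.normal(0, 1, (200, 4)), columns=list("abcd"))
    y = rng.normal(0, 1, 200) + X["a"] * 0.5 - X["c"] * 0.2
    table, overall = multiple_regression(y, X)
    Xd = np.column_stack([np.ones(200), X.to_numpy()])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    for i, col in enumerate(X.columns):
        assert table.set_index("factor").loc[col, "coefficient"] == pytest.approx(
            beta[i + 1], abs=1e-10
        )
        # marginal r is the plain Pearson correlation
        assert table.set_index("factor").loc[col, "r"] == pytest.approx(
            np.corrcoef(X[col], y)[0, 1], abs=1e-12
        )
    # residual orthogonality
    resid = y - Xd @ beta
    assert np.max(np.abs(Xd.T @ resid)) < 1e-8


def test_regression_rank_deficiency_names_collinear_factors():
    X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0), "c": np.random.default_rng(0).normal(size=10)})
    with pytest.raises(ValueError, match="'a' and 'b'|'b' and 'a'"):
        multiple_regression(np.arange(10.0) + 1.0, X)


def test_regression_partial_correlation_option():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(0, 1, (100, 2)), columns=["a", "b"])
    y = X["a"].to_numpy() + rng.normal(0, 0.1, 100)
    marg, _ = multiple_regression(y, X, marginal="pearson")
    part, _ = multiple_regression(y, X, marginal="partial")
    # partial r for the driving factor should exceed its marginal... both near 1
    assert abs(part.set_index("factor").loc["a", "r"]) > 0.9
    assert not np.allclose(marg["r"], part["r"])


def test_diet_scores_arithmetic_and_order_invariance():
    df = pd.DataFrame(
        {
            "meat": [3],
            "sausage": [2],
            "fish": [1],
            "dairy_products": [4],
            "eggs": [5],
            "salad_raw_vegetable": [2],
            "cooked_vegetable": [4],
        }
    )
    out = diet_scores(df)
    assert out["protein_score"].iloc[0] == pytest.approx(3.0)
    assert out["vegetable_score"].iloc[0] == pytest.approx(3.0)
    shuffled = df[list(df.columns[::-1])]
    out2 = diet_scores(shuffled)
    assert out2["protein_score"].iloc[0] == 3.0
    with pytest.raises(ValueError, match="eggs"):
        diet_scores(df.drop(columns=["eggs"]))


def _geno_frame(counts_by_subject):
    rows = []
    for sid, counts in counts_by_subject.items():
        for locus, c in counts.items():
            rows.append({"subject_id": sid, "locus": locus, "allele_count": c})
    return pd.DataFrame(rows)


def test_verify_zygosity_rules():
    loci = [f"ZYG{i:02d}" for i in range(1, 24)]
    base = {l: 1 for l in loci}
    mismatch = dict(base, ZYG05=2)
    geno = _geno_frame(
        {
            "a1": base, "a2": base,  # identical 23/23 → MZ
            "b1": base, "b2": mismatch,  # 1 mismatch → DZ
            "c1": base, "c2": {l: base[l] for l in loci[:-1]},  # missing → indeterminate
        }
    )
    pairs = pd.DataFrame(
        {
            "subject_id": ["a1", "a2", "b1", "b2", "c1", "c2"],
            "pair_id": ["A", "A", "B", "B", "C", "C"],
            "zygosity": ["MZ", "MZ", "MZ", "MZ", "DZ", "DZ"],
        }
    )
    out = verify_zygosity(geno, pairs, zygosity_loci=loci).set_index("pair_id")
    assert out.loc["A", "inferred"] == "MZ" and out.loc["A", "concordant"]
    assert out.loc["B", "inferred"] == "DZ" and not out.loc["B", "concordant"]
    assert out.loc["C", "inferred"] == "indeterminate"


def test_genotype_trend_table_detects_dose_effect():
    rng = np.random.default_rng(6)
    n = 120
    counts = rng.integers(0, 3, n)
    pheno = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "cl_f": 1.0 + 0.4 * counts + rng.normal(0, 0.2, n),
        }
    )
    geno = pd.DataFrame(
        {"subject_id": [f"s{i}" for i in range(n)], "locus": "SNP", "allele_count": counts}
    )
    table = genotype_trend_table(pheno, geno, "cl_f")
    assert set(table["allele_count"]) == {0, 1, 2}
    assert (table["n"] > 0).all()
    assert table["trend_p"].iloc[0] < 0.001
    means = table.set_index("allele_count")["mean"]
    assert means.loc[0] < means.loc[1] < means.loc[2]
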