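import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from valveoptics import compare_groups, correlate


def brute_pearson(x, y):
    """Explicit covariance-formula Pearson, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def midranks(v):
    """Average ranks with midrank ties, from first principles."""
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def brute_spearman(x, y):
    return brute_pearson(midranks(x), midranks(y))


def make_table(values_by_cell):
    rows = []
    for (diet, week), values in values_by_cell.items():
        for k, v in enumerate(values):
            rows.append(
                {"animal": f"{diet}{week}{k}", "diet": diet, "week": week,
                 "region": "commissure", "metric": "m", "value": v}
            )
    return pd.DataFrame(rows)


def test_correlation_identity_line():
    x = np.arange(1.0, 11.0)
    assert correlate(x, x, method="pearson").coefficient == pytest.approx(1.0)
    assert correlate(x, x, method="spearman").coefficient == pytest.approx(1.0)


def test_monotone_nonlinearity_separates_methods():
    x = np.arange(1.0, 11.0)
    y = np.exp(x)
    assert correlate(x, y, method="spearman").coefficient == pytest.approx(1.0)
    assert correlate(x, y, method="pearson").coefficient < 1.0


def test_correlation_against_brute_force_oracle():
    """100 seeded draws (some with heavy ties): both coefficients agree with
    explicit-formula implementations to 1e-12."""
    rng = np.random.default_rng(77)
    for i in range(100):
        n = int(rng.integers(5, 40))
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        if i % 3 == 0:  # force midrank ties
            x = np.round(x, 1)
            y = np.round(y, 1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        assert correlate(x, y, method="pearson").coefficient == pytest.approx(
            brute_pearson(x, y), abs=1e-12
        )
        assert correlate(x, y, method="spearman").coefficient == pytest.approx(
            brute_spearman(x, y), abs=1e-12
        )


def test_spearman_is_pearson_on_midranks():
    rng = np.random.default_rng(8)
    for _ in range(25):
        x = np.round(rng.normal(size=15), 1)
        y = np.round(rng.normal(size=15), 1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        s = correlate(x, y, method="spearman").coefficient
        p = correlate(midranks(x), midranks(y), method="pearson").coefficient
        assert s == pytest.approx(p, abs=1e-12)


def test_auto_method_gates_on_ordinal_and_normality():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    y = x + rng.normal(size=30)
    assert correlate(x, y, method="auto").method == "pearson"
    assert correlate(x, y, method="auto", ordinal=True).method == "spearman"
    skewed = np.exp(rng.normal(size=30) * 2)
    assert correlate(skewed, y, method="auto").method == "spearman"


def test_correlation_validation():
    with pytest.raises(ValueError, match="n >= 3"):
        correlate([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="variance"):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="finite"):
        correlate([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


def test_permutation_p_close_to_asymptotic():
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    y = x + rng.normal(size=20)
    asym = correlate(x, y, method="pearson")
    perm = correlate(x, y, method="pearson", n_permutations=2000, seed=1)
    assert perm.coefficient == asym.coefficient
    assert perm.p == pytest.approx(asym.p, abs=0.05)


# ---- group comparisons ----


def normal_table(seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    return make_table(
        {
            ("control", 4): rng.normal(0, 1, 6),
            ("control", 16): rng.normal(0, 1, 6),
            ("pro_calcific", 4): rng.normal(0, 1, 6),
            ("pro_calcific", 16): rng.normal(shift, 1, 6),
        }
    )


def test_anova_path_on_normal_data():
    res = compare_groups(normal_table(seed=1), "m", "commissure")
    assert res.test_used == "anova_tukey"
    assert set(res.factors.factor) == {"diet", "week", "interaction"}
    assert ((res.factors.p >= 0) & (res.factors.p <= 1)).all()
    assert len(res.contrasts) == 6  # all pairs of 4 cells


def test_large_shift_detected_in_tukey_contrast():
    res = compare_groups(normal_table(seed=2, shift=5.0), "m", "commissure")
    p = res.contrast_p("control-16", "pro_calcific-16")
    assert p < 0.01


def test_kruskal_path_on_heavy_tailed_data():
    rng = np.random.default_rng(4)
    table = make_table(
        {
            ("control", 4): rng.standard_cauchy(8) ** 3,
            ("control", 16): rng.standard_cauchy(8) ** 3,
            ("pro_calcific", 4): rng.standard_cauchy(8) ** 3,
            ("pro_calcific", 16): rng.standard_cauchy(8) ** 3,
        }
    )
    res = compare_groups(table, "m", "commissure")
    assert res.test_used == "kruskal_wallis"
    assert len(res.contrasts) == 6
    assert ((res.contrasts.p_adj >= 0) & (res.contrasts.p_adj <= 1)).all()


def test_tukey_adjusted_p_not_below_unadjusted_pairwise():
    """Tukey family-wise p for each pair >= the pooled-variance t-test p."""
    table = normal_table(seed=6, shift=1.0)
    res = compare_groups(table, "m", "commissure")
    cells = {c: g.value.to_numpy() for c, g in table.assign(
        cell=[f"{d}-{w}" for d, w in zip(table.diet, table.week)]
    ).groupby("cell")}
    n_total = sum(len(v) for v in cells.values())
    k = len(cells)
    mse = sum(((v - v.mean()) ** 2).sum() for v in cells.values()) / (n_total - k)
    for _, row in res.contrasts.iterrows():
        a, b = cells[row.group1], cells[row.group2]
        se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
        t = abs(a.mean() - b.mean()) / se
        p_unadj = 2 * sps.t.sf(t, n_total - k)
        assert row.p_adj >= p_unadj - 1e-12


def test_tukey_matches_statsmodels_reference():
    """Cross-check contrast p-values against statsmodels pairwise_tukeyhsd."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    table = normal_table(seed=9, shift=1.5)
    res = compare_groups(table, "m", "commissure")
    labels = [f"{d}-{w}" for d, w in zip(table.diet, table.week)]
    tk = pairwise_tukeyhsd(table.value.to_numpy(), np.array(labels))
    ref = {
        (row[0], row[1]): p
        for row, p in zip(tk.summary().data[1:], np.asarray(tk.pvalues, float))
    }
    for _, row in res.contrasts.iterrows():
        key = (row.group1, row.group2) if (row.group1, row.group2) in ref else (row.group2, row.group1)
        assert row.p_adj == pytest.approx(ref[key], abs=1e-6)


def test_constant_data_rejected():
    table = make_table({("control", 4): [2.0] * 4, ("pro_calcific", 4): [2.0] * 4})
    with pytest.raises(ValueError, match="identical"):
        compare_groups(table, "m", "commissure")


def test_insufficient_replication_rejected():
    table = make_table({("control", 4): [1.0], ("pro_calcific", 4): [2.0]})
    with pytest.raises(ValueError, match="replication"):
        compare_groups(table, "m", "commissure")


def test_comparison_deterministic():
    table = normal_table(seed=12, shift=0.7)
    a = compare_groups(table, "m", "commissure")
    b = compare_groups(table, "m", "commissure")
    assert a.factors.equals(b.factors)
    assert a.contrasts.equals(b.contrasts)
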