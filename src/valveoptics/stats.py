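"""Group-comparison and correlation statistics for valve study tables.

Study tables are long-format records {animal, diet, week, region, metric,
value}. Comparison of diet groups over time uses a two-way ANOVA (Type-II sums
of squares, since cell counts are small and unbalanced) with Tukey HSD
contrasts over the diet x week cells when residuals pass a Shapiro-Wilk
normality check; otherwise a Kruskal-Wallis rank test with Dunn-style
pairwise rank contrasts (Holm-adjusted) is used. Correlations are Pearson for
normally distributed pairs and Spearman (midrank ties) for ordinal or
non-normal data; ``method='auto'`` applies that gate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class ComparisonResult:
    """Diet/week factor tests plus all-pairs contrasts for one metric/region."""

    factors: pd.DataFrame  # factor, statistic, p
    contrasts: pd.DataFrame  # group1, group2, p_adj, reject
    test_used: str  # "anova_tukey" or "kruskal_wallis"
    normality_p: float
    alpha: float

    def contrast_p(self, group1: str, group2: str) -> float:
        c = self.contrasts
        hit = c[
            ((c.group1 == group1) & (c.group2 == group2))
            | ((c.group1 == group2) & (c.group2 == group1))
        ]
        if hit.empty:
            raise KeyError(f"no contrast between {group1!r} and {group2!r}")
        return float(hit.p_adj.iloc[0])


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p: float
    n: int


def _cell_label(diet: str, week) -> str:
    return f"{diet}-{int(week)}"


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    region: str,
    alpha: float = 0.05,
    with_contrasts: bool = True,
) -> ComparisonResult:
    """Compare diet groups across weeks for one metric in one region.

    Requires at least two diet x week cells with >= 2 observations each.
    Constant data raises (a p-value of 0 from zero variance would be
    meaningless).
    """
    sub = table[(table.metric == metric) & (table.region == region)].copy()
    if sub.empty:
        raise ValueError(f"no rows for metric={metric!r}, region={region!r}")
    values = sub.value.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite metric values")
    if np.ptp(values) == 0:
        raise ValueError("degenerate data: all values identical")

    sub["cell"] = [_cell_label(d, w) for d, w in zip(sub.diet, sub.week)]
    counts = sub.groupby("cell").size()
    if (counts >= 2).sum() < 2:
        raise ValueError(
            f"insufficient replication: need >= 2 cells with >= 2 observations, got {dict(counts)}"
        )

    residuals = sub.value - sub.groupby("cell").value.transform("mean")
    if np.ptp(residuals.to_numpy()) == 0:
        # zero within-cell spread: normality untestable and the parametric
        # error model degenerate; fall through to the rank test
        normality_p = 0.0
    else:
        normality_p = float(sps.shapiro(residuals).pvalue)

    cell_names = sorted(sub.cell.unique())
    cells = [sub.value[sub.cell == c].to_numpy(dtype=float) for c in cell_names]
    if normality_p >= alpha:
        model = smf.ols("value ~ C(diet) * C(week)", data=sub).fit()
        an = sm.stats.anova_lm(model, typ=2)
        factors = pd.DataFrame(
            {
                "factor": ["diet", "week", "interaction"],
                "statistic": [
                    an.loc["C(diet)", "F"],
                    an.loc["C(week)", "F"],
                    an.loc["C(diet):C(week)", "F"],
                ],
                "p": [
                    an.loc["C(diet)", "PR(>F)"],
                    an.loc["C(week)", "PR(>F)"],
                    an.loc["C(diet):C(week)", "PR(>F)"],
                ],
            }
        )
        if with_contrasts:
            tk = sps.tukey_hsd(*cells)
            rows = []
            for i, j in itertools.combinations(range(len(cells)), 2):
                p_adj = float(tk.pvalue[i, j])
                rows.append(
                    {
                        "group1": cell_names[i],
                        "group2": cell_names[j],
                        "estimate": float(cells[j].mean() - cells[i].mean()),
                        "p_adj": p_adj,
                        "reject": p_adj < alpha,
                    }
                )
            contrasts = pd.DataFrame(rows)
        else:
            contrasts = pd.DataFrame(columns=["group1", "group2", "estimate", "p_adj", "reject"])
        test_used = "anova_tukey"
    else:
        stat, p = sps.kruskal(*cells)
        factors = pd.DataFrame(
            {"factor": ["groups"], "statistic": [float(stat)], "p": [float(p)]}
        )
        if with_contrasts:
            contrasts = _dunn_contrasts(sub, alpha)
        else:
            contrasts = pd.DataFrame(columns=["group1", "group2", "estimate", "p_adj", "reject"])
        test_used = "kruskal_wallis"

    return ComparisonResult(
        factors=factors,
        contrasts=contrasts,
        test_used=test_used,
        normality_p=normality_p,
        alpha=alpha,
    )


def _dunn_contrasts(sub: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Dunn's pairwise rank contrasts after Kruskal-Wallis, Holm-adjusted."""
    ranks = sps.rankdata(sub.value.to_numpy(dtype=float))
    n = ranks.size
    groups = {cell: ranks[(sub.cell == cell).to_numpy()] for cell in sub.cell.unique()}
    _, tie_counts = np.unique(sub.value.to_numpy(dtype=float), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    rows = []
    for (c1, r1), (c2, r2) in itertools.combinations(groups.items(), 2):
        se = np.sqrt(var_base * (1.0 / r1.size + 1.0 / r2.size))
        z = (r1.mean() - r2.mean()) / se if se > 0 else 0.0
        rows.append({"group1": c1, "group2": c2, "estimate": r2.mean() - r1.mean(), "p_raw": 2 * sps.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    # Holm step-down adjustment
    order = np.argsort(out.p_raw.to_numpy())
    m = len(out)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * out.p_raw.iloc[idx])
        adj[idx] = min(1.0, running)
    out["p_adj"] = adj
    out["reject"] = out.p_adj < alpha
    return out.drop(columns="p_raw")


def correlate(
    x,
    y,
    method: str = "auto",
    ordinal: bool = False,
    alpha: float = 0.05,
    n_permutations: int = 0,
    seed: int | None = None,
) -> CorrelationResult:
    """Pearson or Spearman correlation of paired values.

    ``method='auto'`` chooses Spearman when either variable is flagged ordinal
    (e.g. IHC score grades) or fails a Shapiro-Wilk normality check at
    ``alpha``; otherwise Pearson. ``n_permutations > 0`` replaces the
    asymptotic p-value with a seeded permutation p-value (useful at small n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 3:
        raise ValueError(f"need n >= 3 pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a correlation variable")

    if method == "auto":
        if ordinal:
            method = "spearman"
        else:
            normal = sps.shapiro(x).pvalue >= alpha and sps.shapiro(y).pvalue >= alpha
            method = "pearson" if normal else "spearman"
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")

    stat_fn = sps.pearsonr if method == "pearson" else sps.spearmanr
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        perm = sps.PermutationMethod(n_resamples=n_permutations, rng=rng)
        res = stat_fn(x, y, method=perm)
    else:
        res = stat_fn(x, y)
    coefficient = float(res.statistic if hasattr(res, "statistic") else res[0])
    p = float(res.pvalue if hasattr(res, "pvalue") else res[1])
    return CorrelationResult(method=method, coefficient=coefficient, p=p, n=int(x.size))


def simulate_null_type1(
    n_tables: int = 1000,
    n_per_cell: int = 6,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the diet effect when both diets share one
    normal distribution (2 diets x 2 weeks design). Returns the fraction of
    simulated tables whose diet p-value falls below ``alpha``."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_tables):
        rows = []
        for diet in ("control", "pro_calcific"):
            for week in (4, 16):
                for k in range(n_per_cell):
                    rows.append(
                        {
                            "animal": f"{diet}-{week}-{k}", "diet": diet, "week": week,
                            "region": "commissure", "metric": "m",
                            "value": float(rng.normal(0.0, 1.0)),
                        }
                    )
        res = compare_groups(
            pd.DataFrame(rows), "m", "commissure", alpha=alpha, with_contrasts=False
        )
        if res.test_used == "anova_tukey":
            p = float(res.factors.loc[res.factors.factor == "diet", "p"].iloc[0])
        else:
            p = float(res.factors.p.iloc[0])
        hits += p < alpha
    return hits / n_tables
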