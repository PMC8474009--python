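"""Downstream statistics for light/heavy ratio matrices.

Covers the full post-quantification path: log2 transformation with the
three-category censoring taxonomy, left-censored imputation from the
below-threshold category, empirical-Bayes moderated t-tests (one- and
two-sample), Benjamini-Hochberg adjustment, one-way ANOVA with Tukey HSD,
robust median-MAD normalization and Spearman-distance sample clustering.

Imputation model
----------------
Cells in category 3 (no signal) are drawn independently from
``Normal(mu - shift*sd, sd)`` where ``mu`` and ``sd`` are the mean and
standard deviation of the category-2 (below-threshold) log2 ratios — the
observed values closest to the detection limit — and ``shift`` defaults to 1
so imputed values sit one standard deviation below them.  Parameters are
estimated per dataset and per enrichment route.

Moderated t-test
----------------
Per-row variances s_g^2 with d_g residual degrees of freedom are modeled as
s_g^2 ~ s0^2 * F(d_g, d0).  The hyperparameters (d0, s0^2) are estimated by
the closed-form method of moments on log s_g^2 (digamma/trigamma moments,
with a Newton inversion of the trigamma function).  The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces the per-row variance in an otherwise ordinary t statistic, which is
referred to a t distribution with d0 + d_g degrees of freedom.  d0 = 0
recovers the ordinary Student t; d0 -> inf pools every row to s0^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from scipy.cluster.hierarchy import linkage


class StatsError(ValueError):
    pass


@dataclass
class RatioMatrix:
    """Peptides x samples log2 ratios with per-cell categories.

    ``values`` holds log2 light/heavy ratios (NaN where missing);
    ``categories`` the 1/2/3 taxonomy (3 = missing before imputation).
    """

    values: pd.DataFrame
    categories: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.categories.index) or not (
            self.values.columns.equals(self.categories.columns)
        ):
            raise StatsError("values and categories must share index/columns")

    def copy(self) -> "RatioMatrix":
        return RatioMatrix(self.values.copy(), self.categories.copy())


@dataclass
class ImputationParams:
    mu: float
    sd: float
    shift: float = 1.0


def categorize_and_transform(records: pd.DataFrame) -> RatioMatrix:
    """Long-format quant records -> log2 RatioMatrix.

    ``records`` needs columns peptide, sample, par, category.  Categories 1-2
    contribute log2(par) (category-2 values are kept as measured); category 3
    becomes a missing cell.
    """
    required = {"peptide", "sample", "par", "category"}
    missing = required - set(records.columns)
    if missing:
        raise StatsError(f"records missing columns {sorted(missing)}")
    bad = records[(records["category"].isin([1, 2])) & ~(records["par"] > 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise StatsError(
            f"non-positive ratio for quantified cell "
            f"({row['peptide']}, {row['sample']})"
        )
    work = records.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        work["log2"] = np.where(
            work["category"].isin([1, 2]), np.log2(work["par"].astype(float)), np.nan
        )
    values = work.pivot(index="peptide", columns="sample", values="log2")
    categories = work.pivot(index="peptide", columns="sample", values="category")
    return RatioMatrix(values.sort_index(), categories.sort_index())


def estimate_imputation_params(
    matrix: RatioMatrix, shift: float = 1.0
) -> ImputationParams:
    """mu/sd of the category-2 (below-threshold) log2 ratios."""
    mask = matrix.categories == 2
    vals = matrix.values.where(mask).to_numpy().ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise StatsError(
            "fewer than 2 category-2 values; supply explicit ImputationParams"
        )
    return ImputationParams(mu=float(vals.mean()), sd=float(vals.std(ddof=1)), shift=shift)


def impute_missing(
    matrix: RatioMatrix,
    params: ImputationParams | None = None,
    seed: int = 0,
    shift: float = 1.0,
) -> RatioMatrix:
    """Replace every category-3 cell with a draw from Normal(mu - shift*sd, sd).

    Categories 1-2 are untouched; re-running with the same seed is
    bit-identical.
    """
    out = matrix.copy()
    if params is None:
        params = estimate_imputation_params(matrix, shift=shift)
    rng = np.random.default_rng(seed)
    mask = (out.categories == 3).to_numpy()
    n = int(mask.sum())
    if n == 0:
        return out
    draws = rng.normal(params.mu - params.shift * params.sd, params.sd, size=n)
    vals = out.values.to_numpy()
    vals[mask] = draws
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return math.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on the scaled-F model for s^2.

    Works on z = log(s^2); E and Var of z involve digamma/trigamma of the
    degrees of freedom, giving closed-form moment equations.  Returns
    (d0, s0_squared); d0 = inf when the observed spread of z is no larger
    than expected under a common variance.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size == 0:
        # Fully degenerate input (e.g. all rows constant): no spread to fit.
        return math.inf, 0.0
    if s2.size == 1:
        return math.inf, float(s2[0])
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = float(np.sum((e - e_mean) ** 2) / (e.size - 1))
    excess = e_var - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return math.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _moderate(
    s2: np.ndarray, df: np.ndarray, d0: float | None, s0_sq: float | None
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Posterior variances and total degrees of freedom."""
    if d0 is None or s0_sq is None:
        d0, s0_sq = fit_f_dist(s2, df)
    if math.isinf(d0):
        post = np.full_like(s2, s0_sq)
        total_df = np.full_like(df, np.inf, dtype=float)
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = d0 + df
    return post, total_df, d0, s0_sq


@dataclass
class ModeratedTestResult:
    table: pd.DataFrame  # row id indexed: effect, t, df, p_value, adj_p_value, n...
    d0: float
    s0_squared: float


def moderated_t_two_sample(
    matrix: RatioMatrix | pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    d0: float | None = None,
    s0_squared: float | None = None,
) -> ModeratedTestResult:
    """Row-wise moderated two-sample t-test of group A vs group B.

    Rows with fewer than 2 non-missing values in either group are skipped
    (flagged with NaN statistics).  Pass ``d0=0`` to disable shrinkage and
    recover the ordinary pooled-variance Student t.
    """
    values = matrix.values if isinstance(matrix, RatioMatrix) else matrix
    a = values[group_a].to_numpy(dtype=float)
    b = values[group_b].to_numpy(dtype=float)
    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    testable = (na >= 2) & (nb >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        var_a = np.nanvar(a, axis=1, ddof=1)
        var_b = np.nanvar(b, axis=1, ddof=1)
    effect = mean_a - mean_b
    df_res = (na + nb - 2).astype(float)
    pooled = np.where(
        testable,
        ((na - 1) * var_a + (nb - 1) * var_b) / np.maximum(df_res, 1),
        np.nan,
    )
    post, total_df, d0, s0_squared = _moderate(
        pooled[testable], df_res[testable], d0, s0_squared
    )
    t = np.full(values.shape[0], np.nan)
    p = np.full(values.shape[0], np.nan)
    dfs = np.full(values.shape[0], np.nan)
    se = np.sqrt(post * (1.0 / na[testable] + 1.0 / nb[testable]))
    eff_t = effect[testable]
    with np.errstate(invalid="ignore", divide="ignore"):
        t[testable] = np.where(
            se > 0,
            np.divide(eff_t, se, out=np.zeros_like(eff_t), where=se > 0),
            np.where(eff_t == 0, 0.0, np.sign(eff_t) * np.inf),
        )
    dfs[testable] = total_df
    p[testable] = 2.0 * sps.t.sf(np.abs(t[testable]), total_df)
    table = pd.DataFrame(
        {
            "effect": np.where(testable, effect, np.nan),
            "t": t,
            "df": dfs,
            "p_value": p,
            "n_a": na,
            "n_b": nb,
            "tested": testable,
        },
        index=values.index,
    )
    table["adj_p_value"] = np.nan
    tested = table["tested"]
    table.loc[tested, "adj_p_value"] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
    return ModeratedTestResult(table=table, d0=d0, s0_squared=s0_squared)


def moderated_t_one_sample(
    matrix: RatioMatrix | pd.DataFrame,
    columns: list[str] | None = None,
    d0: float | None = None,
    s0_squared: float | None = None,
) -> ModeratedTestResult:
    """Row-wise moderated one-sample t-test against mean 0 (ratio-of-ratios)."""
    values = matrix.values if isinstance(matrix, RatioMatrix) else matrix
    if columns is not None:
        values = values[columns]
    x = values.to_numpy(dtype=float)
    n = np.sum(~np.isnan(x), axis=1)
    testable = n >= 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=1)
        var = np.nanvar(x, axis=1, ddof=1)
    df_res = (n - 1).astype(float)
    post, total_df, d0, s0_squared = _moderate(
        var[testable], df_res[testable], d0, s0_squared
    )
    t = np.full(x.shape[0], np.nan)
    p = np.full(x.shape[0], np.nan)
    dfs = np.full(x.shape[0], np.nan)
    se = np.sqrt(post / n[testable])
    eff_t = mean[testable]
    with np.errstate(invalid="ignore", divide="ignore"):
        t[testable] = np.where(
            se > 0,
            np.divide(eff_t, se, out=np.zeros_like(eff_t), where=se > 0),
            np.where(eff_t == 0, 0.0, np.sign(eff_t) * np.inf),
        )
    dfs[testable] = total_df
    p[testable] = 2.0 * sps.t.sf(np.abs(t[testable]), total_df)
    table = pd.DataFrame(
        {
            "effect": np.where(testable, mean, np.nan),
            "t": t,
            "df": dfs,
            "p_value": p,
            "n": n,
            "tested": testable,
        },
        index=values.index,
    )
    table["adj_p_value"] = np.nan
    tested = table["tested"]
    table.loc[tested, "adj_p_value"] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
    return ModeratedTestResult(table=table, d0=d0, s0_squared=s0_squared)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise StatsError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def anova_tukey(
    matrix: RatioMatrix | pd.DataFrame, groups: dict[str, list[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-wise one-way ANOVA plus Tukey HSD pairwise comparisons.

    Groups with fewer than 2 non-missing values are dropped per row (flagged
    in ``dropped_groups``).  Tukey p-values are BH-adjusted across all
    comparisons of all rows.
    """
    values = matrix.values if isinstance(matrix, RatioMatrix) else matrix
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    anova_rows, pair_rows = [], []
    for row_id, row in values.iterrows():
        samples, names, dropped = [], [], []
        for gname, cols in groups.items():
            vals = row[cols].dropna().to_numpy(dtype=float)
            if vals.size >= 2:
                samples.append(vals)
                names.append(gname)
            else:
                dropped.append(gname)
        if len(samples) < 2:
            anova_rows.append(
                {"row": row_id, "F": np.nan, "p_value": np.nan,
                 "dropped_groups": ",".join(dropped)}
            )
            continue
        if all(np.allclose(s, samples[0][0]) for s in samples):
            f_stat, p_val = 0.0, 1.0
        else:
            f_stat, p_val = sps.f_oneway(*samples)
        anova_rows.append(
            {"row": row_id, "F": float(f_stat), "p_value": float(p_val),
             "dropped_groups": ",".join(dropped)}
        )
        tukey = sps.tukey_hsd(*samples)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                pair_rows.append(
                    {
                        "row": row_id,
                        "group_a": names[i],
                        "group_b": names[j],
                        "difference": float(np.mean(samples[i]) - np.mean(samples[j])),
                        "p_value": float(tukey.pvalue[i, j]),
                    }
                )
    anova = pd.DataFrame(anova_rows).set_index("row")
    pairs = pd.DataFrame(pair_rows)
    if not pairs.empty:
        pairs["adj_p_value"] = bh_adjust(pairs["p_value"].to_numpy())
    return anova, pairs


def median_mad_normalize(
    values: pd.DataFrame, consistency: bool = False
) -> tuple[pd.DataFrame, list]:
    """Row-wise robust z-score: (x - median) / MAD.

    MAD is unscaled by default (no 1.4826 consistency factor).  Rows with
    zero MAD become all zeros and are returned in the flag list.
    """
    med = values.median(axis=1, skipna=True)
    mad = (values.sub(med, axis=0)).abs().median(axis=1, skipna=True)
    if consistency:
        mad = mad * 1.4826
    flagged = list(values.index[(mad == 0) | mad.isna()])
    safe = mad.replace(0, np.nan)
    out = values.sub(med, axis=0).div(safe, axis=0)
    out.loc[(mad == 0).values] = 0.0
    return out, flagged


def cluster_samples(
    values: pd.DataFrame, min_shared: int = 3
) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage hierarchical clustering of samples on 1 - Spearman.

    Correlations use pairwise-complete rows (>= ``min_shared`` per pair).
    Columns are ordered lexicographically first so merge order is
    deterministic under ties.  Returns (scipy linkage matrix, sample order).
    """
    if values.shape[1] < 3:
        raise StatsError("need >= 3 samples to cluster")
    cols = sorted(values.columns)
    x = values[cols].to_numpy(dtype=float)
    n = len(cols)
    dist = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
            if both.sum() < min_shared:
                raise StatsError(
                    f"samples {cols[i]!r} and {cols[j]!r} share < {min_shared} rows"
                )
            xi, xj = x[both, i], x[both, j]
            if np.all(xi == xi[0]):
                raise StatsError(f"constant sample {cols[i]!r}: correlation undefined")
            if np.all(xj == xj[0]):
                raise StatsError(f"constant sample {cols[j]!r}: correlation undefined")
            rho = sps.spearmanr(xi, xj).statistic
            dist.append(1.0 - rho)
    z = linkage(np.asarray(dist), method="complete")
    return z, cols


def export_causalpath_table(
    results: pd.DataFrame, path, site_info: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flat gene/site/effect-sign/adjusted-p table for causal network tools.

    ``results`` must be indexed by row id with effect and adj_p_value
    columns; ``site_info`` optionally maps row id -> (gene, site).  Rows are
    sorted by adjusted p.  No network computation is performed here.
    """
    table = results.copy()
    if site_info is not None:
        table = table.join(site_info)
    if "gene" not in table.columns:
        if len(table):
            split = table.index.to_series().astype(str).str.split(" ", n=1, expand=True)
            table["gene"] = split[0]
            table["site"] = split[1] if split.shape[1] > 1 else ""
        else:
            table["gene"] = pd.Series(dtype=str)
            table["site"] = pd.Series(dtype=str)
    out = table.reset_index(names="row_id")[
        ["gene", "site", "effect", "adj_p_value"]
    ].copy()
    out["effect_sign"] = np.sign(out["effect"]).fillna(0).astype(int)
    out = out[["gene", "site", "effect_sign", "adj_p_value"]]
    out = out.sort_values("adj_p_value", kind="stable").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return out
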