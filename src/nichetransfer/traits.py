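"""Life-history trait analyses.

Relates per-species accuracy/transferability summaries to trait
categories with the study's statistical battery: category tabulations,
Pearson contingency chi-square, Gaussian-identity GLMs with single-term
deletion (R's ``drop1`` semantics), Wilcoxon rank-sum and
Kruskal-Wallis tests. The 37-species trait table ships as a package
fixture; it carries two population-trend codings because published
trend assessments conflict for two species (Field Sparrow and Eastern
Meadowlark).
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "load_trait_table",
    "derive_range_components",
    "tabulate_traits",
    "contingency_chisq",
    "glm_drop1",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
]

RANGE_CLASSES = ("WC", "WR", "NEC", "NER")


def load_trait_table(trend_coding: str = "trend") -> pd.DataFrame:
    """The packaged 37-species trait table.

    ``trend_coding`` selects "trend" (primary) or "trend_alt" (the
    alternative coding for the two conflicting species); the chosen
    column is copied into ``trend``. Derived wide/narrow and
    common/rare range components are attached.
    """
    with resources.files("nichetransfer.data").joinpath(
            "table1_traits.csv").open() as fh:
        df = pd.read_csv(fh)
    if trend_coding not in {"trend", "trend_alt"}:
        raise ValueError("trend_coding must be 'trend' or 'trend_alt'")
    df = df.assign(trend=df[trend_coding])
    return derive_range_components(df)


def derive_range_components(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse the 4-level range class into its two 2-level components."""
    bad = set(df["range_class"]) - set(RANGE_CLASSES)
    if bad:
        raise ValueError(f"unknown range classes {sorted(bad)}")
    wide = df["range_class"].isin(["WC", "WR"])
    common = df["range_class"].isin(["WC", "NEC"])
    return df.assign(
        range_wide_narrow=np.where(wide, "wide", "narrow"),
        range_common_rare=np.where(common, "common", "rare"),
    )


def tabulate_traits(df: pd.DataFrame,
                    columns: list[str] | None = None) -> dict[str, pd.Series]:
    """Exact category counts per trait column."""
    allowed = {
        "range_class": set(RANGE_CLASSES),
        "migratory": {"N", "T", "R"},
        "habitat": {"S", "W", "G", "E", "D", "B", "O"},
        "conservation": {"LC", "NT", "V"},
        "trend": {"stable", "increasing", "decreasing"},
    }
    columns = columns or [c for c in allowed if c in df.columns]
    out = {}
    for col in columns:
        if col in allowed:
            bad = df[~df[col].isin(allowed[col])]
            if len(bad):
                raise ValueError(
                    f"unknown {col} level in rows {bad.index.tolist()[:5]}")
        out[col] = df[col].value_counts()
    return out


def contingency_chisq(df: pd.DataFrame, trait_a: str, trait_b: str,
                      ) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on the full
    cross-tabulation of two categorical traits; zero marginals are
    dropped with a warning. Returns (chi2, df, p)."""
    tab = pd.crosstab(df[trait_a], df[trait_b])
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("each trait needs >= 2 observed levels")
    zero_rows = tab.index[tab.sum(axis=1) == 0]
    zero_cols = tab.columns[tab.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(f"dropping zero marginals: rows {list(zero_rows)}, "
                      f"cols {list(zero_cols)}")
        tab = tab.drop(index=zero_rows, columns=zero_cols)
    chi2, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return float(chi2), int(dof), float(p)


def _design_matrix(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Full-rank treatment-coded design with intercept."""
    cols = [np.ones(len(df))]
    for t in terms:
        x = df[t]
        if x.dtype.kind in "ifu" and x.nunique() > 2:
            cols.append(x.to_numpy(float))
        else:
            dummies = pd.get_dummies(x.astype("category"), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
    return np.column_stack(cols)


def _term_df(df: pd.DataFrame, term: str) -> int:
    x = df[term]
    if x.dtype.kind in "ifu" and x.nunique() > 2:
        return 1
    return max(x.nunique() - 1, 1)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rank = np.linalg.matrix_rank(X)
    return float(resid @ resid), rank


def glm_drop1(df: pd.DataFrame, response: str, terms: list[str],
              mode: str = "F") -> pd.DataFrame:
    """Single-term deletion from a Gaussian-identity GLM.

    Fits the full least-squares model with all ``terms`` (categorical
    traits expanded to treatment dummies), then refits once per term
    without it. Reports for each term the deletion sum of squares
    (RSS_reduced - RSS_full), the reduced model's RSS and AIC, and
    either an F test (default, F = (SS/df_term)/(RSS_full/df_resid))
    or a chi-square analysis-of-deviance test (``mode="chisq"``).
    AIC is R's ``extractAIC`` scale: n*log(RSS/n) + 2*edf, without the
    constant n*log(2*pi) + n.
    """
    y = df[response].to_numpy(float)
    n = len(y)
    X_full = _design_matrix(df, terms)
    rss_full, rank_full = _rss(X_full, y)
    if rank_full < X_full.shape[1]:
        raise ValueError("rank-deficient design; aliased terms among "
                         f"{terms}")
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("more parameters than species")

    def aic(rss: float, edf: int) -> float:
        return n * np.log(max(rss, 1e-300) / n) + 2 * edf

    rows = [{"term": "<none>", "df": 0, "ss": np.nan, "rss": rss_full,
             "aic": aic(rss_full, rank_full), "F": np.nan, "p": np.nan}]
    for t in terms:
        X_red = _design_matrix(df, [u for u in terms if u != t])
        rss_red, rank_red = _rss(X_red, y)
        ss = max(rss_red - rss_full, 0.0)
        dft = rank_full - rank_red
        if dft == 0:
            dft = _term_df(df, t)
        if rss_full <= 1e-300 * max(1.0, abs(y).max()):
            f_stat, p = 0.0, 1.0        # zero-variance response guard
        elif mode == "F":
            f_stat = (ss / dft) / (rss_full / df_resid)
            p = float(stats.f.sf(f_stat, dft, df_resid))
        elif mode == "chisq":
            # analysis of deviance: scaled deviance difference ~ chi2
            dev = n * np.log(rss_red / rss_full)
            f_stat = dev
            p = float(stats.chi2.sf(dev, dft))
        else:
            raise ValueError("mode must be 'F' or 'chisq'")
        rows.append({"term": t, "df": dft, "ss": ss, "rss": rss_red,
                     "aic": aic(rss_red, rank_red), "F": f_stat, "p": p})
    return pd.DataFrame(rows).set_index("term")


def wilcoxon_rank_sum(group1: np.ndarray, group2: np.ndarray,
                      ) -> tuple[float, float]:
    """Two-sided rank-sum test; exact enumeration when n1 + n2 <= 12,
    tie-corrected normal approximation otherwise. Returns (W, p) with W
    the Mann-Whitney statistic of group1."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs >= 2 observations")
    has_ties = len(np.unique(np.concatenate([g1, g2]))) < g1.size + g2.size
    method = "exact" if (g1.size + g2.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p
    (df = n_groups - 1). Identical groups give H = 0."""
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len({tuple(a) for a in map(tuple, arrays)}) == 1:
        return 0.0, 1.0
    try:
        h, p = stats.kruskal(*arrays)
    except ValueError:              # all values identical across groups
        return 0.0, 1.0
    return float(h), float(p)
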