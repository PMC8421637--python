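"""Cohort-level inference on switching rates.

Implements the study-style inference layer: a covariate-adjusted group
comparison of pre-exposure rates (ANCOVA with age, education and mean
framewise displacement as covariates), whole-sample paired t-tests of
post- vs pre-exposure rates with per-group post-hocs, Spearman rank
correlations of rates with clinical scores, partial Pearson correlations
controlling for the same covariates, two-sample t-tests recomputable from
published summary statistics, and Benjamini-Hochberg FDR correction across
subnetwork (m = 6) or node (m = 160) families. All p-values are two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "Cohort",
    "ancova_group_effect",
    "paired_t",
    "two_sample_t_summary",
    "spearman",
    "partial_pearson",
    "bh_fdr",
    "run_study_stats",
    "COVARIATES",
    "SCORES",
]

COVARIATES = ("age", "education", "mean_fd")
SCORES = ("BQDS", "BDI", "BAI", "duration")
GROUPS = ("dependent", "control")


@dataclass(frozen=True)
class StatResult:
    """One test result: statistic, its kind (F/t/rho/r), df, two-sided p."""

    statistic: float
    statistic_kind: str
    df: float | tuple[float, float]
    p: float
    n: int
    adjusted_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")
        if self.adjusted_p is not None and self.adjusted_p < self.p - 1e-12:
            raise ValueError("adjusted p below raw p")


@dataclass
class Cohort:
    """Subjects table plus per-(subject, scan) outcome values.

    subjects : DataFrame indexed by subject_id with columns
        group ('dependent'/'control'), age, education, mean_fd,
        BQDS, BDI, BAI, duration (scores may be NaN where not applicable).
    outcomes : DataFrame indexed by (subject_id, scan in {'pre','post'})
        with one column per outcome key: 'global', 'subnet:<name>',
        'node:<id>'.
    """

    subjects: pd.DataFrame
    outcomes: pd.DataFrame
    subjects_detail: Optional[list] = field(default=None, repr=False)

    def outcome_keys(self, level: str) -> list[str]:
        if level == "global":
            return [c for c in self.outcomes.columns if c == "global"]
        prefix = {"subnetwork": "subnet:", "node": "node:"}[level]
        return [c for c in self.outcomes.columns if c.startswith(prefix)]


def _design_matrix(covariates: np.ndarray, names: Sequence[str]) -> np.ndarray:
    x = np.column_stack([np.ones(covariates.shape[0]), covariates])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the first offending column for the caller
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) < j + 1:
                raise ValueError(
                    f"design matrix rank deficient at column {names[j - 1]!r}"
                )
        raise ValueError("design matrix rank deficient")
    return x


def ancova_group_effect(
    outcome: np.ndarray,
    group: Sequence,
    covariates: np.ndarray,
    covariate_names: Sequence[str] = COVARIATES,
) -> StatResult:
    """F-test for a binary group factor adjusting for continuous covariates.

    Fits the full linear model outcome ~ 1 + group + covariates and the
    reduced model without group; F = ((RSS_r - RSS_f)/1) / (RSS_f/df_f).
    """
    outcome = np.asarray(outcome, dtype=float)
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != outcome.size:
        covariates = covariates.T
    levels = pd.unique(pd.Series(list(group)))
    if len(levels) != 2:
        raise ValueError(f"group factor must have 2 levels, got {len(levels)}")
    g = (pd.Series(list(group)) == levels[1]).to_numpy(dtype=float)
    counts = [int((g == v).sum()) for v in (0, 1)]
    if min(counts) < 2:
        raise ValueError("need at least 2 subjects per group")
    names = list(covariate_names) + ["group"]
    x_full = _design_matrix(np.column_stack([covariates, g]), names)
    x_red = x_full[:, :-1]
    fit_full = sm.OLS(outcome, x_full).fit()
    fit_red = sm.OLS(outcome, x_red).fit()
    df_f = outcome.size - x_full.shape[1]
    if df_f <= 0:
        raise ValueError("no residual degrees of freedom")
    f = (fit_red.ssr - fit_full.ssr) / (fit_full.ssr / df_f)
    f = max(float(f), 0.0)
    p = float(sps.f.sf(f, 1, df_f))
    return StatResult(f, "F", (1, df_f), p, outcome.size)


def paired_t(pre: np.ndarray, post: np.ndarray) -> StatResult:
    """Paired t-test of post - pre differences, two-sided."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D and equal length")
    if pre.size < 2:
        raise ValueError("need at least 2 pairs")
    d = post - pre
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("paired differences have zero variance")
    res = sps.ttest_rel(post, pre)
    return StatResult(float(res.statistic), "t", pre.size - 1, float(res.pvalue), pre.size)


def two_sample_t_summary(
    n1: int, mean1: float, sd1: float,
    n2: int, mean2: float, sd2: float,
    variant: str = "pooled",
) -> StatResult:
    """Two-sample t-test recomputed from group summary statistics.

    ``pooled`` assumes equal variances (df = n1 + n2 - 2); ``welch`` uses the
    Welch-Satterthwaite approximation. Suitable for checking published
    demographics tables where only means/SDs/sizes are printed.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        raise ValueError("both group SDs are zero")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df: float = n1 + n2 - 2
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return StatResult(float(res.statistic), "t", df, float(res.pvalue), n1 + n2)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided permutation p over all n! orderings of y (n <= 10)."""
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum())
    count = 0
    total = 0
    chunk = []
    observed = abs(rho) - 1e-12
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += _chunk_count(np.array(chunk), rx_c, ry, denom, observed)
            total += len(chunk)
            chunk = []
    if chunk:
        count += _chunk_count(np.array(chunk), rx_c, ry, denom, observed)
        total += len(chunk)
    return count / total


def _chunk_count(perms, rx_c, ry, denom_x, observed) -> int:
    ry_p = ry[perms]
    ry_c = ry_p - ry_p.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((ry_c**2).sum(axis=1))
    rhos = ry_c @ rx_c / (denom_x * denom_y)
    return int((np.abs(rhos) >= observed).sum())


def spearman(x: np.ndarray, y: np.ndarray, method: str = "t-approx") -> StatResult:
    """Spearman rank correlation with mid-rank ties.

    p-value by the t-approximation t = rho * sqrt((n-2)/(1-rho^2)) by
    default; ``method='exact'`` enumerates all permutations (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if method == "exact":
        if x.size > 10:
            raise ValueError("exact permutation p only for n <= 10")
        p = _exact_spearman_p(x, y, rho)
    elif method != "t-approx":
        raise ValueError(f"unknown method {method!r}")
    p = float(min(max(p, 0.0), 1.0))
    return StatResult(rho, "rho", x.size - 2, p, x.size)


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: Optional[np.ndarray] = None
) -> StatResult:
    """Pearson correlation of x and y after removing covariate effects.

    Both vectors are residualized against [intercept | covariates]; with no
    covariates this reduces to the plain Pearson correlation. df = n - k - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        z = np.empty((n, 0))
    else:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != n:
            z = z.T
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = _design_matrix(z, [f"cov{i}" for i in range(k)]) if k else np.ones((n, 1))
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a vector the covariates explain exactly leaves only rounding noise
    # behind; its partial correlation is 0 by convention, not noise
    def _null(resid, orig):
        scale = ((orig - orig.mean()) ** 2).sum()
        return (resid**2).sum() <= 1e-20 * max(scale, 1e-300)

    if _null(rx, x) or _null(ry, y):
        return StatResult(0.0, "r", n - k - 2, 1.0, n)
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return StatResult(r, "r", df, p, n)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_study_stats(cohort: Cohort, level: str = "global") -> pd.DataFrame:
    """Full inference battery at one outcome level.

    Per outcome at the level: ANCOVA group effect on pre-exposure rates
    (covariates age, education, mean FD); whole-sample paired t of post vs
    pre; per-group post-hoc paired t; Spearman correlation of pre-exposure
    rate with each clinical score in the dependent group. Within each test
    family, p-values are FDR-adjusted across the level's outcomes (the
    single global outcome is left unadjusted).

    Returns a tidy DataFrame with columns level, outcome, test,
    statistic_kind, statistic, df, p, p_fdr, n.
    """
    if level not in ("global", "subnetwork", "node"):
        raise ValueError(f"unknown level {level!r}")
    keys = cohort.outcome_keys(level)
    if not keys:
        raise ValueError(f"cohort has no outcomes at level {level!r}")
    subs = cohort.subjects
    out = cohort.outcomes

    pre = out.xs("pre", level="scan")
    post = out.xs("post", level="scan")
    paired_ids = pre.index.intersection(post.index)
    excluded = sorted(set(subs.index) - set(paired_ids))
    cov_ok = subs[list(COVARIATES)].notna().all(axis=1)
    ancova_ids = pre.index.intersection(subs.index[cov_ok])

    for g in GROUPS:
        if (subs.loc[subs.index.isin(ancova_ids), "group"] == g).sum() < 2:
            raise ValueError(f"ANCOVA cell for group {g!r} is empty or singleton")
        if (subs.loc[subs.index.isin(paired_ids), "group"] == g).sum() < 2:
            raise ValueError(f"paired-test cell for group {g!r} is empty or singleton")

    rows: list[dict] = []

    def add(test: str, outcome: str, res: StatResult) -> None:
        rows.append(
            {
                "level": level,
                "outcome": outcome,
                "test": test,
                "statistic_kind": res.statistic_kind,
                "statistic": res.statistic,
                "df": res.df if np.isscalar(res.df) else str(res.df),
                "p": res.p,
                "n": res.n,
            }
        )

    for key in keys:
        a_out = pre.loc[ancova_ids, key].to_numpy()
        a_grp = subs.loc[ancova_ids, "group"].to_numpy()
        a_cov = subs.loc[ancova_ids, list(COVARIATES)].to_numpy()
        add("ancova_pre_group", key, ancova_group_effect(a_out, a_grp, a_cov))

        p_pre = pre.loc[paired_ids, key].to_numpy()
        p_post = post.loc[paired_ids, key].to_numpy()
        add("paired_all", key, paired_t(p_pre, p_post))
        for g in GROUPS:
            ids_g = [i for i in paired_ids if subs.loc[i, "group"] == g]
            add(
                f"paired_{g}",
                key,
                paired_t(pre.loc[ids_g, key].to_numpy(), post.loc[ids_g, key].to_numpy()),
            )

        dep_ids = [i for i in paired_ids if subs.loc[i, "group"] == "dependent"]
        for score in SCORES:
            if score not in subs.columns:
                continue
            sc = subs.loc[dep_ids, score]
            ok = sc.notna()
            if ok.sum() >= 3:
                add(
                    f"spearman_{score}",
                    key,
                    spearman(pre.loc[sc.index[ok], key].to_numpy(), sc[ok].to_numpy()),
                )

    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    if level != "global":
        for test_name, idx in table.groupby("test").groups.items():
            table.loc[idx, "p_fdr"] = bh_fdr(table.loc[idx, "p"].to_numpy())
    table.attrs["excluded_subjects"] = excluded
    return table
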