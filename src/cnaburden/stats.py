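"""Associations, differential-region tests and survival analysis.

Score-vs-variable associations dispatch on the variable type: a two-level
categorical variable gets a t-test plus Wilcoxon rank-sum; more levels get
one-way ANOVA plus Kruskal-Wallis; a numeric variable gets Pearson and
Spearman correlations. Differential-region tests compare window profiles
between sample groups either on the window means (t-test) or on the
gain/loss/neutral state counts (exact Fisher test on the contingency table),
with Benjamini-Hochberg correction across windows.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .profiles import ProfileMatrix, call_states

STATES = ("gain", "loss", "neutral")


# ---------------------------------------------------------------------------
# associations between scores and annotated variables

@dataclass
class AssociationResult:
    variable: str
    score: str
    kind: str                       # "categorical" or "numeric"
    test_parametric: str
    p_parametric: float
    test_nonparametric: str
    p_nonparametric: float
    group_summaries: pd.DataFrame   # per-level mean/median/n, or coefficients


def _is_numeric(values: pd.Series) -> bool:
    if pd.api.types.is_numeric_dtype(values):
        return True
    coerced = pd.to_numeric(values, errors="coerce")
    return bool(coerced.notna().equals(values.notna()) and values.notna().any())


def associate(scores: pd.Series, variable: pd.Series, *,
              variable_name: str | None = None, score_name: str | None = None,
              equal_var: bool = False) -> AssociationResult:
    """Test the association between a per-sample score and an annotation.

    Both series must be indexed by sample id; samples missing either value
    are dropped. Categorical levels with fewer than 2 samples are dropped
    with a warning.
    """
    variable_name = variable_name or str(variable.name or "variable")
    score_name = score_name or str(scores.name or "score")
    df = pd.concat([scores.rename("score"), variable.rename("var")],
                   axis=1, join="inner").dropna()
    if len(df) < 2:
        raise ValidationError("variable present for fewer than 2 samples")

    if _is_numeric(df["var"]):
        x = pd.to_numeric(df["var"]).to_numpy(float)
        y = df["score"].to_numpy(float)
        r_p, p_p = sps.pearsonr(x, y)
        r_s, p_s = sps.spearmanr(x, y)
        summaries = pd.DataFrame(
            {"coefficient": [r_p, r_s]},
            index=["pearson_r", "spearman_rho"],
        )
        return AssociationResult(variable_name, score_name, "numeric",
                                 "pearson", float(p_p), "spearman", float(p_s),
                                 summaries)

    counts = df["var"].value_counts()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(
            f"dropping level(s) with <2 samples: {sorted(map(str, small))}")
        df = df[~df["var"].isin(small)]
    levels = sorted(df["var"].unique(), key=str)
    if len(levels) < 2:
        raise ValidationError("all samples fall in a single level")
    groups = [df.loc[df["var"] == lv, "score"].to_numpy(float) for lv in levels]
    summaries = pd.DataFrame(
        {
            "n": [len(g) for g in groups],
            "mean": [g.mean() for g in groups],
            "median": [float(np.median(g)) for g in groups],
        },
        index=pd.Index(levels, name=variable_name),
    )
    if len(levels) == 2:
        _, p_p = sps.ttest_ind(groups[0], groups[1], equal_var=equal_var)
        _, p_np = sps.mannwhitneyu(groups[0], groups[1],
                                   alternative="two-sided")
        return AssociationResult(variable_name, score_name, "categorical",
                                 "t_test", float(p_p),
                                 "wilcoxon_rank_sum", float(p_np), summaries)
    _, p_p = sps.f_oneway(*groups)
    _, p_np = sps.kruskal(*groups)
    return AssociationResult(variable_name, score_name, "categorical",
                             "anova", float(p_p), "kruskal_wallis",
                             float(p_np), summaries)


# ---------------------------------------------------------------------------
# multiple-testing correction

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# exact Fisher test on r x c contingency tables

def _log_table_prob(table: np.ndarray, row_sums, col_sums, log_n_fact) -> float:
    return (
        gammaln(np.asarray(row_sums) + 1).sum()
        + gammaln(np.asarray(col_sums) + 1).sum()
        - log_n_fact
        - gammaln(table + 1.0).sum()
    )


def fisher_exact_rxc(table, max_exact_total: int = 200,
                     n_sim: int = 10_000, rng=None) -> float:
    """Two-sided Fisher exact test for an r x c contingency table.

    The p-value sums the conditional (multivariate hypergeometric)
    probabilities of every table with the observed margins whose probability
    does not exceed the observed one. Tables with total count above
    ``max_exact_total`` fall back to a seeded Monte Carlo estimate over
    random tables with fixed margins.
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValidationError("table must be a non-negative 2-D array")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return 1.0
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    total = int(obs.sum())
    log_n_fact = gammaln(total + 1)
    log_p_obs = _log_table_prob(obs, row_sums, col_sums, log_n_fact)

    if total > max_exact_total:
        rng = np.random.default_rng(rng)
        # permutation draw: shuffle column labels against fixed row labels
        rows = np.repeat(np.arange(len(row_sums)), row_sums)
        cols = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(n_sim):
            perm = rng.permutation(cols)
            sim = np.zeros_like(obs)
            np.add.at(sim, (rows, perm), 1)
            if _log_table_prob(sim, row_sums, col_sums, log_n_fact) \
                    <= log_p_obs + 1e-9:
                hits += 1
        return (hits + 1) / (n_sim + 1)

    # exact enumeration over all tables with the observed margins
    r, c = obs.shape
    p_total = 0.0
    log_const = (gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum()
                 - log_n_fact)

    def recurse(row: int, col_rem: np.ndarray, logp_rows: float):
        nonlocal p_total
        if row == r - 1:
            last = col_rem
            logp = log_const + logp_rows - gammaln(last + 1.0).sum()
            if logp <= log_p_obs + 1e-9:
                p_total += math.exp(logp)
            return
        target = row_sums[row]

        def fill(j: int, remaining: int, cells: list[int]):
            if j == c - 1:
                if remaining > col_rem[c - 1]:
                    return
                full = cells + [remaining]
                new_rem = col_rem - np.array(full)
                recurse(row + 1, new_rem,
                        logp_rows - gammaln(np.array(full) + 1.0).sum())
                return
            for v in range(min(int(target) - sum(cells), int(col_rem[j])) + 1):
                fill(j + 1, remaining - v, cells + [v])

        fill(0, int(target), [])

    recurse(0, col_sums.astype(np.int64), 0.0)
    return min(1.0, p_total)


# ---------------------------------------------------------------------------
# differential regions between sample groups

def _ttest_window(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if a.std() == 0 and b.std() == 0:
        # degenerate window: constant in both groups
        return 1.0 if a.mean() == b.mean() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(p) if np.isfinite(p) else 1.0


def compare_regions(profile: ProfileMatrix, groups: pd.Series,
                    mode: str = "t_test", alpha: float = 0.1,
                    adjust: bool = True, equal_var: bool = False,
                    seed: int | None = None) -> pd.DataFrame:
    """Test every genomic window for differential alteration between groups.

    With two groups the result has one row per window; with more, all
    pairwise group comparisons are run and BH adjustment is applied across
    windows within each pair. ``t_test`` mode compares window means (Welch
    by default); ``fisher`` mode tests the groups x {gain,loss,neutral}
    contingency table with the exact Fisher test.
    """
    if mode not in ("t_test", "fisher"):
        raise ValidationError(f"unknown mode {mode!r}")
    labels = groups.reindex(profile.means.index).dropna()
    counts = labels.value_counts()
    keep = counts[counts >= 2].index
    if len(keep) < len(counts):
        warnings.warn("dropping group(s) with fewer than 2 samples")
    labels = labels[labels.isin(keep)]
    if labels.nunique() < 2:
        raise ValidationError("need >= 2 groups with >= 2 samples each")
    states = call_states(profile) if mode == "fisher" else None
    rng = np.random.default_rng(seed)

    results = []
    for ga, gb in itertools.combinations(sorted(labels.unique(), key=str), 2):
        ia = labels.index[labels == ga]
        ib = labels.index[labels == gb]
        pvals = []
        extras = []
        for win in profile.means.columns:
            if mode == "t_test":
                a = profile.means.loc[ia, win].to_numpy(float)
                b = profile.means.loc[ib, win].to_numpy(float)
                pvals.append(_ttest_window(a, b, equal_var))
                extras.append({"mean_a": a.mean(), "mean_b": b.mean()})
            else:
                tab = np.array([
                    [(states.loc[ix, win] == s).sum() for s in STATES]
                    for ix in (ia, ib)
                ])
                pvals.append(fisher_exact_rxc(tab, rng=rng))
                extras.append({
                    f"{grp}_{s}": int(tab[gi, si])
                    for gi, grp in enumerate(("a", "b"))
                    for si, s in enumerate(STATES)
                })
        adj = bh_adjust(pvals) if adjust else np.asarray(pvals)
        for win, p, ap, extra in zip(profile.means.columns, pvals, adj, extras):
            results.append({
                "group_a": ga, "group_b": gb, "window_id": win,
                "test": mode, "p_value": p, "adj_p_value": float(ap),
                "significant": (float(ap) if adjust else p) < alpha,
                **extra,
            })
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# survival

@dataclass
class SurvivalResult:
    curves: dict                 # group -> survival function DataFrame
    logrank_p: float | None
    n_events: pd.Series


def km_logrank(times, events, groups) -> SurvivalResult:
    """Kaplan-Meier curves per group and a log-rank test across groups.

    ``events`` uses 1 for an observed event, 0 for censoring. When a group
    has no events the test is skipped with a warning (curves still returned).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = pd.DataFrame({"time": np.asarray(times, float),
                       "event": np.asarray(events, int),
                       "group": np.asarray(groups)})
    if (df["time"] < 0).any():
        raise ValidationError("survival times must be non-negative")
    curves = {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = kmf.survival_function_
    n_events = df.groupby("group")["event"].sum()
    if (n_events == 0).any() or df["group"].nunique() < 2:
        warnings.warn("log-rank test skipped: a group has no observed events")
        return SurvivalResult(curves, None, n_events)
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return SurvivalResult(curves, float(res.p_value), n_events)


def median_split(values: pd.Series, name: str | None = None) -> pd.Series:
    """Dichotomize a numeric variable at its median (default grouping rule
    for survival on continuous scores)."""
    v = pd.to_numeric(values)
    med = v.median()
    labels = np.where(v <= med, f"<= {med:g}", f"> {med:g}")
    return pd.Series(labels, index=values.index, name=name or values.name)
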