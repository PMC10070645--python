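"""Subgroup profiling: nonparametric test battery, effect sizes, FDR, GLM.

Clusters are characterized on in-model variables (those that entered the
fusion) and out-of-model variables (held-out outcomes used as external
validation). Dispatch follows variable kind:

- numeric: Shapiro-Wilk normality gate per group at alpha = 0.05; if any
  group is non-normal, Mann-Whitney (2 groups; exact p when the smaller
  group has <= 8 subjects and there are no ties, tie-corrected normal
  approximation otherwise) or Kruskal-Wallis (>= 3 groups); if all groups are
  normal, a one-way linear model with Cohen's F.
- 3-level ordinal: extended Cochran-Armitage trend test (permutation p).
- categorical count tables: chi-squared when every cell exceeds 5, Fisher's
  exact test otherwise; Cramér's V either way.

Raw p-values are Benjamini-Hochberg adjusted within the in-model and
out-of-model families separately. The battery can be repeated as a
covariate-adjusted permutation GLM (Freedman-Lane residual permutation of
``outcome ~ group + age + sex``).

Effect sizes: rank-biserial gr = 1 - 2 U1/(n1 n2) for two-group rank tests
(positive when group 1 tends lower), epsilon-squared H/(n-1) for
Kruskal-Wallis, Cohen's F for linear models, Cramér's V for categorical and
trend tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .blocks import FeatureBlock
from .consensus import ClusterAssignment
from .preprocessing import categorize_zero_inflated

__all__ = [
    "ProfileResult",
    "compare_numeric",
    "compare_categorical",
    "trend_test",
    "fdr_adjust",
    "permutation_glm",
    "profile_clusters",
    "results_to_frame",
]


@dataclass
class ProfileResult:
    """One variable's between-cluster comparison."""

    variable: str
    model_status: str  # in_model / out_of_model
    test: str
    statistic: float
    p_raw: float
    q_fdr: float = np.nan
    effect_size: float = np.nan
    effect_family: str = ""
    group_summaries: dict = field(default_factory=dict)
    note: str = ""


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    groups = [values[labels == g] for g in uniq]
    for g, arr in zip(uniq, groups):
        if len(arr) < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
    return uniq, groups


def _numeric_summaries(uniq, groups) -> dict:
    out = {}
    for g, arr in zip(uniq, groups):
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out[int(g)] = {"n": int(len(arr)), "median": float(med), "iqr": float(q3 - q1)}
    return out


def compare_numeric(
    values, labels, normality_alpha: float = 0.05, gate: str = "auto"
) -> ProfileResult:
    """Between-group comparison of one numeric variable (see module docstring).

    ``gate`` controls the normality decision: ``"auto"`` applies the
    Shapiro-Wilk gate per group, ``"nonparametric"`` / ``"parametric"`` force
    the respective path. Groups of fewer than 3 subjects cannot be
    Shapiro-tested and are treated as non-normal (the conservative path).
    """
    if gate not in ("auto", "nonparametric", "parametric"):
        raise ValueError(f"unknown gate {gate!r}")
    uniq, groups = _split_groups(values, labels)
    summaries = _numeric_summaries(uniq, groups)
    grand = np.concatenate(groups)
    if np.ptp(grand) == 0:
        # identical values everywhere: no difference by any test
        if len(groups) == 2:
            n1, n2 = len(groups[0]), len(groups[1])
            return ProfileResult(
                "", "", "mann_whitney_asymptotic", n1 * n2 / 2.0, 1.0,
                effect_size=0.0, effect_family="rank_biserial_gr",
                group_summaries=summaries, note="constant variable",
            )
        return ProfileResult(
            "", "", "kruskal_wallis", 0.0, 1.0,
            effect_size=0.0, effect_family="epsilon_squared",
            group_summaries=summaries, note="constant variable",
        )
    if gate == "auto":
        normal = True
        for arr in groups:
            if len(arr) < 3 or np.ptp(arr) == 0:
                normal = False
                break
            if stats.shapiro(arr).pvalue < normality_alpha:
                normal = False
                break
    else:
        normal = gate == "parametric"

    if normal:
        grand_mean = grand.mean()
        ssb = sum(len(a) * (a.mean() - grand_mean) ** 2 for a in groups)
        ssw = sum(((a - a.mean()) ** 2).sum() for a in groups)
        F = (ssb / (len(groups) - 1)) / (ssw / (len(grand) - len(groups)))
        p = float(stats.f.sf(F, len(groups) - 1, len(grand) - len(groups)))
        eta2 = ssb / (ssb + ssw)
        cohens_f = float(np.sqrt(eta2 / (1 - eta2))) if eta2 < 1 else np.inf
        return ProfileResult(
            "", "", "one_way_linear_model", float(F), p,
            effect_size=cohens_f, effect_family="cohens_f", group_summaries=summaries,
        )
    if len(groups) == 2:
        x, y = groups
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        u1 = float(res.statistic)
        gr = 1.0 - 2.0 * u1 / (len(x) * len(y))  # positive when group 1 tends lower
        return ProfileResult(
            "", "", f"mann_whitney_{method}", u1, float(res.pvalue),
            effect_size=float(gr), effect_family="rank_biserial_gr",
            group_summaries=summaries,
        )
    H, p = stats.kruskal(*groups)
    n = sum(len(a) for a in groups)
    return ProfileResult(
        "", "", "kruskal_wallis", float(H), float(p),
        effect_size=float(H / (n - 1)), effect_family="epsilon_squared",
        group_summaries=summaries,
    )


def _table_log_prob(table, log_fact):
    """Log hypergeometric probability of an r x c table with fixed margins."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    return (
        log_fact[rows].sum() + log_fact[cols].sum()
        - log_fact[n] - log_fact[table].sum()
    )


def _enumerate_tables(rows, cols):
    """All nonnegative integer tables with the given margins (recursive)."""
    r, c = len(rows), len(cols)

    def rec(row_idx, remaining_cols, current):
        if row_idx == r - 1:
            yield current + [list(remaining_cols)]
            return
        target = rows[row_idx]

        def fill(col_idx, left, row_acc):
            if col_idx == c - 1:
                if left <= remaining_cols[col_idx]:
                    yield row_acc + [left]
                return
            hi = min(left, remaining_cols[col_idx])
            for v in range(hi + 1):
                yield from fill(col_idx + 1, left - v, row_acc + [v])

        for row in fill(0, target, []):
            new_remaining = tuple(rc - v for rc, v in zip(remaining_cols, row))
            yield from rec(row_idx + 1, new_remaining, current + [row])

    yield from rec(0, tuple(cols), [])


def compare_categorical(
    counts, max_enumerate: int = 200_000, n_mc: int = 20_000, seed=None
) -> ProfileResult:
    """Chi-squared / Fisher-exact comparison of a 2-d count table.

    Every cell > 5 -> chi-squared without continuity correction; otherwise
    Fisher's exact test (hypergeometric for 2x2, fixed-margin enumeration with
    the probability-ordering two-sided rule for larger tables, Monte-Carlo
    beyond ``max_enumerate`` enumerated tables). Cramér's V is reported for
    both branches from the uncorrected chi-squared statistic.
    """
    table = np.asarray(counts, dtype=np.int64)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-dimensional table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("count table has an empty row or column")
    n = int(table.sum())
    r, c = table.shape
    chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    cramers_v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    summaries = {"table": table.tolist()}

    if (table > 5).all():
        return ProfileResult(
            "", "", "chi_squared", float(chi2), float(chi2_p),
            effect_size=cramers_v, effect_family="cramers_v",
            group_summaries=summaries,
        )

    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return ProfileResult(
            "", "", "fisher_exact", float(chi2), float(p),
            effect_size=cramers_v, effect_family="cramers_v",
            group_summaries=summaries,
        )

    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    log_fact = np.cumsum(np.log(np.arange(1, n + 2)))
    log_fact = np.concatenate([[0.0], log_fact])  # log_fact[k] = log k!
    obs_lp = _table_log_prob(table, log_fact)
    tol = 1e-7
    total_seen = 0
    p_sum = 0.0
    capped = False
    for t in _enumerate_tables(rows.tolist(), cols.tolist()):
        total_seen += 1
        if total_seen > max_enumerate:
            capped = True
            break
        lp = _table_log_prob(np.asarray(t, dtype=np.int64), log_fact)
        if lp <= obs_lp + tol:
            p_sum += np.exp(lp)
    if not capped:
        return ProfileResult(
            "", "", "fisher_exact_rxc", float(chi2), float(min(p_sum, 1.0)),
            effect_size=cramers_v, effect_family="cramers_v",
            group_summaries=summaries,
        )

    # Monte-Carlo fallback: permute column labels of the flattened data
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(r), rows)
    col_labels = np.repeat(np.arange(c), cols)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        t = np.zeros((r, c), dtype=np.int64)
        np.add.at(t, (row_labels, perm), 1)
        if _table_log_prob(t, log_fact) <= obs_lp + tol:
            hits += 1
    p = (1 + hits) / (1 + n_mc)
    mc_err = float(np.sqrt(p * (1 - p) / n_mc))
    return ProfileResult(
        "", "", "fisher_exact_mc", float(chi2), float(p),
        effect_size=cramers_v, effect_family="cramers_v",
        group_summaries=summaries, note=f"monte_carlo_se={mc_err:.2e}",
    )


def _trend_statistic(scores: np.ndarray, labels: np.ndarray, uniq) -> float:
    """Max over groups of the standardized one-vs-rest trend contrast."""
    n = len(scores)
    grand = scores.mean()
    var = scores.var()
    if var == 0:
        return 0.0
    t_max = 0.0
    for g in uniq:
        mask = labels == g
        ng = int(mask.sum())
        se = np.sqrt(var * (n - ng) / (ng * (n - 1)))
        z = abs(scores[mask].mean() - grand) / se
        t_max = max(t_max, z)
    return float(t_max)


def trend_test(
    ordinal_values, labels, n_perm: int = 10_000, seed=None
) -> ProfileResult:
    """Extended Cochran-Armitage trend test of a 3-level ordinal across groups.

    Scores 0/1/2 are compared across unordered groups: the statistic is the
    maximum over groups of the standardized one-vs-rest mean-score contrast
    (for two groups this is the classical Cochran-Armitage trend statistic up
    to sign), and the p-value comes from Monte-Carlo permutation of the group
    labels. The minimum attainable p is 1/(n_perm + 1).
    """
    scores = np.asarray(ordinal_values, dtype=float)
    labels = np.asarray(labels)
    if not np.isin(scores, (0, 1, 2)).all():
        raise ValueError("ordinal values must be in {0, 1, 2}")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    levels = np.unique(scores)
    table = np.zeros((len(uniq), 3), dtype=np.int64)
    for i, g in enumerate(uniq):
        for lvl in (0, 1, 2):
            table[i, lvl] = int(((labels == g) & (scores == lvl)).sum())
    summaries = {int(g): table[i].tolist() for i, g in enumerate(uniq)}
    if len(levels) < 2:
        return ProfileResult(
            "", "", "extended_cochran_armitage", 0.0, 1.0,
            effect_size=0.0, effect_family="cramers_v",
            group_summaries=summaries, note="degenerate: single observed level",
        )

    obs = _trend_statistic(scores, labels, uniq)
    rng = np.random.default_rng(seed)
    # permuting scores against fixed labels is equivalent to permuting labels;
    # vectorized: group mean scores for every permutation at once
    n = len(scores)
    grand = scores.mean()
    var = scores.var()
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    S = scores[perms]  # n_perm x n
    t_perm = np.zeros(n_perm)
    for g in uniq:
        mask = labels == g
        ng = int(mask.sum())
        se = np.sqrt(var * (n - ng) / (ng * (n - 1)))
        z = np.abs(S[:, mask].mean(axis=1) - grand) / se
        np.maximum(t_perm, z, out=t_perm)
    p = (1 + int((t_perm >= obs - 1e-12).sum())) / (1 + n_perm)

    nz = table[:, table.sum(axis=0) > 0]
    chi2 = stats.chi2_contingency(nz, correction=False)[0] if nz.shape[1] > 1 else 0.0
    v = float(np.sqrt(chi2 / (scores.size * (min(nz.shape) - 1)))) if min(nz.shape) > 1 else 0.0
    return ProfileResult(
        "", "", "extended_cochran_armitage", obs, float(p),
        effect_size=v, effect_family="cramers_v", group_summaries=summaries,
        note=f"n_perm={n_perm}",
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def permutation_glm(
    outcome, group_labels, covariates, n_perm: int = 5000, seed=None
) -> ProfileResult:
    """Covariate-adjusted group test by Freedman-Lane residual permutation.

    Fits ``outcome ~ group + covariates`` and tests the group factor's F
    statistic against permutations of the reduced-model (covariates-only)
    residuals added back to the reduced-model fit:
    ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``. Cohen's F is reported
    as sqrt(df1 * F / df2) (from the partial eta-squared of the group factor).
    """
    y = np.asarray(outcome, dtype=float)
    labels = np.asarray(group_labels)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if np.isnan(y).any() or np.isnan(cov).any():
        raise ValueError("missing values in outcome or covariates")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(y)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    dummies = np.column_stack([(labels == g).astype(float) for g in uniq[1:]])
    X_red = np.column_stack([np.ones(n), cov])
    X_full = np.column_stack([X_red, dummies])
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < X_full.shape[1]:
        cols = (
            ["intercept"]
            + [f"covariate_{i}" for i in range(cov.shape[1])]
            + [f"group_{g}" for g in uniq[1:]]
        )
        keep = []
        for j in range(X_full.shape[1]):
            if np.linalg.matrix_rank(X_full[:, keep + [j]]) > len(keep):
                keep.append(j)
        dropped = [cols[j] for j in range(X_full.shape[1]) if j not in keep]
        raise ValueError(f"rank-deficient design; collinear columns: {dropped}")

    def hat(X):
        return X @ np.linalg.solve(X.T @ X, X.T)

    H_red = hat(X_red)
    H_full = hat(X_full)
    df1 = len(uniq) - 1
    df2 = n - X_full.shape[1]
    R_red = np.eye(n) - H_red
    R_full = np.eye(n) - H_full

    def f_stat(Y):
        rss_red = (Y * (R_red @ Y)).sum(axis=0)
        rss_full = (Y * (R_full @ Y)).sum(axis=0)
        return ((rss_red - rss_full) / df1) / (rss_full / df2)

    F_obs = float(f_stat(y[:, None])[0])
    fitted_red = H_red @ y
    resid_red = y - fitted_red
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)  # n_perm independent shuffles
    Yp = fitted_red[:, None] + resid_red[perms].T
    F_perm = f_stat(Yp)
    p = (1 + int((F_perm >= F_obs - 1e-12).sum())) / (1 + n_perm)
    cohens_f = float(np.sqrt(df1 * F_obs / df2))
    summaries = _numeric_summaries(*_split_groups(y, labels))
    return ProfileResult(
        "", "", "permutation_glm", F_obs, float(p),
        effect_size=cohens_f, effect_family="cohens_f",
        group_summaries=summaries, note=f"n_perm={n_perm},freedman_lane",
    )


def profile_clusters(
    assignment,
    in_model_blocks: list[FeatureBlock] | None = None,
    out_of_model: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 5000,
    seed=None,
    fdr_families: str = "separate",
) -> list[ProfileResult]:
    """Run the full test battery over in-model and out-of-model variables.

    Every variable is dispatched by kind (numeric -> normality-gated rank
    test, ordinal3 / zero-inflated count -> trend test). If ``covariates``
    is given, each numeric variable additionally gets a covariate-adjusted
    permutation-GLM row. BH correction is applied within the
    {in_model, out_of_model} x {unadjusted, adjusted} families separately
    (``fdr_families="pooled"`` pools everything). Results are sorted by q.
    """
    if isinstance(assignment, ClusterAssignment):
        labels = assignment.labels
        ids = list(assignment.subject_ids)
    else:
        labels = np.asarray(assignment)
        ids = None
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    seed_iter = iter(ss.spawn(4096))

    results: list[ProfileResult] = []

    def add(res: ProfileResult, variable: str, status: str, adjusted: bool) -> None:
        res.variable = variable
        res.model_status = status
        res.note = (res.note + (";adjusted" if adjusted else "")).strip(";")
        results.append(res)

    def run_numeric(values, name, status):
        add(compare_numeric(values, labels), name, status, False)
        if covariates is not None:
            add(
                permutation_glm(values, labels, covariates.to_numpy(float),
                                n_perm=n_perm, seed=next(seed_iter)),
                name, status, True,
            )

    for block in in_model_blocks or []:
        values = block.values if ids is None else block.values.loc[ids]
        for var, kind in block.kinds.items():
            col = np.asarray(values[var], dtype=float)
            if kind == "numeric":
                run_numeric(col, var, "in_model")
            elif kind in ("ordinal3", "zero_inflated_count"):
                if kind == "zero_inflated_count":
                    col = categorize_zero_inflated(col, var).levels
                add(
                    trend_test(col, labels, n_perm=n_perm, seed=next(seed_iter)),
                    var, "in_model", False,
                )
            else:  # pragma: no cover - blocks validate kinds on construction
                raise ValueError(f"unknown variable kind {kind!r}")

    if out_of_model is not None and len(out_of_model.columns):
        table = out_of_model if ids is None else out_of_model.loc[ids]
        for var in table.columns:
            run_numeric(np.asarray(table[var], dtype=float), var, "out_of_model")

    # BH within families
    if fdr_families == "pooled":
        keys = [("all",) for _ in results]
    else:
        keys = [(r.model_status, "adjusted" in r.note) for r in results]
    for key in set(keys):
        idx = [i for i, k in enumerate(keys) if k == key]
        qs = fdr_adjust([results[i].p_raw for i in idx])
        for i, q in zip(idx, qs):
            results[i].q_fdr = float(q)
    results.sort(key=lambda r: (r.q_fdr, r.p_raw, r.variable))
    return results


def results_to_frame(results: list[ProfileResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable,
                "family": r.model_status,
                "test": r.test,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "q_fdr": r.q_fdr,
                "effect_size": r.effect_size,
                "effect_family": r.effect_family,
                "group_summaries": repr(r.group_summaries),
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)
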