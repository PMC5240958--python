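"""Tests of the three Rasch assumptions.

Local independence
    Conditional on ability, items should be uncorrelated; examined through
    Pearson correlations of the standardized fit residuals, flagging any
    pair above 0.3.

Unidimensionality
    A principal component analysis of the residual correlations splits the
    items into the positively- and negatively-loading subsets on the first
    component.  Person abilities estimated separately on the two subsets
    (with item parameters anchored at the full-scale fit) are compared by
    per-person t-tests; fewer than 5% significant supports a single
    dimension.  A likelihood-ratio (Martin-Löf type) test of the same
    split is provided with both an asymptotic chi-square reference and a
    parametric-bootstrap p-value.

Invariance
    Differential item functioning is probed by a two-way analysis of
    variance of the residuals on person group (e.g. sex, age group) and
    ability class interval, Bonferroni-corrected across items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import InputError, ResponseMatrix
from .pcm import (
    ItemParameters,
    PersonParameters,
    estimate_persons,
    fit_cml,
    _fit_beta,
    _suff_stats,
)
from .residuals import ResidualMatrix

__all__ = [
    "IndependenceReport",
    "DimensionalityReport",
    "DIFTable",
    "residual_correlations",
    "pca_residual_split",
    "subset_person_ttests",
    "martin_lof_test",
    "dif_anova",
]

RESIDUAL_CORR_BOUND = 0.3


@dataclass
class IndependenceReport:
    """Item × item residual correlations and pairs above the 0.3 bound."""

    corr: pd.DataFrame
    flagged_pairs: list
    undefined_pairs: list

    @property
    def passed(self) -> bool:
        return len(self.flagged_pairs) == 0


@dataclass
class DimensionalityReport:
    loadings: pd.Series
    subset_A: list
    subset_B: list
    fallback_median_split: bool
    t_values: np.ndarray | None = None
    pct_significant: float | None = None
    n_tested: int | None = None
    supported: bool | None = None
    martin_lof: dict | None = None


@dataclass
class DIFTable:
    """Per item × grouping ANOVA results with Bonferroni-adjusted flags."""

    table: pd.DataFrame
    alpha: float = 0.05

    def flagged_items(self, grouping=None) -> list:
        t = self.table
        if grouping is not None:
            t = t[t["grouping"] == grouping]
        return sorted(set(t.loc[t["flagged"], "item"]))


def residual_correlations(residuals: ResidualMatrix) -> IndependenceReport:
    """Pairwise Pearson correlations of item residuals.

    Correlations use persons observed on both items; pairs with fewer than
    3 common persons are undefined and reported as such.  Pairs with
    correlation above 0.3 are flagged as local-dependence suspects.
    """
    z = pd.DataFrame(residuals.z, columns=residuals.item_labels)
    corr = z.corr(min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    labels = residuals.item_labels
    flagged, undefined = [], []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            r = corr.iloc[a, b]
            if np.isnan(r):
                undefined.append((labels[a], labels[b]))
            elif r > RESIDUAL_CORR_BOUND:
                flagged.append((labels[a], labels[b], float(r)))
    return IndependenceReport(corr=corr, flagged_pairs=flagged,
                              undefined_pairs=undefined)


def pca_residual_split(residuals: ResidualMatrix) -> DimensionalityReport:
    """Split items by the sign of first-principal-component loadings.

    The PCA runs on the residual correlation matrix.  The sign convention
    puts the largest-magnitude loading in subset A (positive); zero
    loadings join subset A.  When all loadings share one sign the split
    falls back to the loading median and is tagged as such.
    """
    labels = residuals.item_labels
    if len(labels) < 2:
        raise InputError("need at least 2 items to split")
    corr = pd.DataFrame(residuals.z, columns=labels).corr(min_periods=3)
    c = np.nan_to_num(corr.to_numpy(), nan=0.0)
    np.fill_diagonal(c, 1.0)
    evals, evecs = np.linalg.eigh(0.5 * (c + c.T))
    v = evecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    loadings = pd.Series(v, index=labels, name="pc1_loading")
    pos = v >= 0
    fallback = bool(pos.all() or (~pos).all())
    if fallback:
        med = np.median(v)
        pos = v >= med
        if pos.all() or (~pos).all():  # all loadings exactly equal
            pos = np.arange(len(v)) < (len(v) + 1) // 2
    subset_A = [lab for lab, p in zip(labels, pos) if p]
    subset_B = [lab for lab, p in zip(labels, pos) if not p]
    return DimensionalityReport(
        loadings=loadings,
        subset_A=subset_A,
        subset_B=subset_B,
        fallback_median_split=fallback,
    )


def subset_person_ttests(
    responses: ResponseMatrix,
    item_params: ItemParameters,
    subsets,
    alpha: float = 0.05,
    support_bound_pct: float = 5.0,
) -> DimensionalityReport | dict:
    """Per-person comparison of abilities from two item subsets.

    With item parameters anchored at the full-scale fit, each person's
    ability is estimated on subset A and on subset B; the statistic
    ``t = (theta_A - theta_B) / sqrt(SE_A^2 + SE_B^2)`` is referred to the
    standard normal (two-sided).  Persons with an extreme score on either
    subset are excluded.  Unidimensionality is supported when fewer than
    ``support_bound_pct`` percent of the tests are significant.
    """
    subset_A, subset_B = subsets
    if len(subset_A) == 0 or len(subset_B) == 0:
        raise InputError("both subsets must be non-empty")
    labels = responses.item_labels
    idx_A = [labels.index(i) if isinstance(i, str) else int(i) for i in subset_A]
    idx_B = [labels.index(i) if isinstance(i, str) else int(i) for i in subset_B]
    resp_A = responses.subset_items(idx_A)
    resp_B = responses.subset_items(idx_B)
    par_A = item_params.subset(idx_A)
    par_B = item_params.subset(idx_B)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pers_A = estimate_persons(resp_A, par_A)
        pers_B = estimate_persons(resp_B, par_B)
    ok = (
        ~pers_A.extreme_flag
        & ~pers_B.extreme_flag
        & np.isfinite(pers_A.theta)
        & np.isfinite(pers_B.theta)
    )
    n_excluded = int((~ok).sum())
    if n_excluded > 0.5 * responses.n_persons:
        warnings.warn(
            f"subset t-tests exclude {n_excluded} of {responses.n_persons} "
            "persons (extreme on a subset); subsets may be too short",
            stacklevel=2,
        )
    t = (pers_A.theta[ok] - pers_B.theta[ok]) / np.sqrt(
        pers_A.se[ok] ** 2 + pers_B.se[ok] ** 2
    )
    crit = stats.norm.ppf(1 - alpha / 2)
    n_sig = int((np.abs(t) > crit).sum())
    pct = 100.0 * n_sig / t.size if t.size else np.nan
    return {
        "t_values": t,
        "n_tested": int(t.size),
        "n_excluded": n_excluded,
        "n_significant": n_sig,
        "pct_significant": pct,
        "supported": bool(pct < support_bound_pct) if t.size else None,
    }


def _complete_case(responses: ResponseMatrix) -> ResponseMatrix:
    complete = ~responses.missing_mask.any(axis=1)
    return responses.subset_persons(np.flatnonzero(complete))


def _cml_loglik_fit(responses: ResponseMatrix, x0=None, gtol=1e-8):
    """CML fit allowing restricted category supports; returns the raw fit."""
    obs = ~responses.missing_mask
    supports = []
    n_free = 0
    for j in range(responses.n_items):
        s = np.unique(responses.scores[obs[:, j], j])
        if s.size < 2:
            raise InputError(
                f"item {responses.item_labels[j]!r} has fewer than 2 "
                "observed categories in this subset"
            )
        supports.append(s)
        n_free += s.size - 1
    if x0 is not None and x0.size != n_free - 1:
        x0 = None  # support pattern changed; cold start
    return _fit_beta(
        _suff_stats(responses), supports, responses.max_cat, x0=x0, gtol=gtol
    )


def _entropy_term(counts: np.ndarray) -> float:
    """``sum n log(n/N)`` with empty cells dropped (0 log 0 = 0)."""
    n = counts[counts > 0].astype(float)
    N = n.sum()
    return float(np.sum(n * np.log(n / N))) if N > 0 else 0.0


def _martin_lof_statistic(
    responses: ResponseMatrix, idx_A, idx_B, warm=None, gtol=1e-8
):
    warm = warm if warm is not None else {}
    resp_A = responses.subset_items(idx_A)
    resp_B = responses.subset_items(idx_B)
    raw_A = _cml_loglik_fit(resp_A, x0=warm.get("A"), gtol=gtol)
    raw_B = _cml_loglik_fit(resp_B, x0=warm.get("B"), gtol=gtol)
    raw_F = _cml_loglik_fit(responses, x0=warm.get("full"), gtol=gtol)
    warm_out = {"A": raw_A["x"], "B": raw_B["x"], "full": raw_F["x"]}
    ll_A, ll_B, ll_full = raw_A["loglik"], raw_B["loglik"], raw_F["loglik"]
    a = resp_A.raw_scores()
    b = resp_B.raw_scores()
    R_A = int(resp_A.max_cat.sum())
    R_B = int(resp_B.max_cat.sum())
    n_ab = np.zeros((R_A + 1, R_B + 1))
    np.add.at(n_ab, (a, b), 1.0)
    n_r = np.bincount(a + b, minlength=R_A + R_B + 1).astype(float)
    T = 2.0 * (
        ll_A + ll_B + _entropy_term(n_ab.ravel())
        - ll_full - _entropy_term(n_r)
    )
    return T, R_A, R_B, warm_out


def martin_lof_test(
    responses: ResponseMatrix,
    subsets,
    bootstrap: int | None = 200,
    seed: int = 0,
) -> dict:
    """Likelihood-ratio test that two item subsets measure one dimension.

    ``T = 2 [ l_A + l_B + sum_ab n_ab log(n_ab/N) - l_full -
    sum_r n_r log(n_r/N) ]`` compares the factorization through the joint
    subscore distribution against the unidimensional model.  Persons with
    a missing response are dropped listwise (logged in the result).
    ``df = R_A * R_B - 1``; the parametric bootstrap (default B = 200)
    re-simulates complete cohorts at the fitted full-scale parameters and
    abilities, and is the recommended reference at realistic sample sizes.
    """
    subset_A, subset_B = subsets
    labels = responses.item_labels
    idx_A = [labels.index(i) if isinstance(i, str) else int(i) for i in subset_A]
    idx_B = [labels.index(i) if isinstance(i, str) else int(i) for i in subset_B]
    if sorted(idx_A + idx_B) != list(range(responses.n_items)):
        raise InputError("subsets must partition the items")
    cc = _complete_case(responses)
    n_dropped = responses.n_persons - cc.n_persons
    T, R_A, R_B, warm = _martin_lof_statistic(cc, idx_A, idx_B)
    df = R_A * R_B - 1
    p_asym = float(stats.chi2.sf(max(T, 0.0), df))
    result = {
        "statistic": float(T),
        "df": int(df),
        "p_value": p_asym,
        "method": "asymptotic",
        "n_persons": cc.n_persons,
        "n_dropped_incomplete": int(n_dropped),
    }
    if bootstrap:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, _ = fit_cml(cc, on_nonconvergence="warn")
            persons = estimate_persons(cc, params)
        rng = np.random.default_rng(seed)
        theta = persons.theta
        betas = params.cumulative
        exceed = 0
        used = 0
        for _ in range(bootstrap):
            sim = _simulate_at(theta, betas, cc, rng)
            try:
                T_b, _, _, _ = _martin_lof_statistic(
                    sim, idx_A, idx_B, warm=warm, gtol=1e-5
                )
            except InputError:
                continue  # degenerate bootstrap draw
            used += 1
            if T_b >= T:
                exceed += 1
        p_boot = (1.0 + exceed) / (used + 1.0) if used else np.nan
        result.update(
            p_value=p_boot,
            p_asymptotic=p_asym,
            method="parametric_bootstrap",
            bootstrap_samples=used,
        )
    return result


def _simulate_at(theta, betas, template: ResponseMatrix, rng):
    """Simulate a complete cohort at given abilities and cumulative betas."""
    n = theta.size
    scores = np.zeros((n, len(betas)), dtype=int)
    for j, beta in enumerate(betas):
        h = np.arange(beta.size, dtype=float)
        logits = h[None, :] * theta[:, None] - beta[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random(n)
        scores[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return ResponseMatrix(
        scores=scores,
        max_cat=template.max_cat.copy(),
        missing_mask=np.zeros_like(scores, dtype=bool),
        person_ids=list(template.person_ids),
        item_labels=list(template.item_labels),
    )


def _two_way_anova(y, g_codes, s_codes):
    """Type-II F tests for a two-way unbalanced layout via model comparison.

    Returns (F_main, p_main, F_int, p_int) for the group main effect and
    the group × stratum interaction, both against the full-model MSE.
    """
    n = y.size
    g_levels = np.unique(g_codes)
    s_levels = np.unique(s_codes)
    Dg = (g_codes[:, None] == g_levels[None, 1:]).astype(float)
    Ds = (s_codes[:, None] == s_levels[None, 1:]).astype(float)
    inter = (Dg[:, :, None] * Ds[:, None, :]).reshape(n, -1)
    one = np.ones((n, 1))

    def sse_rank(X):
        coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ coef
        return float(((y - fitted) ** 2).sum()), rank

    X0 = np.hstack([one, Ds])
    X1 = np.hstack([one, Ds, Dg])
    X2 = np.hstack([one, Ds, Dg, inter])
    sse0, r0 = sse_rank(X0)
    sse1, r1 = sse_rank(X1)
    sse2, r2 = sse_rank(X2)
    df_res = n - r2
    if df_res <= 0:
        return np.nan, np.nan, np.nan, np.nan
    mse = sse2 / df_res
    df_g = r1 - r0
    df_i = r2 - r1
    F_main = ((sse0 - sse1) / df_g) / mse if df_g > 0 else np.nan
    p_main = float(stats.f.sf(F_main, df_g, df_res)) if df_g > 0 else np.nan
    if df_i > 0:
        F_int = ((sse1 - sse2) / df_i) / mse
        p_int = float(stats.f.sf(F_int, df_i, df_res))
    else:
        F_int, p_int = np.nan, np.nan
    return F_main, p_main, F_int, p_int


def dif_anova(
    residuals: ResidualMatrix,
    persons: PersonParameters,
    grouping,
    n_strata: int = 4,
    alpha: float = 0.05,
    grouping_name: str = "group",
) -> DIFTable:
    """Differential item functioning by residual analysis of variance.

    Per item, a two-way ANOVA of the standardized residuals on the person
    group and on ability class intervals (default 4 equal-count strata of
    the ability estimates) yields group main-effect and group × class
    interaction p-values, Bonferroni-corrected across items.  The DIF flag
    rests on the group main effect; a significant interaction is reported
    as non-uniform DIF alongside.  Empty group × stratum cells reduce the
    strata count automatically (logged in the table attrs).
    """
    g_raw = np.asarray(grouping)
    ok_person = np.isfinite(persons.theta) & ~persons.extreme_flag
    ok_person &= ~pd.isna(g_raw)
    levels = np.unique(g_raw[ok_person])
    if levels.size < 2:
        raise InputError("grouping must have at least 2 levels")
    g_codes_all = np.searchsorted(levels, g_raw.astype(levels.dtype))
    theta = persons.theta
    strata_used = max(1, int(n_strata))
    while strata_used >= 1:
        if strata_used == 1:
            s_codes_all = np.zeros(theta.size, dtype=int)
        else:
            qs = np.nanquantile(
                theta[ok_person], np.linspace(0, 1, strata_used + 1)[1:-1]
            )
            s_codes_all = np.searchsorted(qs, theta)
        cells_ok = True
        for gl in range(levels.size):
            for sl in range(strata_used):
                if not np.any(
                    ok_person & (g_codes_all == gl) & (s_codes_all == sl)
                ):
                    cells_ok = False
        if cells_ok:
            break
        strata_used -= 1
    n_items = len(residuals.item_labels)
    rows = []
    for j, lab in enumerate(residuals.item_labels):
        zcol = residuals.z[:, j]
        sel = ok_person & np.isfinite(zcol)
        F_m, p_m, F_i, p_i = _two_way_anova(
            zcol[sel], g_codes_all[sel], s_codes_all[sel]
        )
        p_adj_m = min(1.0, p_m * n_items) if np.isfinite(p_m) else np.nan
        p_adj_i = min(1.0, p_i * n_items) if np.isfinite(p_i) else np.nan
        # DIF is defined by the group main effect; a significant
        # group x class interaction marks non-uniform DIF and is reported
        # separately without driving the item flag
        flagged = bool(np.isfinite(p_adj_m) and p_adj_m < alpha)
        nonuniform = bool(np.isfinite(p_adj_i) and p_adj_i < alpha)
        rows.append(
            {
                "item": lab,
                "grouping": grouping_name,
                "F_main": F_m,
                "p_main": p_m,
                "p_main_bonferroni": p_adj_m,
                "F_interaction": F_i,
                "p_interaction": p_i,
                "p_interaction_bonferroni": p_adj_i,
                "flagged": flagged,
                "nonuniform_flagged": nonuniform,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_strata_requested"] = int(n_strata)
    table.attrs["n_strata_used"] = int(strata_used)
    return DIFTable(table=table, alpha=alpha)
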