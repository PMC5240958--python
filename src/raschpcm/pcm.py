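"""Partial Credit Model: category probabilities, elementary symmetric
functions, conditional likelihood, CML item estimation and ML person
estimation.

Model
-----
For an item with maximum category ``m`` and cumulative step parameters
``beta_0 = 0, beta_1, ..., beta_m`` (``beta_h = sum_{j<=h} delta_j`` over the
Andrich step thresholds ``delta_j``), the probability that a person with
ability ``theta`` (logits) scores ``h`` is

    P(X = h | theta) = exp(h*theta - beta_h) / sum_l exp(l*theta - beta_l).

Item parameters are estimated by conditional maximum likelihood (CML):
conditioning on each person's raw score eliminates ``theta``, leaving a
likelihood whose normalizer is the elementary symmetric function
``gamma_r = sum over response patterns with total r of prod_i exp(-beta_{i,x_i})``.

Identification: the conditional likelihood is invariant to a uniform shift
of all step thresholds; estimates are reported under the mean-zero
normalization (mean of all ``delta_ij`` equals 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data import DegenerateItemError, EstimationError, InputError, ResponseMatrix

__all__ = [
    "ItemParameters",
    "PersonParameters",
    "GammaTable",
    "pcm_category_probs",
    "gamma_functions",
    "conditional_loglik",
    "fit_cml",
    "estimate_persons",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ItemParameters:
    """Per-item Andrich step thresholds ``delta_i1..delta_im_i`` in logits."""

    thresholds: list
    item_labels: list
    normalization: str = "mean_zero"

    def __post_init__(self):
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]

    @property
    def n_items(self) -> int:
        return len(self.thresholds)

    @property
    def max_cat(self) -> np.ndarray:
        return np.array([len(t) for t in self.thresholds], dtype=int)

    @property
    def cumulative(self) -> list:
        """``beta_ih = sum_{j<=h} delta_ij`` with ``beta_i0 = 0``."""
        return [
            np.concatenate([[0.0], np.cumsum(t)]) for t in self.thresholds
        ]

    @property
    def locations(self) -> np.ndarray:
        """Item location ``L_i``: mean of the item's step thresholds."""
        return np.array([t.mean() for t in self.thresholds])

    def subset(self, item_indices) -> "ItemParameters":
        idx = list(item_indices)
        return ItemParameters(
            thresholds=[self.thresholds[i].copy() for i in idx],
            item_labels=[self.item_labels[i] for i in idx],
            normalization="inherited",
        )

    def recenter(self) -> "ItemParameters":
        allv = np.concatenate(self.thresholds)
        shift = allv.mean()
        return ItemParameters(
            thresholds=[t - shift for t in self.thresholds],
            item_labels=list(self.item_labels),
            normalization="mean_zero",
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for lab, t in zip(self.item_labels, self.thresholds):
            for j, d in enumerate(t, start=1):
                rows.append({"item": lab, "step": j, "delta": d})
        return pd.DataFrame(rows)


@dataclass
class PersonParameters:
    """Per-person ability estimates (logits) with standard errors."""

    theta: np.ndarray
    se: np.ndarray
    extreme_flag: np.ndarray
    adjusted_score: np.ndarray
    person_ids: list = field(default_factory=list)

    @property
    def n_persons(self) -> int:
        return len(self.theta)


@dataclass
class GammaTable:
    """Log elementary symmetric values over total scores 0..R."""

    log_gamma: np.ndarray

    @property
    def gamma(self) -> np.ndarray:
        return np.exp(self.log_gamma)


# ---------------------------------------------------------------------------
# category probabilities
# ---------------------------------------------------------------------------

def pcm_category_probs(theta, thresholds) -> np.ndarray:
    """PCM category probabilities for one item at ability ``theta``.

    Returns a vector over categories ``0..m``; rows sum to one within 1e-12.
    ``theta`` may be a scalar (returns shape ``(m+1,)``) or a 1-D array
    (returns shape ``(len(theta), m+1)``).
    """
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise InputError("theta must be finite")
    delta = np.asarray(thresholds, dtype=float)
    if delta.ndim != 1 or delta.size < 1:
        raise InputError("thresholds must be a non-empty 1-D vector")
    if not np.all(np.isfinite(delta)):
        raise InputError("thresholds must be finite")
    beta = np.concatenate([[0.0], np.cumsum(delta)])
    h = np.arange(beta.size, dtype=float)
    scalar = th.ndim == 0
    th2 = np.atleast_1d(th)[:, None]
    logits = h[None, :] * th2 - beta[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if scalar else p


def _category_moments(theta, thresholds):
    """E, Var and 4th central moment of the category score at each theta."""
    p = np.atleast_2d(pcm_category_probs(np.atleast_1d(theta), thresholds))
    h = np.arange(p.shape[1], dtype=float)
    e = p @ h
    d = h[None, :] - e[:, None]
    w = np.einsum("ij,ij->i", p, d**2)
    c = np.einsum("ij,ij->i", p, d**4)
    return e, w, c


# ---------------------------------------------------------------------------
# elementary symmetric (gamma) functions
# ---------------------------------------------------------------------------

def _log_gamma_recursion(neg_beta_list) -> np.ndarray:
    """Log-space recursion with log-sum-exp.

    ``neg_beta_list``: per item, the vector ``-beta_ih`` over categories
    0..m_i (``-inf`` allowed for structurally absent categories).
    """
    lg = np.zeros(1)
    for nb in neg_beta_list:
        nb = np.asarray(nb, dtype=float)
        m = nb.size - 1
        old = lg.size
        mat = np.full((m + 1, old + m), -np.inf)
        for h in range(m + 1):
            mat[h, h : h + old] = nb[h] + lg
        with np.errstate(divide="ignore"):
            lg = logsumexp(mat, axis=0)
    return lg


def gamma_functions(item_params: ItemParameters, item_subset=None) -> GammaTable:
    """Elementary symmetric function table for an item set.

    ``item_subset`` selects items by label or index; default is all items.
    ``log_gamma`` has length ``R+1`` where ``R = sum m_i`` over the subset,
    and ``exp(log_gamma[r])`` equals the sum over all response patterns with
    total score ``r`` of ``prod_i exp(-beta_{i,x_i})``.
    """
    if item_subset is None:
        idx = range(item_params.n_items)
    else:
        idx = [
            item_params.item_labels.index(i) if isinstance(i, str) else int(i)
            for i in item_subset
        ]
        if len(list(idx)) == 0:
            raise InputError("item subset must be non-empty")
    cum = item_params.cumulative
    neg = [-cum[i] for i in idx]
    if not neg:
        raise InputError("item subset must be non-empty")
    return GammaTable(log_gamma=_log_gamma_recursion(neg))


# ---------------------------------------------------------------------------
# sufficient statistics and the CML objective
# ---------------------------------------------------------------------------

@dataclass
class _GroupStats:
    """Sufficient statistics for one set of persons sharing an item subset."""

    items: tuple            # indices into the item list
    n_r: np.ndarray         # counts of raw scores 0..R over the subset
    cat_counts: list        # per item in subset: counts over categories 0..m_i
    n_persons: int


def _suff_stats(responses: ResponseMatrix) -> list:
    groups = {}
    obs = ~responses.missing_mask
    for v in range(responses.n_persons):
        key = tuple(np.flatnonzero(obs[v]))
        if key:
            groups.setdefault(key, []).append(v)
    out = []
    for key, members in groups.items():
        idx = np.asarray(key)
        sub = responses.scores[np.asarray(members)][:, idx]
        m = responses.max_cat[idx]
        R = int(m.sum())
        r = sub.sum(axis=1)
        n_r = np.bincount(r, minlength=R + 1).astype(float)
        counts = [
            np.bincount(sub[:, j], minlength=m[j] + 1).astype(float)
            for j in range(idx.size)
        ]
        out.append(_GroupStats(key, n_r, counts, len(members)))
    return out


def _group_eval(eps_list, n_r, want_hessian=False):
    """Per-group contribution to -loglik, expected counts and (optionally)
    the Hessian building blocks.

    ``eps_list``: per item, scaled ``exp(-beta - s_i)`` arrays (max 1);
    the caller owns the log-scale offsets.  Returns ``(sum_r n_r log g_r,
    expected counts list[, P matrices, pair q-tables])`` on the scaled
    table, or ``None`` on underflow.
    """
    K = len(eps_list)
    F = [np.ones(1)]
    for e in eps_list:
        F.append(np.convolve(F[-1], e))
    g = F[K]
    active = n_r > 0
    if np.any(g[active] <= 1e-280):
        return None
    B = [None] * (K + 1)
    B[K] = np.ones(1)
    for i in range(K - 1, -1, -1):
        B[i] = np.convolve(eps_list[i], B[i + 1])
    w = np.where(active, n_r / np.where(g > 1e-280, g, 1.0), 0.0)
    expected = []
    gms = []
    for i, e in enumerate(eps_list):
        gm = np.convolve(F[i], B[i + 1])
        gms.append(gm)
        m = e.size - 1
        Ei = np.empty(m + 1)
        for h in range(m + 1):
            Ei[h] = e[h] * np.dot(gm, w[h : h + gm.size])
        expected.append(Ei)
    term = float(np.dot(n_r[active], np.log(g[active])))
    if not want_hessian:
        return term, expected
    # conditional category probabilities P[i][h, r] = P(X_i = h | total r)
    R = g.size - 1
    ginv = np.where(g > 1e-280, 1.0 / np.where(g > 1e-280, g, 1.0), 0.0)
    P = []
    for i, e in enumerate(eps_list):
        m = e.size - 1
        Pi = np.zeros((m + 1, R + 1))
        gm = gms[i]
        for h in range(m + 1):
            Pi[h, h : h + gm.size] = e[h] * gm
        Pi *= ginv[None, :]
        P.append(Pi)
    # pairwise tables q_ij[s] = sum_r n_r gamma^{(-i,-j)}_{r-s} / gamma_r
    qpair = {}
    for i in range(K):
        mid = F[i]  # product of items before i; item i itself excluded
        for j in range(i + 1, K):
            gmij = np.convolve(mid, B[j + 1])
            q = np.empty(g.size - gmij.size + 1)
            for s in range(q.size):
                q[s] = np.dot(gmij, w[s : s + gmij.size])
            qpair[(i, j)] = q
            mid = np.convolve(mid, eps_list[j])
    return term, expected, P, qpair


def _group_eval_log(neg_beta_list, n_r):
    """Log-space fallback for :func:`_group_eval` (slow, overflow-proof)."""
    K = len(neg_beta_list)
    F = [np.zeros(1)]
    for nb in neg_beta_list:
        F.append(_logconv(F[-1], np.asarray(nb, dtype=float)))
    B = [None] * (K + 1)
    B[K] = np.zeros(1)
    for i in range(K - 1, -1, -1):
        B[i] = _logconv(np.asarray(neg_beta_list[i], dtype=float), B[i + 1])
    lg = F[K]
    active = n_r > 0
    term = float(np.dot(n_r[active], lg[active]))
    expected = []
    for i, nb in enumerate(neg_beta_list):
        gm = _logconv(F[i], B[i + 1])
        m = len(nb) - 1
        Ei = np.zeros(m + 1)
        for h in range(m + 1):
            contrib = nb[h] + gm - lg[h : h + gm.size]
            wpos = n_r[h : h + gm.size] > 0
            if np.any(wpos):
                Ei[h] = float(
                    np.sum(n_r[h : h + gm.size][wpos] * np.exp(contrib[wpos]))
                )
        expected.append(Ei)
    return term, expected


def _logconv(la, lb):
    """Convolution in log space: log of conv(exp(la), exp(lb))."""
    la = np.asarray(la, dtype=float)
    lb = np.asarray(lb, dtype=float)
    p, q = la.size, lb.size
    M = la[:, None] + lb[None, :]
    out = np.full(p + q - 1, -np.inf)
    rows, cols = np.indices((p, q))
    diag = (rows + cols).ravel()
    vals = M.ravel()
    finite = np.isfinite(vals)
    for r in range(p + q - 1):
        sel = vals[(diag == r) & finite]
        if sel.size:
            out[r] = logsumexp(sel)
    return out


class _CMLProblem:
    """Negative conditional log-likelihood and gradient over free betas.

    Parameterization: per item, ``beta`` at each observed category in
    ``supports[i]`` with the lowest observed category fixed at 0 (per-item
    gauge); the first remaining parameter overall is additionally fixed at 0
    (translation gauge) and recovered afterwards by mean-centering.
    """

    def __init__(self, groups, supports, max_cat):
        self.groups = groups
        self.supports = [np.asarray(s, dtype=int) for s in supports]
        self.max_cat = np.asarray(max_cat, dtype=int)
        self.nfree = [s.size - 1 for s in self.supports]
        self.offsets = np.concatenate([[0], np.cumsum(self.nfree)])
        self.total_free = int(self.offsets[-1])
        # total category counts across groups, on the full 0..m_i grid
        k = len(supports)
        self.tot_counts = [np.zeros(self.max_cat[i] + 1) for i in range(k)]
        for gstat in groups:
            for j, i in enumerate(gstat.items):
                self.tot_counts[i] += gstat.cat_counts[j]

    def unpack(self, x):
        """Free vector (length total_free - 1) -> per-item full beta arrays."""
        full = np.concatenate([[0.0], x])
        betas = []
        for i, s in enumerate(self.supports):
            b = np.full(self.max_cat[i] + 1, np.inf)
            b[s[0]] = 0.0
            b[s[1:]] = full[self.offsets[i] : self.offsets[i + 1]]
            betas.append(b)
        return betas

    def value_grad(self, x):
        betas = self.unpack(x)
        f = 0.0
        grad_full = [np.zeros(self.max_cat[i] + 1) for i in range(len(betas))]
        for i, b in enumerate(betas):
            fin = np.isfinite(b)
            f += float(np.dot(self.tot_counts[i][fin], b[fin]))
            grad_full[i][fin] += self.tot_counts[i][fin]
        for gstat in self.groups:
            nb_list, eps_list, scales = [], [], 0.0
            for i in gstat.items:
                nb = -betas[i]
                s = nb[np.isfinite(nb)].max()
                nb_list.append(nb)
                eps_list.append(np.exp(np.clip(nb - s, -745, 50)))
                scales += s
            res = _group_eval(eps_list, gstat.n_r)
            if res is None:
                res = _group_eval_log([nb for nb in nb_list], gstat.n_r)
            term, expected = res
            f += term + scales * float(gstat.n_r.sum())
            for j, i in enumerate(gstat.items):
                grad_full[i] -= expected[j]
        g = np.concatenate(
            [grad_full[i][self.supports[i][1:]] for i in range(len(betas))]
        )
        return f, g[1:]

    def value_grad_hess(self, x):
        """Objective, gradient and exact Hessian of -loglik over free betas.

        The negative conditional log-likelihood is the log-partition of an
        exponential family in -beta, so its Hessian is the summed
        conditional covariance of the category-indicator counts: convex,
        and Newton converges in a handful of steps.
        """
        betas = self.unpack(x)
        k = len(betas)
        full_sizes = [self.max_cat[i] + 1 for i in range(k)]
        foffs = np.concatenate([[0], np.cumsum(full_sizes)])
        ntot = int(foffs[-1])
        f = 0.0
        grad_full = [np.zeros(full_sizes[i]) for i in range(k)]
        H = np.zeros((ntot, ntot))
        for i, b in enumerate(betas):
            fin = np.isfinite(b)
            f += float(np.dot(self.tot_counts[i][fin], b[fin]))
            grad_full[i][fin] += self.tot_counts[i][fin]
        for gstat in self.groups:
            eps_list, scales = [], 0.0
            for i in gstat.items:
                nb = -betas[i]
                s = nb[np.isfinite(nb)].max()
                eps_list.append(np.exp(np.clip(nb - s, -745, 50)))
                scales += s
            res = _group_eval(eps_list, gstat.n_r, want_hessian=True)
            if res is None:
                raise _Underflow()
            term, expected, P, qpair = res
            f += term + scales * float(gstat.n_r.sum())
            n_r = gstat.n_r
            for j_loc, i in enumerate(gstat.items):
                grad_full[i] -= expected[j_loc]
                o = foffs[i]
                m1 = full_sizes[i]
                S = (P[j_loc] * n_r[None, :]) @ P[j_loc].T
                block = np.diag(expected[j_loc]) - S
                H[o : o + m1, o : o + m1] += block
            for (a_loc, b_loc), q in qpair.items():
                ia, ib = gstat.items[a_loc], gstat.items[b_loc]
                ea, eb = eps_list[a_loc], eps_list[b_loc]
                S = (P[a_loc] * n_r[None, :]) @ P[b_loc].T
                cross = ea[:, None] * eb[None, :] * q[
                    np.add.outer(np.arange(ea.size), np.arange(eb.size))
                ] - S
                oa, ob = foffs[ia], foffs[ib]
                H[oa : oa + ea.size, ob : ob + eb.size] += cross
                H[ob : ob + eb.size, oa : oa + ea.size] += cross.T
        free_idx = np.concatenate(
            [foffs[i] + self.supports[i][1:] for i in range(k)]
        )
        g = np.concatenate(
            [grad_full[i][self.supports[i][1:]] for i in range(k)]
        )
        Hf = H[np.ix_(free_idx, free_idx)]
        return f, g[1:], Hf[1:, 1:]


class _Underflow(Exception):
    """Scaled linear-space gamma arithmetic underflowed; use log space."""


def _count_init(prob):
    """Closed-form starting values from marginal category counts.

    Adjacent-category log odds ``log(n_{h-1}/n_h)`` approximate the step
    thresholds; the result is gauge-shifted so the fixed parameter is 0.
    """
    betas = []
    for i, s in enumerate(prob.supports):
        n = prob.tot_counts[i][s] + 0.5
        delta = np.log(n[:-1]) - np.log(n[1:])
        betas.append(np.cumsum(delta))
    shift = betas[0][0] / (prob.supports[0][1] - prob.supports[0][0])
    x = []
    for i, s in enumerate(prob.supports):
        b = betas[i] - (s[1:] - s[0]) * shift
        x.append(b)
    return np.concatenate(x)[1:]


def _fit_beta(groups, supports, max_cat, x0=None, gtol=1e-8, maxiter=200):
    """Maximize the conditional likelihood; returns a raw fit dict.

    Primary solver: damped Newton with the exact Hessian (the objective is
    convex).  Falls back to L-BFGS with the analytic gradient when the
    scaled linear-space gamma arithmetic underflows.
    """
    prob = _CMLProblem(groups, supports, max_cat)
    if prob.total_free < 1:
        raise DegenerateItemError("no free parameters to estimate")
    x = _count_init(prob) if x0 is None else np.asarray(x0, dtype=float)
    nit = 0
    try:
        f, g, H = prob.value_grad_hess(x)
        for _ in range(maxiter):
            gnorm = np.max(np.abs(g)) if g.size else 0.0
            if gnorm <= gtol:
                break
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                ridge = 1e-10 * (np.trace(H) / max(H.shape[0], 1) + 1.0)
                try:
                    step = np.linalg.solve(H + ridge * np.eye(H.shape[0]), -g)
                except np.linalg.LinAlgError:
                    step = -g
            t = 1.0
            armijo = 1e-4 * float(g @ step)
            for _ in range(40):
                try:
                    fn, gn, Hn = prob.value_grad_hess(x + t * step)
                except _Underflow:
                    fn = np.inf
                if fn <= f + t * armijo:
                    x, f, g, H = x + t * step, fn, gn, Hn
                    break
                t *= 0.5
            else:  # no decrease found; treat as converged-as-is
                break
            nit += 1
    except _Underflow:
        fun = prob.value_grad
        for attempt in range(5):
            res = minimize(
                fun,
                x,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
            )
            x = res.x
            nit += res.nit
            f, g = fun(x)
            if np.max(np.abs(g)) <= gtol:
                break
            if attempt >= 1:
                x, f, g, extra = _newton_polish(fun, x, f, g, gtol)
                nit += extra
                if np.max(np.abs(g)) <= gtol:
                    break
    gnorm = float(np.max(np.abs(g))) if g.size else 0.0
    betas = prob.unpack(x)
    n_params = prob.total_free - 1
    return {
        "betas": betas,
        "supports": prob.supports,
        "loglik": -f,
        "grad_norm": gnorm,
        "n_iter": nit,
        "converged": gnorm <= gtol,
        "n_params": n_params,
        "x": x,
    }


def _newton_polish(fun, x, f, g, gtol, max_steps=5):
    """Finite-difference Newton steps on the analytic gradient."""
    n = x.size
    steps = 0
    for _ in range(max_steps):
        if np.max(np.abs(g)) <= gtol:
            break
        H = np.empty((n, n))
        h = 1e-6
        for j in range(n):
            xp = x.copy()
            xp[j] += h
            _, gp = fun(xp)
            H[:, j] = (gp - g) / h
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(n), -g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(20):
            fn, gn = fun(x + t * step)
            if fn <= f + 1e-12:
                x, f, g = x + t * step, fn, gn
                break
            t *= 0.5
        else:
            break
        steps += 1
    return x, f, g, steps


# ---------------------------------------------------------------------------
# public estimation API
# ---------------------------------------------------------------------------

def conditional_loglik(responses: ResponseMatrix, item_params: ItemParameters) -> float:
    """Conditional log-likelihood of the responses at the given parameters.

    Persons with extreme raw scores contribute zero (their pattern is the
    only one compatible with their score); missing responses condition on
    per-person item subsets.  The value does not involve person abilities
    and is invariant to the translation gauge of the thresholds.
    """
    groups = _suff_stats(responses)
    cum = item_params.cumulative
    total = 0.0
    for gstat in groups:
        nb_list = [-cum[i] for i in gstat.items]
        lg = _log_gamma_recursion(nb_list)
        active = gstat.n_r > 0
        total -= float(np.dot(gstat.n_r[active], lg[active]))
        for j, i in enumerate(gstat.items):
            total -= float(np.dot(gstat.cat_counts[j], cum[i]))
    return total


def fit_cml(
    responses: ResponseMatrix,
    gtol: float = 1e-8,
    maxiter: int = 500,
    on_nonconvergence: str = "raise",
):
    """Estimate PCM step thresholds by conditional maximum likelihood.

    Returns ``(ItemParameters, metadata)`` where metadata reports
    convergence status, iteration count, final gradient norm and the
    maximized conditional log-likelihood.  Estimates are reported under the
    mean-zero normalization of all step thresholds.

    Raises :class:`DegenerateItemError` for items with fewer than two
    observed categories, and :class:`EstimationError` (carrying the last
    iterate) on non-convergence when ``on_nonconvergence='raise'``.
    """
    obs = ~responses.missing_mask
    supports = []
    for j in range(responses.n_items):
        s = np.unique(responses.scores[obs[:, j], j])
        if s.size < 2:
            raise DegenerateItemError(
                f"item {responses.item_labels[j]!r} has fewer than 2 "
                "observed categories"
            )
        if s.size != responses.max_cat[j] + 1:
            raise InputError(
                f"item {responses.item_labels[j]!r} has unobserved "
                "categories; run validate_responses to recode first"
            )
        supports.append(s)
    groups = _suff_stats(responses)
    raw = _fit_beta(groups, supports, responses.max_cat, gtol=gtol, maxiter=maxiter)
    if not raw["converged"]:
        msg = (
            f"CML did not reach gradient norm {gtol:g} "
            f"(final {raw['grad_norm']:.2e} after {raw['n_iter']} iterations)"
        )
        if on_nonconvergence == "raise":
            raise EstimationError(msg, last_iterate=raw)
        warnings.warn(msg, stacklevel=2)
    thresholds = [np.diff(b) for b in raw["betas"]]
    params = ItemParameters(
        thresholds=thresholds, item_labels=list(responses.item_labels)
    ).recenter()
    meta = {
        "converged": raw["converged"],
        "n_iter": raw["n_iter"],
        "grad_norm": raw["grad_norm"],
        "loglik": raw["loglik"],
        "n_params": raw["n_params"],
    }
    return params, meta


def _solve_theta(deltas, r_target, lo=-30.0, hi=30.0, tol=1e-10, maxit=200):
    """Solve sum_i E[X_i | theta] = r_target by safeguarded Newton."""
    theta = 0.0
    for _ in range(maxit):
        e = w = 0.0
        for d in deltas:
            ei, wi, _ = _category_moments(theta, d)
            e += ei[0]
            w += wi[0]
        diff = e - r_target
        if abs(diff) < tol:
            break
        if diff > 0:
            hi = min(hi, theta)
        else:
            lo = max(lo, theta)
        step = diff / max(w, 1e-12)
        cand = theta - step
        if not (lo < cand < hi):
            cand = 0.5 * (lo + hi)
        theta = cand
    return theta


def estimate_persons(
    responses: ResponseMatrix,
    item_params: ItemParameters,
    extreme_adjust: float = 0.3,
) -> PersonParameters:
    """Maximum-likelihood person abilities given fitted item parameters.

    Per person, ``theta`` solves ``r_v = sum_i E[X_vi | theta]`` over the
    answered items (a monotone 1-D root find); ``SE = (sum_i Var)^{-1/2}``
    evaluated at the solution.  Extreme raw scores (0 or the maximum) are
    pulled ``extreme_adjust`` score points toward the interior before
    solving and flagged.  Persons answering zero items are excluded with a
    warning (NaN estimates).
    """
    n = responses.n_persons
    theta = np.full(n, np.nan)
    se = np.full(n, np.nan)
    extreme = responses.extreme_mask()
    r = responses.raw_scores().astype(float)
    rmax = responses.max_scores().astype(float)
    adjusted = r.copy()
    adjusted[extreme & (r == 0)] = extreme_adjust
    top = extreme & (r == rmax) & (rmax > 0)
    adjusted[top] = rmax[top] - extreme_adjust
    answered = responses.n_answered()
    if np.any(answered == 0):
        warnings.warn(
            f"{int((answered == 0).sum())} person(s) answered zero items; "
            "excluded from ability estimation",
            stacklevel=2,
        )
    obs = ~responses.missing_mask
    cache = {}
    for v in range(n):
        if answered[v] == 0:
            continue
        key = (tuple(np.flatnonzero(obs[v])), float(adjusted[v]))
        if key not in cache:
            deltas = [item_params.thresholds[i] for i in key[0]]
            th = _solve_theta(deltas, key[1])
            wsum = 0.0
            for d in deltas:
                _, wi, _ = _category_moments(th, d)
                wsum += wi[0]
            cache[key] = (th, 1.0 / np.sqrt(max(wsum, 1e-300)))
        theta[v], se[v] = cache[key]
    return PersonParameters(
        theta=theta,
        se=se,
        extreme_flag=extreme,
        adjusted_score=adjusted,
        person_ids=list(responses.person_ids),
    )
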