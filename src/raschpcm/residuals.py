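"""Standardized residuals, item/person fit statistics, person-fit QC and
the Person Separation Index.

Residuals are ``z_vi = (x_vi - E_vi) / sqrt(W_vi)`` with conditional
moments evaluated at the person's estimated ability; under the model their
per-item distribution is expected to be approximately standard normal.
Mean-square fit statistics follow the usual Rasch conventions: outfit is
the unweighted mean of ``z^2``, infit the information-weighted analogue,
and both are standardized to t statistics by the Wilson-Hilferty cube-root
transformation.  Mean-squares above 1.3 (or t > 2) flag underfit, below
0.7 (or t < -2) overfit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ResponseMatrix
from .pcm import ItemParameters, PersonParameters, pcm_category_probs

__all__ = [
    "ResidualMatrix",
    "FitReport",
    "standardized_residuals",
    "item_fit",
    "person_fit",
    "person_qc_filter",
    "person_separation_index",
]

MSQ_UNDERFIT = 1.3
MSQ_OVERFIT = 0.7
T_BOUND = 2.0
PSI_ACCEPTABLE = 0.7


@dataclass
class ResidualMatrix:
    """Persons × items standardized residuals with conditional moments.

    ``z`` is NaN where an item was not administered and for persons with
    extreme raw scores (their residuals are identically zero by
    construction and carry no fit information).
    """

    z: np.ndarray
    expected: np.ndarray
    variance: np.ndarray
    kurtosis: np.ndarray     # 4th central conditional moment C_vi
    observed: np.ndarray     # x as float, NaN where missing/excluded
    person_ids: list
    item_labels: list


@dataclass
class FitReport:
    """Residual-based fit statistics per unit (items or persons)."""

    table: pd.DataFrame
    unit: str = "item"       # "item" or "person"

    def __getitem__(self, col):
        return self.table[col]


def standardized_residuals(
    responses: ResponseMatrix,
    item_params: ItemParameters,
    persons: PersonParameters,
) -> ResidualMatrix:
    """Compute standardized response residuals at the ability estimates.

    Extreme-flagged persons are excluded (all-NaN rows), as are cells where
    the item was not administered.
    """
    n, k = responses.scores.shape
    E = np.full((n, k), np.nan)
    W = np.full((n, k), np.nan)
    C = np.full((n, k), np.nan)
    include = ~persons.extreme_flag & np.isfinite(persons.theta)
    th = persons.theta[include]
    for j in range(k):
        delta = item_params.thresholds[j]
        p = pcm_category_probs(th, delta)
        h = np.arange(p.shape[1], dtype=float)
        e = p @ h
        d = h[None, :] - e[:, None]
        E[include, j] = e
        W[include, j] = np.einsum("ij,ij->i", p, d**2)
        C[include, j] = np.einsum("ij,ij->i", p, d**4)
    x = np.where(responses.missing_mask, np.nan, responses.scores).astype(float)
    x[~include] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - E) / np.sqrt(W)
    E[np.isnan(x)] = np.nan
    W[np.isnan(x)] = np.nan
    C[np.isnan(x)] = np.nan
    return ResidualMatrix(
        z=z,
        expected=E,
        variance=W,
        kurtosis=C,
        observed=x,
        person_ids=list(responses.person_ids),
        item_labels=list(responses.item_labels),
    )


def _msq_t(msq, q2):
    """Wilson-Hilferty standardization of a mean-square statistic."""
    q2 = max(q2, 1e-12)
    q = np.sqrt(q2)
    return (np.cbrt(max(msq, 0.0)) - 1.0) * (3.0 / q) + q / 3.0


def _fit_stats_1d(z, x, e, w, c):
    """Fit statistics for one unit from its non-missing residual entries."""
    ok = np.isfinite(z)
    N = int(ok.sum())
    if N < 2:
        return None
    z, x, e, w, c = z[ok], x[ok], e[ok], w[ok], c[ok]
    z2 = z**2
    chisq = float(z2.sum())
    df = N - 1
    p = float(stats.chi2.sf(chisq, df))
    outfit = float(z2.mean())
    sw = float(w.sum())
    infit = float(((x - e) ** 2).sum() / sw)
    # moment-based variances of the mean squares (Wright-Masters forms)
    q2_out = float((c / w**2).sum() / N**2 - 1.0 / N)
    q2_in = float(((c - w**2).sum()) / sw**2)
    return {
        "n": N,
        "residual_mean": float(z.mean()),
        "residual_sd": float(z.std(ddof=1)),
        "chisq": chisq,
        "df": df,
        "p_value": p,
        "outfit_msq": outfit,
        "infit_msq": infit,
        "outfit_t": _msq_t(outfit, q2_out),
        "infit_t": _msq_t(infit, q2_in),
    }


def _classify(row):
    under = (
        row["outfit_msq"] > MSQ_UNDERFIT
        or row["infit_msq"] > MSQ_UNDERFIT
        or row["outfit_t"] > T_BOUND
        or row["infit_t"] > T_BOUND
    )
    over = (
        row["outfit_msq"] < MSQ_OVERFIT
        or row["infit_msq"] < MSQ_OVERFIT
        or row["outfit_t"] < -T_BOUND
        or row["infit_t"] < -T_BOUND
    )
    return under, over


def item_fit(residuals: ResidualMatrix) -> FitReport:
    """Per-item chi-square, infit/outfit mean squares and t statistics.

    Items with fewer than two contributing persons are reported with NaN
    statistics.  The chi-square sums squared residuals over persons with
    ``df = N_i - 1``; t statistics use the cube-root standardization with
    moment variances from the conditional kurtosis.
    """
    rows = []
    for j, lab in enumerate(residuals.item_labels):
        st = _fit_stats_1d(
            residuals.z[:, j],
            residuals.observed[:, j],
            residuals.expected[:, j],
            residuals.variance[:, j],
            residuals.kurtosis[:, j],
        )
        if st is None:
            st = {
                k: np.nan
                for k in (
                    "n", "residual_mean", "residual_sd", "chisq", "df",
                    "p_value", "outfit_msq", "infit_msq", "outfit_t", "infit_t",
                )
            }
            st["underfit"] = st["overfit"] = False
            st["defined"] = False
        else:
            under, over = _classify(st)
            st["underfit"], st["overfit"], st["defined"] = under, over, True
        st["item"] = lab
        rows.append(st)
    table = pd.DataFrame(rows).set_index("item")
    return FitReport(table=table, unit="item")


def person_fit(residuals: ResidualMatrix) -> FitReport:
    """Per-person fit: ``chisq_v = sum_i z^2`` with ``df = k_v - 1``."""
    rows = []
    for v, pid in enumerate(residuals.person_ids):
        st = _fit_stats_1d(
            residuals.z[v],
            residuals.observed[v],
            residuals.expected[v],
            residuals.variance[v],
            residuals.kurtosis[v],
        )
        if st is None:
            st = {
                k: np.nan
                for k in (
                    "n", "residual_mean", "residual_sd", "chisq", "df",
                    "p_value", "outfit_msq", "infit_msq", "outfit_t", "infit_t",
                )
            }
            st["defined"] = False
        else:
            st["defined"] = True
        st["person"] = pid
        rows.append(st)
    table = pd.DataFrame(rows).set_index("person")
    return FitReport(table=table, unit="person")


def person_qc_filter(
    responses: ResponseMatrix,
    fit: FitReport,
    alpha: float = 0.05,
):
    """Remove persons whose person-fit chi-square is significant.

    Returns ``(filtered ResponseMatrix, exclusion log DataFrame)``.  The
    log lists person id, chi-square and p-value, and its attrs record the
    exclusion rate in percent.  Persons without defined fit statistics
    (extreme scorers) are retained.  Removing more than half the sample
    triggers a hard warning; the run continues.
    """
    if fit.unit != "person":
        raise ValueError("person_qc_filter needs a person FitReport")
    p = fit.table["p_value"].to_numpy()
    ids = list(fit.table.index)
    if ids != list(responses.person_ids):
        raise ValueError("fit report and responses are not person-aligned")
    significant = np.isfinite(p) & (p < alpha)
    keep = np.flatnonzero(~significant)
    log = fit.table.loc[significant, ["chisq", "df", "p_value"]].copy()
    rate = 100.0 * significant.sum() / len(ids) if ids else 0.0
    log.attrs["n_excluded"] = int(significant.sum())
    log.attrs["n_total"] = len(ids)
    log.attrs["rate_percent"] = round(rate, 1)
    if significant.sum() > 0.5 * len(ids):
        warnings.warn(
            f"person QC removed {significant.sum()} of {len(ids)} persons "
            "(> 50%); results are likely unreliable",
            stacklevel=2,
        )
    return responses.subset_persons(keep), log


def person_separation_index(persons: PersonParameters) -> dict:
    """Person Separation Index: true variance over total variance.

    ``PSI = (V - M) / V`` with ``V`` the variance of the ability estimates
    over non-extreme persons and ``M`` the mean squared standard error;
    clipped at 0 from below.  Values above 0.7 are conventionally
    acceptable.  Returns a dict with ``psi``, ``acceptable``, ``n``, and
    ``defined`` (False when V = 0 or fewer than 2 usable persons).
    """
    ok = ~persons.extreme_flag & np.isfinite(persons.theta)
    th = persons.theta[ok]
    s = persons.se[ok]
    if th.size < 2:
        return {"psi": np.nan, "acceptable": False, "n": int(th.size),
                "defined": False}
    V = float(th.var(ddof=1))
    M = float((s**2).mean())
    if V <= 0:
        return {"psi": np.nan, "acceptable": False, "n": int(th.size),
                "defined": False}
    psi = max(0.0, (V - M) / V)
    return {
        "psi": psi,
        "acceptable": bool(psi > PSI_ACCEPTABLE),
        "n": int(th.size),
        "defined": True,
    }
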