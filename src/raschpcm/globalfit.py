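"""Andersen's conditional likelihood-ratio test of overall model fit.

Persons are split into score-level subgroups; if the model holds, item
parameters estimated within each subgroup agree with those estimated on
the pooled sample, and

    LR = 2 ( sum_g log L_C(g)  -  log L_C )

is asymptotically chi-square with degrees of freedom equal to the number
of parameters estimated in the score groups minus the number estimated in
the complete sample.  A non-significant p-value indicates goodness of fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import DegenerateItemError, EstimationError, InputError, ResponseMatrix
from .pcm import _fit_beta, _suff_stats

__all__ = ["AndersenResult", "andersen_lr_test"]

SMALL_GROUP = 30


@dataclass
class AndersenResult:
    statistic: float
    df: int
    p_value: float
    group_spec: str
    group_logliks: list
    pooled_loglik: float
    group_sizes: list

    @property
    def goodness_of_fit(self) -> bool:
        """True when the test does not reject at the 5% level."""
        return bool(self.p_value >= 0.05)


def _restricted_fit(responses: ResponseMatrix, what: str):
    """CML fit with category support restricted to what the group observed.

    Categories never observed in a subgroup sit at the boundary of the
    parameter space (their step parameter diverges); the supremum of the
    group likelihood equals the support-restricted fit, and the divergent
    parameters are excluded from the degrees-of-freedom count.
    """
    obs = ~responses.missing_mask
    supports = []
    for j in range(responses.n_items):
        s = np.unique(responses.scores[obs[:, j], j])
        if s.size < 2:
            raise DegenerateItemError(
                f"item {responses.item_labels[j]!r} has fewer than 2 observed "
                f"categories in {what}; use a coarser score split"
            )
        supports.append(s)
    try:
        raw = _fit_beta(_suff_stats(responses), supports, responses.max_cat)
    except Exception as exc:
        raise EstimationError(f"estimation failed in {what}: {exc}") from exc
    return raw["loglik"], raw["n_params"]


def andersen_lr_test(
    responses: ResponseMatrix,
    n_groups: int = 2,
    split_rule: str = "median",
) -> AndersenResult:
    """Andersen likelihood-ratio test over raw-score subgroups.

    The default split is G = 2 at the median raw score (scores at or below
    the median go to the low group); ``split_rule`` may be ``"median"``,
    ``"mean"`` or ``"quantile"`` (equal-count groups for ``n_groups`` > 2).
    Persons with extreme raw scores carry no conditional information and
    are excluded from the groups.  Groups smaller than 30 persons trigger
    an asymptotics warning.
    """
    if n_groups < 2:
        raise InputError("need at least 2 score groups")
    extreme = responses.extreme_mask()
    keep = np.flatnonzero(~extreme)
    if keep.size < 2 * n_groups:
        raise InputError("too few non-extreme persons for a split")
    work = responses.subset_persons(keep)
    r = work.raw_scores()
    if split_rule == "median" and n_groups == 2:
        cut = np.median(r)
        codes = (r > cut).astype(int)
        spec = f"G=2 at median raw score {cut:g} (ties to the lower group)"
    elif split_rule == "mean" and n_groups == 2:
        cut = r.mean()
        codes = (r > cut).astype(int)
        spec = f"G=2 at mean raw score {cut:.2f}"
    else:
        qs = np.quantile(r, np.linspace(0, 1, n_groups + 1)[1:-1])
        codes = np.searchsorted(qs, r, side="left")
        spec = f"G={n_groups} equal-count raw-score groups"
    sizes, logliks, n_params_groups = [], [], []
    for g in range(codes.max() + 1):
        members = np.flatnonzero(codes == g)
        if members.size == 0:
            continue
        if members.size < SMALL_GROUP:
            warnings.warn(
                f"score group {g + 1} has only {members.size} persons; "
                "asymptotic reference doubtful",
                stacklevel=2,
            )
        sub = work.subset_persons(members)
        ll, k = _restricted_fit(sub, f"score group {g + 1}")
        sizes.append(int(members.size))
        logliks.append(ll)
        n_params_groups.append(k)
    ll_pool, k_pool = _restricted_fit(work, "the pooled sample")
    statistic = 2.0 * (sum(logliks) - ll_pool)
    df = int(sum(n_params_groups) - k_pool)
    p = float(stats.chi2.sf(max(statistic, 0.0), df))
    return AndersenResult(
        statistic=float(statistic),
        df=df,
        p_value=p,
        group_spec=spec,
        group_logliks=[float(v) for v in logliks],
        pooled_loglik=float(ll_pool),
        group_sizes=sizes,
    )
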