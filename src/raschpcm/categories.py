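"""Threshold ordering, category curves, category collapsing and the
person-item (Wright) map.

Two threshold notions coexist for polytomous Rasch items.  The Andrich
step thresholds ``delta_ij`` are the abilities at which adjacent
categories are equally probable; nothing forces them to be increasing,
and a non-increasing run ("disorder") signals categories that never
become modal.  The Thurstonian thresholds — where the cumulative
probability of scoring at least ``j`` reaches 0.5 — are strictly ordered
by construction and therefore cannot express disorder; the disorder flag
rests on the Andrich sequence, and both kinds are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import InputError, ResponseMatrix
from .pcm import ItemParameters, PersonParameters, pcm_category_probs

__all__ = [
    "ThresholdProfile",
    "CollapseMap",
    "PersonItemMap",
    "threshold_profile",
    "category_curves",
    "collapse_categories",
    "build_person_item_map",
    "category_frequency_ratios",
]

UNDER_SELECT_RATIO = 0.5
OVER_SELECT_RATIO = 1.5


@dataclass
class ThresholdProfile:
    andrich: list            # per item, delta_ij
    thurstonian: list        # per item, ordered cumulative-0.5 thresholds
    disordered: np.ndarray   # bool per item
    disorder_detail: dict    # item label -> list of offending (j, j+1) pairs
    item_labels: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, lab in enumerate(self.item_labels):
            for j, (a, t) in enumerate(
                zip(self.andrich[i], self.thurstonian[i]), start=1
            ):
                rows.append(
                    {
                        "item": lab,
                        "step": j,
                        "andrich": a,
                        "thurstonian": t,
                        "item_disordered": bool(self.disordered[i]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CollapseMap:
    """Per item, an order-preserving surjection old category → new category."""

    maps: dict               # item label -> {old: new}

    def validate(self, max_cat: dict) -> None:
        for lab, m in self.maps.items():
            if lab not in max_cat:
                raise InputError(f"collapse map references unknown item {lab!r}")
            old = sorted(m)
            if old != list(range(max_cat[lab] + 1)):
                raise InputError(
                    f"collapse map for {lab!r} must cover categories "
                    f"0..{max_cat[lab]} without gaps"
                )
            new = [m[o] for o in old]
            if new[0] != 0 or any(b - a not in (0, 1) for a, b in zip(new, new[1:])):
                raise InputError(
                    f"collapse map for {lab!r} must be monotone onto "
                    "consecutive codes starting at 0"
                )
            if max(new) < 1:
                raise InputError(
                    f"collapse map for {lab!r} leaves a single category"
                )


@dataclass
class PersonItemMap:
    person_bins: np.ndarray      # histogram bin edges (logits)
    person_counts: np.ndarray
    items: pd.DataFrame          # label, location, disordered — sorted
    thresholds: pd.DataFrame     # label, step, location
    zero_line: float = 0.0


def threshold_profile(item_params: ItemParameters, tol: float = 1e-10) -> ThresholdProfile:
    """Andrich ordering check plus Thurstonian thresholds by bisection.

    An item is disordered when its Andrich step thresholds are not
    strictly increasing; the offending adjacent step pairs are listed.
    Thurstonian thresholds solve ``P(X >= j | theta) = 0.5`` to ``tol``.
    """
    andrich, thurst, disordered = [], [], []
    detail = {}
    for lab, delta in zip(item_params.item_labels, item_params.thresholds):
        andrich.append(np.asarray(delta, dtype=float))
        bad = [
            (j, j + 1)
            for j in range(1, delta.size)
            if delta[j] <= delta[j - 1]
        ]
        disordered.append(bool(bad))
        if bad:
            detail[lab] = bad
        ts = []
        for j in range(1, delta.size + 1):
            def cum(th, j=j, d=delta):
                p = pcm_category_probs(th, d)
                return p[j:].sum() - 0.5

            lo, hi = -50.0, 50.0
            ts.append(brentq(cum, lo, hi, xtol=tol))
        thurst.append(np.asarray(ts))
    return ThresholdProfile(
        andrich=andrich,
        thurstonian=thurst,
        disordered=np.asarray(disordered, dtype=bool),
        disorder_detail=detail,
        item_labels=list(item_params.item_labels),
    )


def category_curves(item_params: ItemParameters, theta_grid) -> dict:
    """Category characteristic curves on an ability grid.

    Returns per item a ``(len(grid), m_i + 1)`` probability matrix; each
    row sums to 1.
    """
    grid = np.asarray(theta_grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise InputError("theta grid must be finite")
    return {
        lab: pcm_category_probs(grid, delta)
        for lab, delta in zip(item_params.item_labels, item_params.thresholds)
    }


def collapse_categories(
    responses: ResponseMatrix, cmap: CollapseMap
) -> ResponseMatrix:
    """Recode response categories by an order-preserving collapse map.

    Items not named in the map are left untouched; the map must be
    monotone, gap-free and onto consecutive codes (``InputError``
    otherwise).
    """
    cmap.validate(
        {lab: int(m) for lab, m in zip(responses.item_labels, responses.max_cat)}
    )
    scores = responses.scores.copy()
    max_cat = responses.max_cat.copy()
    for j, lab in enumerate(responses.item_labels):
        if lab not in cmap.maps:
            continue
        m = cmap.maps[lab]
        lut = np.array([m[o] for o in range(responses.max_cat[j] + 1)])
        obs = ~responses.missing_mask[:, j]
        scores[obs, j] = lut[scores[obs, j]]
        max_cat[j] = lut.max()
    return ResponseMatrix(
        scores=scores,
        max_cat=max_cat,
        missing_mask=responses.missing_mask.copy(),
        person_ids=list(responses.person_ids),
        item_labels=list(responses.item_labels),
        covariates=responses.covariates,
        recode_maps={**responses.recode_maps},
    )


def build_person_item_map(
    persons: PersonParameters,
    profile: ThresholdProfile,
    item_params: ItemParameters,
    bin_width: float = 0.25,
) -> PersonItemMap:
    """Assemble Wright-map data: person histogram, item and threshold
    locations, disorder flags and the zero line (no rendering).

    Items with equal locations are ordered stably by label.
    """
    theta = persons.theta[np.isfinite(persons.theta)]
    if theta.size:
        lo = np.floor(theta.min() / bin_width) * bin_width
        hi = np.ceil(theta.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        if edges.size < 2:
            edges = np.array([lo, lo + bin_width])
        counts, edges = np.histogram(theta, bins=edges)
    else:
        edges = np.array([0.0, bin_width])
        counts = np.zeros(1, dtype=int)
    items = pd.DataFrame(
        {
            "item": item_params.item_labels,
            "location": item_params.locations,
            "disordered": profile.disordered,
        }
    ).sort_values(["location", "item"], kind="stable").reset_index(drop=True)
    thr_rows = []
    for lab, delta in zip(item_params.item_labels, item_params.thresholds):
        for j, d in enumerate(delta, start=1):
            thr_rows.append({"item": lab, "step": j, "location": float(d)})
    return PersonItemMap(
        person_bins=edges,
        person_counts=counts,
        items=items,
        thresholds=pd.DataFrame(thr_rows),
        zero_line=0.0,
    )


def category_frequency_ratios(
    responses: ResponseMatrix,
    item_params: ItemParameters,
    persons: PersonParameters,
) -> pd.DataFrame:
    """Observed vs expected category frequencies per item.

    Expected frequencies average the model category probabilities over
    the estimated ability distribution.  A ratio below 0.5 marks a
    category as under-selected, above 1.5 as over-selected.
    """
    ok = np.isfinite(persons.theta)
    th = persons.theta[ok]
    rows = []
    for j, lab in enumerate(responses.item_labels):
        obs_sel = ~responses.missing_mask[:, j] & ok
        x = responses.scores[obs_sel, j]
        m = responses.max_cat[j]
        obs = np.bincount(x, minlength=m + 1) / max(x.size, 1)
        p = pcm_category_probs(th, item_params.thresholds[j])
        exp = p.mean(axis=0)
        for h in range(m + 1):
            ratio = obs[h] / exp[h] if exp[h] > 0 else np.nan
            rows.append(
                {
                    "item": lab,
                    "category": h,
                    "observed_freq": obs[h],
                    "expected_freq": exp[h],
                    "ratio": ratio,
                    "under_selected": bool(ratio < UNDER_SELECT_RATIO)
                    if np.isfinite(ratio) else False,
                    "over_selected": bool(ratio > OVER_SELECT_RATIO)
                    if np.isfinite(ratio) else False,
                }
            )
    return pd.DataFrame(rows)
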