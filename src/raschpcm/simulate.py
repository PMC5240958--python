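"""Synthetic cohorts with the statistical structure of a 9-item, 5-category
ordinal severity scale — and controlled violations of it.

The default fixture mirrors a CMTNS-like instrument: 9 items scored 0-4
whose locations span roughly 2.3 logits, administered to a cohort mixing
mild, moderate and severe patients.  Optional violations inject
differential item functioning (a group-specific threshold shift), a second
latent dimension (correlated trait pair routed to item subsets),
non-uniform discrimination (generalized-PCM slopes) and threshold disorder
(swapped adjacent steps), so each diagnostic in the package can be tested
for both calibration and power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import InputError, ResponseMatrix
from .pcm import ItemParameters, fit_cml

__all__ = [
    "SimulationConfig",
    "make_cmtns_like_items",
    "simulate_responses",
    "targeting_precision_experiment",
    "CMTNS_ITEM_LABELS",
    "CMTNS_LOCATIONS",
]

CMTNS_ITEM_LABELS = [
    "Sensory Symptoms",
    "Motor Symptoms Legs",
    "Motor Symptoms Arms",
    "Pin Sensibility",
    "Vibration",
    "Strength Legs",
    "Strength Arms",
    "Ulnar CMAP",
    "Ulnar SNAP",
]

# Published item locations (logits) of the 9-item fixture, hardest to
# easiest spanning about 2.3 logits; item 9 sits well below the rest.
CMTNS_LOCATIONS = np.array(
    [0.806, 0.942, 1.54, 0.429, 0.353, 0.105, 0.755, 0.687, -0.788]
)

# severity mixture defaults: mild / moderate / severe shares with
# component means chosen to put the bulk of the cohort near the items
MIXTURE_WEIGHTS = (0.17, 0.73, 0.10)
MIXTURE_MEANS = (-1.5, 0.3, 2.0)
MIXTURE_SDS = (0.5, 0.5, 0.5)


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic cohort.

    ``ability`` is either ``("normal", mean, sd)`` or
    ``("mixture", means, sds, weights)``.  Violations are all off by
    default:

    - ``dif``: ``(item_index, delta)`` — persons in DIF group 1 (balanced
      binary ``group`` covariate) get that item's thresholds shifted by
      ``delta`` logits.
    - ``second_dimension``: ``(item_indices_on_trait2, trait_correlation)``.
    - ``slopes``: per-item discrimination; category probabilities use
      ``exp(a_i * (h*theta - beta_h))`` (slope 1 for all items = PCM).
    - ``disorder_item``: swap that item's two middle adjacent thresholds
      (the smallest perturbation producing Andrich disorder).
    """

    n_persons: int = 277
    ability: tuple = ("mixture", MIXTURE_MEANS, MIXTURE_SDS, MIXTURE_WEIGHTS)
    dif: tuple | None = None
    second_dimension: tuple | None = None
    slopes: np.ndarray | None = None
    disorder_item: int | None = None
    seed: int = 0
    covariate_seed_offset: int = 104729  # decouples covariates from traits

    def validate(self, n_items: int) -> None:
        kind = self.ability[0]
        if kind == "normal":
            _, _, sd = self.ability
            if sd <= 0:
                raise InputError("ability sd must be > 0")
        elif kind == "mixture":
            _, means, sds, weights = self.ability
            if not np.isclose(np.sum(weights), 1.0):
                raise InputError("mixture weights must sum to 1")
            if np.any(np.asarray(sds) <= 0):
                raise InputError("mixture sds must be > 0")
            if len(means) != len(sds) or len(means) != len(weights):
                raise InputError("mixture component lengths differ")
        else:
            raise InputError(f"unknown ability spec {kind!r}")
        if self.slopes is not None:
            a = np.asarray(self.slopes, dtype=float)
            if a.size != n_items:
                raise InputError("slopes must have one entry per item")
            if np.any(a <= 0):
                raise InputError("slopes must be > 0")
        for ref in ((self.dif[0],) if self.dif else ()) + (
            tuple(self.second_dimension[0]) if self.second_dimension else ()
        ):
            if not (0 <= int(ref) < n_items):
                raise InputError(f"violation references unknown item {ref}")
        if self.disorder_item is not None and not (
            0 <= self.disorder_item < n_items
        ):
            raise InputError(
                f"violation references unknown item {self.disorder_item}"
            )


def make_cmtns_like_items(spread: float = 0.6) -> ItemParameters:
    """The 9-item, 5-category fixture instrument.

    Step thresholds are ``delta_ij = L_i + spread * (j - 2.5)`` for
    ``j = 1..4`` around the published locations, then re-centered to the
    mean-zero normalization (which shifts every location by the same
    constant; relative locations and the location span are preserved).
    """
    if spread <= 0:
        raise InputError("spread must be > 0")
    steps = spread * (np.arange(1, 5) - 2.5)
    thresholds = [loc + steps for loc in CMTNS_LOCATIONS]
    return ItemParameters(
        thresholds=thresholds, item_labels=list(CMTNS_ITEM_LABELS)
    ).recenter()


def _draw_abilities(config: SimulationConfig, rng: np.random.Generator):
    kind = config.ability[0]
    n = config.n_persons
    if kind == "normal":
        _, mean, sd = config.ability
        return rng.normal(mean, sd, size=n)
    _, means, sds, weights = config.ability
    comp = rng.choice(len(weights), size=n, p=np.asarray(weights, dtype=float))
    return rng.normal(np.asarray(means)[comp], np.asarray(sds)[comp])


def _sample_categories(theta, beta, slope, rng):
    """Sample one item's categories for all persons at once."""
    h = np.arange(beta.size, dtype=float)
    logits = slope * (h[None, :] * theta[:, None] - beta[None, :])
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(theta.size)
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def simulate_responses(
    config: SimulationConfig, items: ItemParameters
):
    """Draw a cohort from the (possibly violated) generating model.

    Returns ``(ResponseMatrix, truth)`` where ``truth`` records the drawn
    abilities, the generating thresholds actually used per person group,
    and the violation labels.  Covariates ``sex`` and ``age_group`` are
    generated independently of ability (so they are null groupings unless a
    DIF violation ties the ``group`` covariate to an item shift).
    """
    config.validate(items.n_items)
    rng = np.random.default_rng(config.seed)
    n, k = config.n_persons, items.n_items
    theta1 = _draw_abilities(config, rng)
    item_trait = np.zeros(k, dtype=int)
    if config.second_dimension is not None:
        idx2, rho = config.second_dimension
        # correlated second trait sharing theta1's marginal location/scale
        sd1 = max(theta1.std(), 1e-12)
        std1 = (theta1 - theta1.mean()) / sd1
        noise = rng.normal(size=n)
        theta2 = theta1.mean() + sd1 * (
            rho * std1 + np.sqrt(max(1 - rho**2, 0.0)) * noise
        )
        item_trait[np.asarray(idx2, dtype=int)] = 1
    else:
        theta2 = theta1
    slopes = (
        np.ones(k) if config.slopes is None
        else np.asarray(config.slopes, dtype=float)
    )
    thresholds = [t.copy() for t in items.thresholds]
    if config.disorder_item is not None:
        t = thresholds[config.disorder_item]
        mid = len(t) // 2
        t[mid - 1], t[mid] = t[mid], t[mid - 1]

    crng = np.random.default_rng(config.seed + config.covariate_seed_offset)
    sex = np.where(crng.random(n) < 0.5, "F", "M")
    age = crng.integers(18, 70, size=n)
    age_group = np.where(age < 45, "<45", ">=45")
    group = np.where(np.arange(n) % 2 == 0, 0, 1)  # balanced DIF grouping
    covariates = pd.DataFrame(
        {"sex": sex, "age": age, "age_group": age_group, "group": group}
    )

    scores = np.zeros((n, k), dtype=int)
    for j in range(k):
        th = theta1 if item_trait[j] == 0 else theta2
        delta = thresholds[j]
        if config.dif is not None and config.dif[0] == j:
            d_shift = config.dif[1]
            for gval, shift in ((0, 0.0), (1, d_shift)):
                sel = group == gval
                beta = np.concatenate([[0.0], np.cumsum(delta + shift)])
                scores[sel, j] = _sample_categories(th[sel], beta, slopes[j], rng)
        else:
            beta = np.concatenate([[0.0], np.cumsum(delta)])
            scores[:, j] = _sample_categories(th, beta, slopes[j], rng)

    responses = ResponseMatrix(
        scores=scores,
        max_cat=items.max_cat.copy(),
        missing_mask=np.zeros((n, k), dtype=bool),
        person_ids=[f"P{i + 1:04d}" for i in range(n)],
        item_labels=list(items.item_labels),
        covariates=covariates,
    )
    truth = {
        "theta": theta1,
        "theta2": theta2 if config.second_dimension is not None else None,
        "thresholds": thresholds,
        "slopes": slopes,
        "dif": config.dif,
        "second_dimension": config.second_dimension,
        "disorder_item": config.disorder_item,
        "seed": config.seed,
    }
    return responses, truth


def targeting_precision_experiment(
    n_persons: int = 150,
    replicates: int = 500,
    seed: int = 0,
    items: ItemParameters | None = None,
    tolerance_logits: float = 0.5,
) -> dict:
    """Sample-size targeting: how often are item locations recovered?

    Simulates well-targeted cohorts (abilities normal with mean equal to
    the mean item location and sd 1), fits the PCM by CML per replicate,
    and records per item whether the estimated location falls within
    ``tolerance_logits`` of its generating value.  Returns the pooled
    fraction over all items and replicates, per-replicate fractions, and a
    log of replicates dropped for estimation failure.
    """
    if items is None:
        items = make_cmtns_like_items()
    true_loc = items.locations
    target_mean = float(true_loc.mean())
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=replicates)
    per_rep = []
    hits = 0
    total = 0
    failures = []
    for rep, s in enumerate(seeds):
        cfg = SimulationConfig(
            n_persons=n_persons,
            ability=("normal", target_mean, 1.0),
            seed=int(s),
        )
        responses, _ = simulate_responses(cfg, items)
        try:
            est, _ = fit_cml(responses, on_nonconvergence="raise")
        except Exception as exc:  # noqa: BLE001 - replicate dropped, logged
            failures.append({"replicate": rep, "error": str(exc)})
            continue
        ok = np.abs(est.locations - true_loc) <= tolerance_logits
        per_rep.append(float(ok.mean()))
        hits += int(ok.sum())
        total += ok.size
    return {
        "pooled_fraction": hits / total if total else np.nan,
        "per_replicate": np.asarray(per_rep),
        "n_persons": n_persons,
        "replicates_used": len(per_rep),
        "failures": failures,
    }
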