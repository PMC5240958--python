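"""Response-matrix container, input validation and CSV I/O.

The central container is :class:`ResponseMatrix`: an integer persons × items
score matrix with a missing mask, per-item maximum category codes and
optional categorical person covariates (e.g. sex, age group).  Missing cells
are treated as *not administered* throughout the package: a person's raw
score and every conditional-likelihood computation run over the items that
person actually answered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Malformed input data (non-integer cells, out-of-range scores, ...)."""


class DegenerateItemError(InputError):
    """An item with fewer than two observed categories cannot be scaled."""


class EstimationError(RuntimeError):
    """Parameter estimation failed; carries the last iterate when available."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class ResponseMatrix:
    """Validated persons × items ordinal responses.

    Attributes
    ----------
    scores : (n_persons, n_items) int array
        Category codes; entries under ``missing_mask`` are arbitrary (0).
    max_cat : (n_items,) int array
        Highest category code ``m_i`` of each item (``m_i >= 1``).
    missing_mask : (n_persons, n_items) bool array
        True where the item was not administered.
    person_ids, item_labels : lists of str
    covariates : pandas.DataFrame or None
        Per-person categorical attributes, index-aligned with ``person_ids``.
    recode_maps : dict
        Per item label, the old→new category map applied during validation
        (empty when all declared categories were observed).
    """

    scores: np.ndarray
    max_cat: np.ndarray
    missing_mask: np.ndarray
    person_ids: list = field(default_factory=list)
    item_labels: list = field(default_factory=list)
    covariates: pd.DataFrame | None = None
    recode_maps: dict = field(default_factory=dict)

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def raw_scores(self) -> np.ndarray:
        """Per-person raw score: sum of observed item scores."""
        s = np.where(self.missing_mask, 0, self.scores)
        return s.sum(axis=1)

    def max_scores(self) -> np.ndarray:
        """Per-person maximum attainable raw score over answered items."""
        m = np.broadcast_to(self.max_cat, self.scores.shape)
        return np.where(self.missing_mask, 0, m).sum(axis=1)

    def n_answered(self) -> np.ndarray:
        return (~self.missing_mask).sum(axis=1)

    def extreme_mask(self) -> np.ndarray:
        """Persons whose raw score is 0 or the maximum attainable."""
        r = self.raw_scores()
        return (r == 0) | (r == self.max_scores())

    def subset_items(self, item_indices) -> "ResponseMatrix":
        idx = np.asarray(item_indices, dtype=int)
        return ResponseMatrix(
            scores=self.scores[:, idx].copy(),
            max_cat=self.max_cat[idx].copy(),
            missing_mask=self.missing_mask[:, idx].copy(),
            person_ids=list(self.person_ids),
            item_labels=[self.item_labels[i] for i in idx],
            covariates=self.covariates,
            recode_maps={},
        )

    def subset_persons(self, person_indices) -> "ResponseMatrix":
        idx = np.asarray(person_indices, dtype=int)
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[idx].reset_index(drop=True)
        return ResponseMatrix(
            scores=self.scores[idx].copy(),
            max_cat=self.max_cat.copy(),
            missing_mask=self.missing_mask[idx].copy(),
            person_ids=[self.person_ids[i] for i in idx],
            item_labels=list(self.item_labels),
            covariates=cov,
            recode_maps=dict(self.recode_maps),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.where(self.missing_mask, np.nan, self.scores),
            columns=self.item_labels,
        )
        df.insert(0, "person_id", self.person_ids)
        if self.covariates is not None:
            for c in self.covariates.columns:
                df.insert(1, c, self.covariates[c].to_numpy())
        return df


def validate_responses(
    raw_table: pd.DataFrame,
    item_columns=None,
    id_column: str = "person_id",
    covariate_columns=None,
    max_cat=None,
) -> ResponseMatrix:
    """Validate a wide person-by-item table into a :class:`ResponseMatrix`.

    Items with unobserved interior (or edge) categories are recoded onto
    consecutive observed codes with a warning; the map is recorded in
    ``recode_maps``.  Non-integer or negative scores, or scores above the
    declared maximum, raise :class:`InputError` naming the offending cell.
    Items with fewer than two observed categories raise
    :class:`DegenerateItemError`.

    Parameters
    ----------
    raw_table : DataFrame
        One row per person.  ``id_column`` (optional) identifies persons,
        ``covariate_columns`` are kept aside, all remaining columns are items.
    max_cat : sequence of int, optional
        Declared per-item maxima; inferred from the observed maxima if absent.
    """
    df = raw_table.copy()
    if id_column in df.columns:
        person_ids = [str(p) for p in df[id_column]]
        df = df.drop(columns=[id_column])
    else:
        person_ids = [str(i) for i in range(len(df))]
    covariates = None
    if covariate_columns:
        present = [c for c in covariate_columns if c in df.columns]
        if present:
            covariates = df[present].reset_index(drop=True)
            df = df.drop(columns=present)
    if item_columns is not None:
        df = df[list(item_columns)]
    item_labels = [str(c) for c in df.columns]
    if len(item_labels) < 2:
        raise InputError("need at least 2 item columns")
    n, k = df.shape
    if n < 2:
        raise InputError("need at least 2 persons")

    scores = np.zeros((n, k), dtype=int)
    missing = np.zeros((n, k), dtype=bool)
    declared = None if max_cat is None else np.asarray(max_cat, dtype=int)
    for j, col in enumerate(df.columns):
        vals = df[col]
        for i, v in enumerate(vals):
            if v is None or (isinstance(v, float) and np.isnan(v)) or (
                isinstance(v, str) and v.strip() in ("", "NA", "NaN", "nan")
            ):
                missing[i, j] = True
                continue
            fv = float(v)
            if not float(fv).is_integer():
                raise InputError(
                    f"non-integer score {v!r} at row {i}, item {col!r}"
                )
            iv = int(fv)
            if iv < 0:
                raise InputError(f"negative score {iv} at row {i}, item {col!r}")
            if declared is not None and iv > declared[j]:
                raise InputError(
                    f"score {iv} exceeds declared maximum {declared[j]} "
                    f"at row {i}, item {col!r}"
                )
            scores[i, j] = iv

    recode_maps = {}
    max_out = np.zeros(k, dtype=int)
    for j, col in enumerate(item_labels):
        obs = np.unique(scores[~missing[:, j], j])
        if obs.size < 2:
            raise DegenerateItemError(
                f"item {col!r} has {obs.size} observed categor"
                f"{'y' if obs.size == 1 else 'ies'}; at least 2 required"
            )
        m_decl = int(declared[j]) if declared is not None else int(obs.max())
        full = np.arange(m_decl + 1)
        if obs.size != full.size or not np.array_equal(obs, full):
            mapping = {int(o): r for r, o in enumerate(obs)}
            recode_maps[col] = mapping
            warnings.warn(
                f"item {col!r}: categories {sorted(mapping)} recoded to "
                f"consecutive codes 0..{obs.size - 1}",
                stacklevel=2,
            )
            lut = np.zeros(int(obs.max()) + 1, dtype=int)
            for o, r in mapping.items():
                lut[o] = r
            col_scores = scores[:, j].copy()
            valid = ~missing[:, j]
            col_scores[valid] = lut[col_scores[valid]]
            scores[:, j] = col_scores
            max_out[j] = obs.size - 1
        else:
            max_out[j] = m_decl
    return ResponseMatrix(
        scores=scores,
        max_cat=max_out,
        missing_mask=missing,
        person_ids=person_ids,
        item_labels=item_labels,
        covariates=covariates,
        recode_maps=recode_maps,
    )


def read_responses_csv(
    path,
    id_column: str = "person_id",
    covariate_columns=("sex", "age", "age_group", "group"),
    max_cat=None,
) -> ResponseMatrix:
    """Read a wide response CSV (missing cells empty or 'NA') and validate."""
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True)
    return validate_responses(
        df,
        id_column=id_column,
        covariate_columns=[c for c in covariate_columns if c in df.columns],
        max_cat=max_cat,
    )


def write_responses_csv(responses: ResponseMatrix, path) -> None:
    df = responses.to_frame()
    # keep integer formatting for observed cells
    for c in responses.item_labels:
        df[c] = df[c].astype("Int64")
    df.to_csv(path, index=False)
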