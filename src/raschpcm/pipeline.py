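"""End-to-end scale validation: QC, assumption tests, global fit,
reliability, item fit and category structure, serialized as a JSON + TSV
report bundle.

Stage order follows standard Rasch-validation practice: person-fit
quality control first, then all diagnostics on the retained sample.
Bonferroni correction is applied across items for the item-fit chi-square
p-values and within each DIF grouping.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assumptions import (
    dif_anova,
    martin_lof_test,
    pca_residual_split,
    residual_correlations,
    subset_person_ttests,
)
from .categories import (
    CollapseMap,
    build_person_item_map,
    category_curves,
    category_frequency_ratios,
    collapse_categories,
    threshold_profile,
)
from .data import ResponseMatrix, read_responses_csv
from .globalfit import andersen_lr_test
from .pcm import estimate_persons, fit_cml
from .residuals import (
    item_fit,
    person_fit,
    person_qc_filter,
    person_separation_index,
    standardized_residuals,
)

__all__ = ["ValidationReport", "run_validation", "compare_modification",
           "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 0,
    "qc": {"enabled": True, "alpha": 0.05},
    "assumptions": {
        "enabled": True,
        "residual_corr_bound": 0.3,
        "ttest_alpha": 0.05,
        "ttest_support_pct": 5.0,
        "martin_lof_bootstrap": 200,
        "dif_groupings": ["sex", "age_group"],
        "dif_strata": 4,
        "dif_alpha": 0.05,
    },
    "global_fit": {"enabled": True, "n_groups": 2, "split_rule": "median"},
    "item_fit": {"enabled": True, "alpha": 0.05},
    "category": {"enabled": True, "theta_grid": [-8.0, 8.0, 0.1]},
    "collapse": None,  # optional {item label: {old: new}}
}


@dataclass
class ValidationReport:
    """Aggregate of one validation run; (re)derivable verdicts included."""

    provenance: dict
    qc: dict
    assumptions: dict
    global_fit: dict
    reliability: dict
    item_table: pd.DataFrame
    category: dict
    verdicts: dict
    tables: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "qc": self.qc,
            "assumptions": self.assumptions,
            "global_fit": self.global_fit,
            "reliability": self.reliability,
            "item_table": json.loads(
                self.item_table.reset_index().to_json(orient="records")
            ),
            "category": self.category,
            "verdicts": self.verdicts,
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "validation_report.json").write_text(
            json.dumps(_jsonify(self.to_json_dict()), indent=2, sort_keys=True)
        )
        self.item_table.to_csv(out / "item_fit.tsv", sep="\t")
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    return obj


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _input_hash(responses: ResponseMatrix) -> str:
    h = hashlib.sha256()
    h.update(responses.scores.tobytes())
    h.update(responses.missing_mask.tobytes())
    h.update(",".join(responses.item_labels).encode())
    return h.hexdigest()[:16]


def run_validation(
    responses_or_csv,
    config: dict | str | Path | None = None,
) -> ValidationReport:
    """Run the full validation workflow on a response table.

    ``responses_or_csv`` is a :class:`ResponseMatrix` or a CSV path;
    ``config`` a dict or YAML path overriding :data:`DEFAULT_CONFIG`.
    Stages: person-fit QC, local independence, unidimensionality (PCA
    split + per-person t-tests + Martin-Löf), DIF over the configured
    groupings, Andersen global test, PSI, item fit, threshold/category
    structure and the Wright map.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge_config(config)
    if isinstance(responses_or_csv, (str, Path)):
        responses = read_responses_csv(responses_or_csv)
        source = str(responses_or_csv)
    else:
        responses = responses_or_csv
        source = "<in-memory>"
    provenance = {
        "source": source,
        "input_hash": _input_hash(responses),
        "n_persons": responses.n_persons,
        "n_items": responses.n_items,
        "config": cfg,
        "version": __version__,
    }

    # --- initial fit for QC --------------------------------------------
    params0, meta0 = fit_cml(responses, on_nonconvergence="warn")
    persons0 = estimate_persons(responses, params0)
    resid0 = standardized_residuals(responses, params0, persons0)
    pfit0 = person_fit(resid0)
    if cfg["qc"]["enabled"]:
        retained, qc_log = person_qc_filter(
            responses, pfit0, alpha=cfg["qc"]["alpha"]
        )
        qc = {
            "enabled": True,
            "alpha": cfg["qc"]["alpha"],
            "n_total": qc_log.attrs["n_total"],
            "n_excluded": qc_log.attrs["n_excluded"],
            "rate_percent": qc_log.attrs["rate_percent"],
            "excluded_persons": list(qc_log.index),
        }
    else:
        retained, qc_log = responses, None
        qc = {"enabled": False, "n_total": responses.n_persons,
              "n_excluded": 0, "rate_percent": 0.0, "excluded_persons": []}

    # --- definitive fit on the retained sample -------------------------
    params, meta = fit_cml(retained, on_nonconvergence="warn")
    persons = estimate_persons(retained, params)
    resid = standardized_residuals(retained, params, persons)
    tables: dict = {"item_parameters": params.to_frame()}

    # --- assumptions ----------------------------------------------------
    assumptions: dict = {"enabled": bool(cfg["assumptions"]["enabled"])}
    if cfg["assumptions"]["enabled"]:
        acfg = cfg["assumptions"]
        indep = residual_correlations(resid)
        assumptions["local_independence"] = {
            "max_offdiag_corr": float(
                np.nanmax(
                    indep.corr.to_numpy()[
                        ~np.eye(len(indep.corr), dtype=bool)
                    ]
                )
            ),
            "flagged_pairs": [list(p) for p in indep.flagged_pairs],
            "passed": indep.passed,
        }
        tables["residual_correlations"] = indep.corr.reset_index(names="item")
        split = pca_residual_split(resid)
        tt = subset_person_ttests(
            retained,
            params,
            (split.subset_A, split.subset_B),
            alpha=acfg["ttest_alpha"],
            support_bound_pct=acfg["ttest_support_pct"],
        )
        ml = martin_lof_test(
            retained,
            (split.subset_A, split.subset_B),
            bootstrap=acfg["martin_lof_bootstrap"],
            seed=cfg["seed"],
        )
        assumptions["unidimensionality"] = {
            "subset_A": split.subset_A,
            "subset_B": split.subset_B,
            "fallback_median_split": split.fallback_median_split,
            "pct_significant": tt["pct_significant"],
            "n_tested": tt["n_tested"],
            "supported": tt["supported"],
            "martin_lof": {
                k: ml[k]
                for k in ml
                if k != "t_values"
            },
        }
        tables["pca_loadings"] = split.loadings.reset_index().rename(
            columns={"index": "item"}
        )
        dif_frames = []
        dif_summary = {}
        cov = retained.covariates
        for grouping in acfg["dif_groupings"]:
            if cov is None or grouping not in cov.columns:
                continue
            table = dif_anova(
                resid,
                persons,
                cov[grouping].to_numpy(),
                n_strata=acfg["dif_strata"],
                alpha=acfg["dif_alpha"],
                grouping_name=grouping,
            )
            dif_frames.append(table.table)
            dif_summary[grouping] = {
                "flagged_items": table.flagged_items(),
                "n_strata_used": table.table.attrs["n_strata_used"],
            }
        if dif_frames:
            tables["dif"] = pd.concat(dif_frames, ignore_index=True)
        assumptions["invariance"] = {
            "groupings": dif_summary,
            "passed": all(
                not v["flagged_items"] for v in dif_summary.values()
            ),
        }

    # --- global fit and reliability ------------------------------------
    global_fit: dict = {"enabled": bool(cfg["global_fit"]["enabled"])}
    if cfg["global_fit"]["enabled"]:
        ar = andersen_lr_test(
            retained,
            n_groups=cfg["global_fit"]["n_groups"],
            split_rule=cfg["global_fit"]["split_rule"],
        )
        global_fit.update(
            statistic=ar.statistic,
            df=ar.df,
            p_value=ar.p_value,
            group_spec=ar.group_spec,
            group_sizes=ar.group_sizes,
            goodness_of_fit=ar.goodness_of_fit,
        )
    psi = person_separation_index(persons)
    reliability = dict(psi)

    # --- item fit -------------------------------------------------------
    ifit = item_fit(resid)
    item_table = ifit.table.copy()
    n_items = len(item_table)
    item_table["location"] = params.locations
    item_table["p_bonferroni"] = np.minimum(1.0, item_table["p_value"] * n_items)
    order = [
        "location", "n", "residual_mean", "residual_sd", "chisq", "df",
        "p_value", "p_bonferroni", "outfit_msq", "infit_msq", "outfit_t",
        "infit_t", "underfit", "overfit", "defined",
    ]
    item_table = item_table[order]

    # --- category structure ---------------------------------------------
    category: dict = {"enabled": bool(cfg["category"]["enabled"])}
    if cfg["category"]["enabled"]:
        profile = threshold_profile(params)
        lo, hi, step = cfg["category"]["theta_grid"]
        grid = np.arange(lo, hi + step / 2, step)
        curves = category_curves(params, grid)
        pim = build_person_item_map(persons, profile, params)
        ratios = category_frequency_ratios(retained, params, persons)
        category.update(
            disordered_items=[
                lab
                for lab, d in zip(profile.item_labels, profile.disordered)
                if d
            ],
            disorder_detail={
                k: [list(p) for p in v]
                for k, v in profile.disorder_detail.items()
            },
        )
        tables["thresholds"] = profile.to_frame()
        curve_rows = []
        for lab, mat in curves.items():
            for gi, th in enumerate(grid):
                for h in range(mat.shape[1]):
                    curve_rows.append(
                        {"item": lab, "theta": th, "category": h,
                         "probability": mat[gi, h]}
                    )
        tables["category_curves"] = pd.DataFrame(curve_rows)
        tables["person_item_map_items"] = pim.items
        tables["person_item_map_thresholds"] = pim.thresholds
        tables["person_item_map_histogram"] = pd.DataFrame(
            {
                "bin_left": pim.person_bins[:-1],
                "bin_right": pim.person_bins[1:],
                "count": pim.person_counts,
            }
        )
        tables["category_frequency_ratios"] = ratios

    # --- verdicts --------------------------------------------------------
    verdicts = {}
    if cfg["assumptions"]["enabled"]:
        verdicts["local_independence"] = assumptions["local_independence"][
            "passed"
        ]
        verdicts["unidimensionality_ttests"] = assumptions[
            "unidimensionality"
        ]["supported"]
        verdicts["unidimensionality_martin_lof"] = bool(
            assumptions["unidimensionality"]["martin_lof"]["p_value"] >= 0.05
        )
        verdicts["invariance"] = assumptions["invariance"]["passed"]
    if cfg["global_fit"]["enabled"]:
        verdicts["global_fit"] = global_fit["goodness_of_fit"]
    verdicts["reliability"] = bool(reliability.get("acceptable", False))
    verdicts["item_fit"] = bool(
        ~item_table["underfit"].fillna(False).to_numpy().any()
    )
    report = ValidationReport(
        provenance=provenance,
        qc=qc,
        assumptions=assumptions,
        global_fit=global_fit,
        reliability=reliability,
        item_table=item_table,
        category=category,
        verdicts=verdicts,
        tables=tables,
    )
    if cfg.get("collapse"):
        cmap = CollapseMap(maps={
            lab: {int(k): int(v) for k, v in m.items()}
            for lab, m in cfg["collapse"].items()
        })
        report.category["modification"] = compare_modification(
            report, cmap, retained
        )
    return report


def compare_modification(
    report_before: ValidationReport,
    cmap: CollapseMap,
    responses: ResponseMatrix,
) -> dict:
    """Refit after collapsing categories and compare key diagnostics.

    Returns PSI before/after, per-item infit t before/after and the count
    of disordered items before/after.
    """
    collapsed = collapse_categories(responses, cmap)
    params_b, _ = fit_cml(responses, on_nonconvergence="warn")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params_a, _ = fit_cml(collapsed, on_nonconvergence="warn")
        persons_b = estimate_persons(responses, params_b)
        persons_a = estimate_persons(collapsed, params_a)
        resid_b = standardized_residuals(responses, params_b, persons_b)
        resid_a = standardized_residuals(collapsed, params_a, persons_a)
    psi_b = person_separation_index(persons_b)
    psi_a = person_separation_index(persons_a)
    ifit_b = item_fit(resid_b).table["infit_t"]
    ifit_a = item_fit(resid_a).table["infit_t"]
    prof_b = threshold_profile(params_b)
    prof_a = threshold_profile(params_a)
    return {
        "collapsed_items": sorted(cmap.maps),
        "psi_before": psi_b["psi"],
        "psi_after": psi_a["psi"],
        "infit_t_before": {k: float(v) for k, v in ifit_b.items()},
        "infit_t_after": {k: float(v) for k, v in ifit_a.items()},
        "n_disordered_before": int(prof_b.disordered.sum()),
        "n_disordered_after": int(prof_a.disordered.sum()),
        "disordered_before": [
            lab for lab, d in zip(prof_b.item_labels, prof_b.disordered) if d
        ],
        "disordered_after": [
            lab for lab, d in zip(prof_a.item_labels, prof_a.disordered) if d
        ],
    }
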