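#!/usr/bin/env python
"""Overall goodness-of-fit and reliability on the QC'd cohort.

Andersen's conditional likelihood-ratio test across the median raw-score
split, the Person Separation Index, and the item-fit table in the
standard layout (location, residual moments, chi-square p, infit/outfit
mean squares and t statistics).
"""

import warnings
from pathlib import Path

import numpy as np

from raschpcm import (
    andersen_lr_test,
    estimate_persons,
    fit_cml,
    item_fit,
    person_separation_index,
    read_responses_csv,
    standardized_residuals,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    responses = read_responses_csv(OUT / "cohort_qc.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params, _ = fit_cml(responses)
        persons = estimate_persons(responses, params)
        resid = standardized_residuals(responses, params, persons)
        andersen = andersen_lr_test(responses)
        psi = person_separation_index(persons)
        fi = item_fit(resid)

    print(
        f"Andersen LR: {andersen.statistic:.1f} on {andersen.df} df, "
        f"p={andersen.p_value:.3f} "
        f"({'good fit' if andersen.goodness_of_fit else 'misfit'}); "
        f"{andersen.group_spec}"
    )
    print(
        f"PSI: {psi['psi']:.3f} over {psi['n']} persons "
        f"({'acceptable' if psi['acceptable'] else 'below 0.7'})"
    )
    table = fi.table.copy()
    table.insert(0, "location", params.locations)
    table["p_bonferroni"] = np.minimum(1.0, table["p_value"] * len(table))
    cols = [
        "location", "residual_mean", "residual_sd", "p_value",
        "outfit_msq", "infit_msq", "outfit_t", "infit_t",
    ]
    print(table[cols].round(3).to_string())
    table.to_csv(OUT / "item_fit.tsv", sep="\t")


if __name__ == "__main__":
    main()
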