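#!/usr/bin/env python
"""Category structure: threshold ordering, curves, the Wright map, and a
what-if collapse of disordered categories.

Flags items whose Andrich step thresholds are not strictly increasing,
exports category characteristic curves and person-item map data, and —
when disorder is present — collapses the offending adjacent categories,
refits, and compares PSI, infit t and disorder counts before/after.
"""

import warnings
from pathlib import Path

import numpy as np

from raschpcm import (
    CollapseMap,
    build_person_item_map,
    category_curves,
    category_frequency_ratios,
    compare_modification,
    estimate_persons,
    fit_cml,
    read_responses_csv,
    standardized_residuals,
    threshold_profile,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def corrective_maps(profile):
    """Merge the first offending adjacent pair of each disordered item."""
    maps = {}
    for lab, pairs in profile.disorder_detail.items():
        lo = pairs[0][0]
        m, new = {}, 0
        for h in range(5):
            m[h] = new
            if h != lo:
                new += 1
        maps[lab] = m
    return maps


def main():
    responses = read_responses_csv(OUT / "cohort_qc.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params, _ = fit_cml(responses)
        persons = estimate_persons(responses, params)
        resid = standardized_residuals(responses, params, persons)
        profile = threshold_profile(params)
        pim = build_person_item_map(persons, profile, params)
        curves = category_curves(params, np.arange(-8, 8.01, 0.1))
        ratios = category_frequency_ratios(responses, params, persons)

    disordered = [
        lab for lab, d in zip(profile.item_labels, profile.disordered) if d
    ]
    print(f"disordered items: {disordered or 'none'}")
    sel = ratios[ratios["under_selected"] | ratios["over_selected"]]
    print("category selection anomalies (observed/expected ratio):")
    print(sel.round(3).to_string() if len(sel) else "  none")

    profile.to_frame().to_csv(OUT / "thresholds.tsv", sep="\t", index=False)
    pim.items.to_csv(OUT / "wright_map_items.tsv", sep="\t", index=False)
    pim.thresholds.to_csv(OUT / "wright_map_thresholds.tsv", sep="\t", index=False)
    ratios.to_csv(OUT / "category_ratios.tsv", sep="\t", index=False)

    if disordered:
        maps = corrective_maps(profile)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp = compare_modification(None, CollapseMap(maps=maps), responses)
        print(
            f"after collapsing {sorted(maps)}: disordered items "
            f"{cmp['n_disordered_before']} -> {cmp['n_disordered_after']}, "
            f"PSI {cmp['psi_before']:.3f} -> {cmp['psi_after']:.3f}"
        )


if __name__ == "__main__":
    main()
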