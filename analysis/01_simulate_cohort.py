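#!/usr/bin/env python
"""Simulate the study cohort.

Generates a 277-person cohort on the 9-item, 5-category instrument with
the mild/moderate/severe severity mixture, and writes the wide response
CSV plus the generating truth.  Every later analysis step starts from
this file, exactly as a real validation would start from collected
scores.
"""

import json
from pathlib import Path

import numpy as np

from raschpcm import (
    SimulationConfig,
    make_cmtns_like_items,
    simulate_responses,
    write_responses_csv,
)
from raschpcm.pipeline import _jsonify

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260929


def main():
    OUT.mkdir(exist_ok=True)
    items = make_cmtns_like_items()
    cfg = SimulationConfig(n_persons=277, seed=SEED)
    responses, truth = simulate_responses(cfg, items)
    write_responses_csv(responses, OUT / "cohort.csv")
    (OUT / "cohort_truth.json").write_text(
        json.dumps(
            _jsonify(
                {
                    "theta": truth["theta"],
                    "thresholds": truth["thresholds"],
                    "locations": items.locations,
                    "seed": SEED,
                }
            ),
            indent=2,
        )
    )
    r = responses.raw_scores()
    print(f"cohort: {responses.n_persons} persons x {responses.n_items} items")
    print(f"raw scores: min {r.min()}, median {np.median(r):.0f}, max {r.max()}")
    print(f"written to {OUT / 'cohort.csv'}")


if __name__ == "__main__":
    main()
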