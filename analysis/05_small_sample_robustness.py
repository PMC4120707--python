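"""Sampling variability of the centroid vs the fitted model peak.

The centroid of direct responses is often preferred over the fitted
criterion midpoint (peak) as a locator of subjectively direct gaze when
trial counts are low. This script measures both estimators' sampling
variance across replicate simulations of a fixed observer at 3 trials
per eye-deviation cell, and reports which is more stable under our
well-specified generative model.
"""

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from gazecues.category import centroid_direct, counts_from_trials, fit_category_model
from gazecues.observer import ObserverParams, simulate_trials

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 20240005
N_REP = 200
TRIALS_PER_CELL = 3
LEVELS = (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0)

obs = ObserverParams(w_direct_head=0.0, bias_deg=-1.0)
design = pd.DataFrame(
    {
        "subject": 0,
        "block": 1,
        "trial_index": range(len(LEVELS) * TRIALS_PER_CELL),
        "condition": "eye_region",
        "identity": 1,
        "head_orientation_deg": 0.0,
        "eye_deviation_deg": [e for e in LEVELS for _ in range(TRIALS_PER_CELL)],
    }
)

peaks, centroids = [], []
for rep in range(N_REP):
    trials = simulate_trials(obs, design, np.random.default_rng(SEED + rep))
    counts = counts_from_trials(trials)
    totals = counts[["n_left", "n_direct", "n_right"]].sum(axis=1).to_numpy()
    p_direct = counts["n_direct"].to_numpy() / totals
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        centroids.append(centroid_direct(counts["eye_deviation_deg"], p_direct))
        try:
            peaks.append(fit_category_model(counts).peak_deg)
        except RuntimeError as err:
            peaks.append(err.best_candidate.peak_deg)

result = {
    "trials_per_cell": TRIALS_PER_CELL,
    "n_replicates": N_REP,
    "peak_sampling_variance": float(np.var(peaks)),
    "centroid_sampling_variance": float(np.nanvar(centroids)),
    "variance_ratio_centroid_over_peak": float(np.nanvar(centroids) / np.var(peaks)),
}
with open(OUT / "small_sample_robustness.json", "w") as fh:
    json.dump(result, fh, indent=2)

print(json.dumps(result, indent=2))
winner = "centroid" if result["variance_ratio_centroid_over_peak"] <= 1 else "model peak"
print(f"\nmore stable locator at {TRIALS_PER_CELL} trials/cell: {winner}")
print("note: with a well-specified model the multi-start MLE peak pools all "
      "left/direct/right information, while the centroid uses only the direct "
      "responses on a 5-degree grid; on real (misspecified) data the ordering "
      "can differ.")
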