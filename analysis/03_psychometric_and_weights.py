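"""Psychometric fits, cue weights and the dual-route decomposition.

Reads results/trials.csv (run 02_simulate_study.py first), fits the
logistic psychometric function per head orientation (group-average and
per subject), regresses the points of subjectively direct gaze on head
orientation, converts the slopes to eye/head cue weights, decomposes the
whole-head weights into the eye-region route and the direct head route,
and t-tests the per-subject weights against zero.
"""

import json
from pathlib import Path

import pandas as pd

from gazecues import io as gio
from gazecues.pipeline import weights_table
from gazecues.psychometric import fit_psychometric_table
from gazecues.weights import decompose, group_t_test

OUT = Path(__file__).resolve().parent.parent / "results"
trials = gio.read_trials(OUT / "trials.csv")

group_fits = fit_psychometric_table(trials, level="group")
subject_fits = fit_psychometric_table(trials, level="subject")
pd.concat([group_fits, subject_fits], ignore_index=True).to_csv(
    OUT / "psychometric_fits.csv", index=False
)

group_w = weights_table(group_fits)
subject_w = weights_table(subject_fits)
subject_w.to_csv(OUT / "weights_subject.csv", index=False)

print("group-average cue weights:")
print(group_w.round(4).to_string(index=False))

m = group_w.set_index("condition")["slope_m"]
dec = decompose(m["whole_head"], m["eye_region"])
per_subject = subject_w.pivot(index="subject", columns="condition", values="slope_m")
subject_direct = per_subject.apply(
    lambda row: decompose(row["whole_head"], row["eye_region"]).w_direct, axis=1
)

decomposition = {
    "m_WH": dec.m_wh,
    "m_ER": dec.m_er,
    "w_er_route": dec.w_er_route,
    "w_direct": dec.w_direct,
    "w_direct_subject_mean": float(subject_direct.mean()),
}
with open(OUT / "decomposition.json", "w") as fh:
    json.dump(decomposition, fh, indent=2)
print("\ndual-route decomposition (group):",
      {k: round(v, 4) for k, v in decomposition.items()})

print("\nper-subject t tests against zero:")
for name, values in [
    ("w_head (whole head)", subject_w.query("condition == 'whole_head'")["w_head"]),
    ("w_head (eye region)", subject_w.query("condition == 'eye_region'")["w_head"]),
    ("w_direct", subject_direct),
]:
    t = group_t_test(values)
    print(f"  {name}: mean={t.mean:+.3f}, t({t.df})={t.t_statistic:+.2f}, "
          f"p={t.p_value:.2g}, d={t.cohen_d:+.2f}")
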