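"""Generate the factorial trial designs for both experiments.

Writes the blocked per-subject designs (20 subjects each) under
results/ and prints the count structure: the main experiment's
6 x 180-trial alternating blocks and the control experiment's
3 x 36-trial consecutive blocks per condition.
"""

from pathlib import Path

import pandas as pd

from gazecues.design import DesignSpec, control_spec, generate_control_design, generate_main_design

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
N_SUBJECTS = 20
SEED = 20240001

main = pd.concat(
    [generate_main_design(DesignSpec(seed=SEED), i) for i in range(N_SUBJECTS)],
    ignore_index=True,
)
control = pd.concat(
    [generate_control_design(control_spec(seed=SEED), i) for i in range(N_SUBJECTS)],
    ignore_index=True,
)
main.to_csv(OUT / "design_main.csv", index=False)
control.to_csv(OUT / "design_control.csv", index=False)

per_subject = main.groupby("subject").size().iloc[0]
block_size = main.groupby(["subject", "block"]).size().iloc[0]
print(f"main design: {per_subject} trials/subject in "
      f"{main['block'].nunique()} blocks of {block_size}")
first_conditions = main[main["block"] == 1].groupby("subject")["condition"].first()
print("first-block condition by subject parity:",
      dict(first_conditions.groupby(first_conditions.index % 2).first()))
ctrl_per_cond = control[control["subject"] == 0].groupby("condition").size()
print(f"control design: {ctrl_per_cond.iloc[0]} trials per condition, "
      f"blocks of {control.groupby(['subject', 'block']).size().iloc[0]}")
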