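"""CSV readers/writers for the trial-record dialect.

Trial tables travel as plain CSV with columns subject, condition, block,
trial_index, identity, head_orientation_deg, eye_deviation_deg and (for
simulated or collected data) response coded L / D / R. Internally
responses are the full words left / direct / right.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_TO_LETTER = {"left": "L", "direct": "D", "right": "R"}
_FROM_LETTER = {"L": "left", "D": "direct", "R": "right"}


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials.copy()
    if "response" in out.columns:
        out["response"] = out["response"].map(lambda r: _TO_LETTER.get(r, r))
    out.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    if "response" in trials.columns:
        trials["response"] = trials["response"].map(lambda r: _FROM_LETTER.get(r, r))
        bad = set(trials["response"]) - {"left", "direct", "right"}
        if bad:
            raise ValueError(f"unknown response labels in {path}: {sorted(bad)}")
    return trials
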