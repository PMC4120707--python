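"""Factorial trial designs for the gaze-categorization experiments.

Two designs are provided. The *main* design crosses facial identity,
head orientation and eye deviation within blocks, alternating the
whole-head and eye-region display conditions between blocks (first block
counterbalanced across subjects). The *control* design fixes head
orientation at 0°, adds an eyes-only condition, and shows each condition
in consecutive blocks in a per-subject random order.

Designs are returned as tidy :class:`pandas.DataFrame` tables with one
row per trial, ready to be written as CSV or fed to the simulator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MAIN_CONDITIONS = ("whole_head", "eye_region")
CONTROL_CONDITIONS = ("whole_head", "eye_region", "eyes_only")

HEAD_ORIENTATIONS = (-30.0, -15.0, 0.0, 15.0, 30.0)
EYE_DEVIATIONS = (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0)

DESIGN_COLUMNS = [
    "subject",
    "block",
    "trial_index",
    "condition",
    "identity",
    "head_orientation_deg",
    "eye_deviation_deg",
]


@dataclass(frozen=True)
class DesignSpec:
    """Factor levels and repetition counts for one experiment design.

    ``seed`` is a master seed; each subject's randomization stream is
    derived as ``seed + subject_index`` so designs are reproducible and
    independent across subjects.
    """

    n_identities: int = 4
    head_orientations: tuple[float, ...] = HEAD_ORIENTATIONS
    eye_deviations: tuple[float, ...] = EYE_DEVIATIONS
    n_repetitions_per_condition: int = 3
    conditions: tuple[str, ...] = MAIN_CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_identities < 1 or self.n_repetitions_per_condition < 1:
            raise ValueError("identity and repetition counts must be positive")
        if not self.head_orientations or not self.eye_deviations or not self.conditions:
            raise ValueError("factor level lists must be non-empty")
        if (
            self.n_identities == 1
            and len(self.head_orientations) == 1
            and len(self.eye_deviations) == 1
        ):
            warnings.warn("degenerate design: a single cell per block", stacklevel=2)

    @property
    def cells_per_block(self) -> int:
        """Trials per block: one presentation of every within-block cell."""
        return self.n_identities * len(self.head_orientations) * len(self.eye_deviations)

    def subject_rng(self, subject_index: int) -> np.random.Generator:
        return np.random.default_rng(self.seed + subject_index)


def control_spec(seed: int = 0, n_repetitions_per_condition: int = 3) -> DesignSpec:
    """Spec for the control experiment: frontal head only, three conditions."""
    return DesignSpec(
        head_orientations=(0.0,),
        conditions=CONTROL_CONDITIONS,
        n_repetitions_per_condition=n_repetitions_per_condition,
        seed=seed,
    )


def _block_cells(spec: DesignSpec) -> list[tuple[int, float, float]]:
    return list(
        itertools.product(
            range(1, spec.n_identities + 1),
            spec.head_orientations,
            spec.eye_deviations,
        )
    )


def _rows_for_block(
    cells: list[tuple[int, float, float]],
    rng: np.random.Generator,
    subject: int,
    block: int,
    condition: str,
    start_index: int,
) -> list[dict]:
    order = rng.permutation(len(cells))
    rows = []
    for k, j in enumerate(order):
        identity, head, eye = cells[j]
        rows.append(
            {
                "subject": subject,
                "block": block,
                "trial_index": start_index + k,
                "condition": condition,
                "identity": identity,
                "head_orientation_deg": head,
                "eye_deviation_deg": eye,
            }
        )
    return rows


def generate_main_design(spec: DesignSpec, subject_index: int) -> pd.DataFrame:
    """Blocked main-experiment design for one subject.

    Blocks alternate between the two display conditions; the condition of
    the first block is counterbalanced by the parity of ``subject_index``
    (even starts with whole-head). Within a block every
    identity x head-orientation x eye-deviation cell appears exactly once,
    in a seeded random order. The default spec yields 1,080 trials in six
    blocks of 180.
    """
    if len(spec.conditions) != 2:
        raise ValueError("main design requires exactly two conditions")
    rng = spec.subject_rng(subject_index)
    first, second = spec.conditions
    if subject_index % 2 == 1:
        first, second = second, first
    cells = _block_cells(spec)
    rows: list[dict] = []
    block = 0
    for _rep in range(spec.n_repetitions_per_condition):
        for condition in (first, second):
            block += 1
            rows.extend(
                _rows_for_block(cells, rng, subject_index, block, condition, len(rows))
            )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def generate_control_design(spec: DesignSpec, subject_index: int) -> pd.DataFrame:
    """Control-experiment design: consecutive blocks per condition.

    Head orientation is fixed (single level, 0° in the study). The order
    of the three conditions is randomized per subject; each condition is
    shown in ``n_repetitions_per_condition`` consecutive blocks, each
    block holding one presentation of every identity x eye-deviation cell.
    The default spec yields 108 trials per condition in three blocks of 36.
    """
    if len(spec.conditions) != 3:
        raise ValueError("control design requires exactly three conditions")
    if len(spec.head_orientations) != 1:
        raise ValueError("control design uses a single head orientation")
    rng = spec.subject_rng(subject_index)
    condition_order = [spec.conditions[i] for i in rng.permutation(len(spec.conditions))]
    cells = _block_cells(spec)
    rows: list[dict] = []
    block = 0
    for condition in condition_order:
        for _rep in range(spec.n_repetitions_per_condition):
            block += 1
            rows.extend(
                _rows_for_block(cells, rng, subject_index, block, condition, len(rows))
            )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)
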