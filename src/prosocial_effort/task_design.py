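"""Seeded construction of the two prosocial-task trial lists.

Two tasks share a 2 (recipient: self/other) x 5 (effort level) x 5 (reward
magnitude) factorial:

* the *effort task* — 200 trials (100 per recipient, each of the 25
  effort x magnitude cells four times), 8 blocks of 25, with gain and
  nongain reward feedback delivered equally often;
* the *decision task* — 150 choice trials (each effort x magnitude pair
  six times, 75 per recipient) between a high-effort option and a
  no-effort baseline worth ¥0.1, plus 20 attention-check ("catch")
  trials, 10 per recipient.

Effort levels index a fraction of the participant's calibrated maximum
press count: level i corresponds to 0.10 + 0.20*(i - 1) of maximum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EFFORT_LEVELS",
    "MAGNITUDES_YUAN",
    "BASELINE_REWARD_YUAN",
    "BASELINE_EFFORT",
    "TrialSpec",
    "effort_proportion",
    "build_effort_task_design",
    "build_decision_task_design",
    "select_payout_trials",
    "design_to_frame",
    "write_design_csv",
    "read_design_csv",
]

#: Effort-level indices (1..5); level i demands ``effort_proportion(i)`` of
#: the calibrated maximum press count.
EFFORT_LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Reward magnitudes of the high-effort options, in yuan.
MAGNITUDES_YUAN: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)

#: The decision task's no-effort baseline option: ¥0.1 for zero effort.
BASELINE_REWARD_YUAN: float = 0.1
BASELINE_EFFORT: float = 0.0

RECIPIENTS: tuple[str, str] = ("self", "other")

_TRIALS_PER_BLOCK = 25
_EFFORT_TASK_REPS_PER_CELL = 4  # 25 cells x 4 = 100 trials per recipient
_DECISION_REPS_PER_CELL = 3  # 25 cells x 3 = 75 choice trials per recipient
_N_CATCH_PER_RECIPIENT = 10
_N_PAYOUT_PER_RECIPIENT = 8


def effort_proportion(index: int) -> float:
    """Fraction of the calibrated maximum required at effort level ``index``.

    Levels 1..5 map to 0.10, 0.30, 0.50, 0.70, 0.90.
    """
    if index not in EFFORT_LEVELS:
        raise ValueError(f"effort index must be in {EFFORT_LEVELS}, got {index!r}")
    return round(0.10 + 0.20 * (index - 1), 2)


@dataclass(frozen=True)
class TrialSpec:
    """One trial of either task.

    ``valence`` is the reward-feedback outcome ("gain"/"nongain") for
    effort-task trials and ``"n/a"`` for decision-task trials, where no
    reward feedback follows the choice.
    """

    task: str  # "effort" | "decision"
    recipient: str  # "self" | "other"
    effort_index: int
    magnitude_yuan: float
    valence: str = "n/a"
    block: int = 0
    position: int = 0
    is_catch: bool = False
    is_payout: bool = False

    def __post_init__(self) -> None:
        if self.task not in ("effort", "decision"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.recipient not in RECIPIENTS:
            raise ValueError(f"unknown recipient {self.recipient!r}")
        effort_proportion(self.effort_index)  # validates index
        if self.magnitude_yuan not in MAGNITUDES_YUAN:
            raise ValueError(f"unknown magnitude {self.magnitude_yuan!r}")
        if self.task == "decision" and self.valence != "n/a":
            raise ValueError("decision trials carry no reward-feedback valence")
        if self.task == "effort" and self.valence not in ("gain", "nongain"):
            raise ValueError("effort trials need a gain/nongain valence")
        if self.is_catch and self.task != "decision":
            raise ValueError("catch trials exist only in the decision task")

    @property
    def effort_proportion(self) -> float:
        return effort_proportion(self.effort_index)


def build_effort_task_design(seed: int) -> list[TrialSpec]:
    """Build the 200-trial effort-task list for one participant.

    Each recipient x effort x magnitude cell occurs four times; within a
    cell exactly two trials end in a gain and two in a nongain, which
    enforces the equiprobable "pseudorandom" outcome schedule at the cell
    level (and hence the 50% marginal). Trial order is shuffled by
    ``seed`` and the list is cut into 8 blocks of 25.
    """
    rng = np.random.default_rng(seed)
    pool: list[TrialSpec] = []
    for recipient, eff, mag in product(RECIPIENTS, EFFORT_LEVELS, MAGNITUDES_YUAN):
        for valence in ("gain", "gain", "nongain", "nongain"):
            pool.append(
                TrialSpec(
                    task="effort",
                    recipient=recipient,
                    effort_index=eff,
                    magnitude_yuan=mag,
                    valence=valence,
                )
            )
    order = rng.permutation(len(pool))
    return [
        dataclasses.replace(
            pool[j], position=pos, block=pos // _TRIALS_PER_BLOCK + 1
        )
        for pos, j in enumerate(order)
    ]


def build_decision_task_design(seed: int) -> list[TrialSpec]:
    """Build the decision-task list: 150 choice trials plus 20 catch trials.

    Each of the 25 effort x magnitude pairs occurs six times (three per
    recipient). Catch trials (10 per recipient) probe the option just
    seen: each is placed immediately after a uniformly sampled choice
    trial of the matching recipient and copies its effort/magnitude.
    """
    rng = np.random.default_rng(seed)
    pool: list[TrialSpec] = []
    for recipient, eff, mag in product(RECIPIENTS, EFFORT_LEVELS, MAGNITUDES_YUAN):
        for _ in range(_DECISION_REPS_PER_CELL):
            pool.append(
                TrialSpec(
                    task="decision",
                    recipient=recipient,
                    effort_index=eff,
                    magnitude_yuan=mag,
                )
            )
    order = rng.permutation(len(pool))
    shuffled = [pool[j] for j in order]

    # choose, per recipient, which choice trials are followed by a catch probe
    probed: set[int] = set()
    for recipient in RECIPIENTS:
        idx = [i for i, t in enumerate(shuffled) if t.recipient == recipient]
        chosen = rng.choice(len(idx), size=_N_CATCH_PER_RECIPIENT, replace=False)
        probed.update(idx[c] for c in chosen)

    trials: list[TrialSpec] = []
    for i, t in enumerate(shuffled):
        trials.append(t)
        if i in probed:
            trials.append(dataclasses.replace(t, is_catch=True))
    return [
        dataclasses.replace(t, position=pos, block=1)
        for pos, t in enumerate(trials)
    ]


def select_payout_trials(design: Sequence[TrialSpec], seed: int) -> list[TrialSpec]:
    """Sample the 16 incentive-compatible payout trials (8 per recipient).

    Sampling is without replacement among non-catch choice trials; the
    returned trials carry ``is_payout=True`` and keep their positions in
    the design.
    """
    rng = np.random.default_rng(seed)
    selected: list[TrialSpec] = []
    for recipient in RECIPIENTS:
        candidates = [
            t for t in design if t.recipient == recipient and not t.is_catch
        ]
        if len(candidates) < _N_PAYOUT_PER_RECIPIENT:
            raise ValueError(
                f"need >= {_N_PAYOUT_PER_RECIPIENT} non-catch {recipient} trials, "
                f"got {len(candidates)}"
            )
        picks = rng.choice(len(candidates), size=_N_PAYOUT_PER_RECIPIENT, replace=False)
        selected.extend(dataclasses.replace(candidates[p], is_payout=True) for p in picks)
    return sorted(selected, key=lambda t: t.position)


# ---------------------------------------------------------------------------
# tabular views / CSV round trip

_CSV_COLUMNS = [
    "task",
    "block",
    "position",
    "recipient",
    "effort_index",
    "effort_proportion",
    "magnitude_yuan",
    "valence",
    "is_catch",
    "is_payout",
]


def design_to_frame(design: Iterable[TrialSpec]) -> pd.DataFrame:
    """Tabulate a trial list, one row per trial, in presentation order."""
    rows = [
        {
            "task": t.task,
            "block": t.block,
            "position": t.position,
            "recipient": t.recipient,
            "effort_index": t.effort_index,
            "effort_proportion": t.effort_proportion,
            "magnitude_yuan": t.magnitude_yuan,
            "valence": t.valence,
            "is_catch": t.is_catch,
            "is_payout": t.is_payout,
        }
        for t in design
    ]
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_design_csv(design: Iterable[TrialSpec], path, header_comment: str | None = None) -> None:
    frame = design_to_frame(design)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def read_design_csv(path) -> list[TrialSpec]:
    frame = pd.read_csv(path, comment="#")
    return [
        TrialSpec(
            task=row.task,
            recipient=row.recipient,
            effort_index=int(row.effort_index),
            magnitude_yuan=float(row.magnitude_yuan),
            valence=row.valence,
            block=int(row.block),
            position=int(row.position),
            is_catch=bool(row.is_catch),
            is_payout=bool(row.is_payout),
        )
        for row in frame.itertuples()
    ]
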