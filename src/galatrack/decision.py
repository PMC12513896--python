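"""Decision-time extraction from oriented 60 Hz trajectories.

Each of the 151 grid samples is categorized into a four-letter alphabet:
't' when the cursor is inside the (oriented, positive-side) target
corridor, otherwise 'l' for a step toward the target (x increased by more
than ``eps``), 'r' for a step away, and 's' for stable.  Concatenation
yields a 151-character state string per trial.

The *decision time* is the start of the last continuous movement that ends
inside the target corridor: find the latest 'lt' bigram (the last move into
the corridor), walk backwards through the maximal contiguous run of 'l',
and take the grid time of the run's first sample.  When the cursor sits
stable just outside the corridor and enters in a single frame there is no
'lt'; the latest 'st' bigram is then used instead (its 't' sample, the
moment of corridor entry), and likewise when an 'st' occurs *later* than
the last 'lt'.  Trials that are always on the target (e.g. a lucky early
guess) or that never reach it yield a typed NA.

Note on naming: 'l'/'r' mean toward/away from the target on the *oriented*
axis, not literal screen left/right.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ScreenGeometry, contrast_codes_for
from .errors import ValidationError
from .preprocess import GridSpec, NormalizedTrajectory, orient

__all__ = [
    "DEFAULT_EPS",
    "StateString",
    "DecisionResult",
    "categorize",
    "extract_decision_time",
    "count_direction_changes",
    "decision_table",
    "write_decision_table",
]

#: Stability threshold in screen widths: per-frame displacements at or below
#: this are "stable".  Far below any intentional per-frame move at 60 Hz.
DEFAULT_EPS = 1e-3

_ALPHABET = frozenset("tlrs")


@dataclass(frozen=True)
class StateString:
    """A per-sample categorization over {t, l, r, s} plus its threshold."""

    states: str
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if set(self.states) - _ALPHABET:
            raise ValidationError("state string contains characters outside {t,l,r,s}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class DecisionResult:
    """Extracted decision time or a typed NA.

    ``time_s`` is relative to target onset and present iff ``na_reason`` is
    "none"; negative times (commitment before the target word) are legal
    since the grid starts 0.5 s before onset.  ``source`` records which rule
    produced the time ("lt_backtrack" or "st_jump").
    """

    time_s: float | None
    na_reason: str = "none"  # {"none", "always_on_target", "never_reached_target"}
    source: str | None = None

    def __post_init__(self) -> None:
        if (self.time_s is None) == (self.na_reason == "none"):
            raise ValidationError("time_s must be present iff na_reason == 'none'")


def categorize(
    traj: NormalizedTrajectory,
    corridor: tuple[float, float] | None = None,
    eps: float = DEFAULT_EPS,
) -> StateString:
    """Categorize each sample of an *oriented* trajectory.

    ``corridor`` is the oriented target corridor (positive side); the
    default is the standard geometry's right corridor.  Sample 0 outside
    the corridor is 's' (no preceding step to classify).
    """
    lo, hi = corridor if corridor is not None else ScreenGeometry().corridor_right
    x = traj.x
    inside = (x >= lo) & (x <= hi)
    d = np.diff(x, prepend=x[0])  # sample 0 gets d = 0 -> 's' unless inside
    chars = np.where(d > eps, "l", np.where(d < -eps, "r", "s"))
    chars[inside] = "t"
    return StateString("".join(chars), eps=eps)


def extract_decision_time(states: StateString | str, grid: GridSpec | None = None) -> DecisionResult:
    """Apply the last-'lt' + backtrack rule with the 'st' fallback.

    Total on valid strings.  A string containing 't' but neither an 'lt'
    nor an 'st' bigram (the trial started on target and never re-entered)
    yields NA with reason "never_reached_target".
    """
    grid = grid or GridSpec()
    s = states.states if isinstance(states, StateString) else states
    if "t" not in s:
        return DecisionResult(None, "never_reached_target")
    if s == "t" * len(s):
        return DecisionResult(None, "always_on_target")
    j = s.rfind("lt")
    k = s.rfind("st")
    if j < 0 and k < 0:
        return DecisionResult(None, "never_reached_target")
    if k >= 0 and (j < 0 or k > j):
        return DecisionResult(grid.time_at(k + 1), source="st_jump")
    i = j
    while i > 0 and s[i - 1] == "l":
        i -= 1
    return DecisionResult(grid.time_at(i), source="lt_backtrack")


def count_direction_changes(
    traj: NormalizedTrajectory | np.ndarray, eps: float = DEFAULT_EPS
) -> int:
    """Number of sign alternations of the eps-thresholded step sequence.

    Steps with magnitude at or below ``eps`` are ignored; works on oriented
    or unoriented trajectories (the count is mirror-invariant).
    """
    x = traj.x if isinstance(traj, NormalizedTrajectory) else np.asarray(traj, dtype=float)
    d = np.diff(x)
    signs = np.sign(d[np.abs(d) > eps])
    if signs.size < 2:
        return 0
    return int(np.sum(signs[1:] != signs[:-1]))


# --------------------------------------------------------------------------
# per-trial decision table
# --------------------------------------------------------------------------


def decision_table(
    trajs: Sequence[NormalizedTrajectory],
    corridor: tuple[float, float] | None = None,
    eps: float = DEFAULT_EPS,
    oriented: bool = False,
) -> pd.DataFrame:
    """Build the per-trial decision table from (by default, unoriented) trajectories.

    Columns: participant, item, trial metadata, contrast codes, decision
    time (s relative to onset and ms), NA reason, extraction source, and
    the per-trial movement-direction-change count.
    """
    rows = []
    for tr in trajs:
        if tr.config is None:
            raise ValidationError("decision_table needs config-bearing trajectories")
        otr = tr if oriented else orient(tr)
        res = extract_decision_time(categorize(otr, corridor, eps), tr.grid)
        row = {
            "participant": tr.participant,
            "item": tr.config.item_id,
            "trial_index": tr.config.trial_index,
            "is_practice": tr.config.is_practice,
            "trial_class": tr.config.trial_class,
            "target_side": tr.config.target_side,
            "segment": tr.config.segment,
            "reduced": tr.config.reduced,
            "competitor": tr.config.competitor,
            "decision_time_s": res.time_s,
            "decision_time_ms": None if res.time_s is None else res.time_s * 1000.0,
            "na_reason": res.na_reason,
            "source": res.source,
            "n_direction_changes": count_direction_changes(otr, eps),
        }
        row.update(contrast_codes_for(tr.config))
        rows.append(row)
    return pd.DataFrame(rows)


def write_decision_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
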