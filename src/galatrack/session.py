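"""Session assembly and trial-log persistence.

A session comprises 5 practice trials followed by 96 experimental trials:
71 critical trials (34 /h/-initial and 37 orthographically vowel-initial,
i.e. glottal-stop-initial, items — each item exactly once per session) and
25 semantic filler trials.  Performance-overview pauses occur whenever the
trial number is divisible by 30 (trials 30, 60, 90).

Thirty-two pre-compiled orders counterbalance the within-item factors over
participants: each critical item is presented segment-present in exactly
half of the orders and segment-deleted in the other half, and each filler
item appears with its similar competitor in half of the orders and with an
unrelated distractor in the rest.  Assignment parity per item is drawn from
the seed and alternates across consecutive orders (a Latin-square-like
alternation); the trial sequence within each order is a seeded permutation.

Trial logs are written as delimited text, one row per frame, with the trial
metadata repeated on every row (header mandatory, UTF-8, '.' decimal
separator).  The reader validates the schema, strictly increasing
timestamps, and known condition codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import TrialConfig, TrialLog, contrast_code
from .errors import AssemblyError, IntegrityError, SchemaError, ValidationError

__all__ = [
    "ItemSpec",
    "ItemInventory",
    "default_inventory",
    "SessionPlan",
    "generate_orders",
    "write_session_log",
    "read_session_log",
]

N_EXPERIMENTAL = 96
N_PRACTICE = 5
FEEDBACK_EVERY = 30


@dataclass(frozen=True)
class ItemSpec:
    """One stimulus item: identity, class, and its audio timing."""

    item_id: str
    trial_class: str  # {"critical", "filler_semantic"}
    segment: str | None  # for critical items
    target_onset_s: float
    audio_dur_s: float


@dataclass(frozen=True)
class ItemInventory:
    """The stimulus pool a session design draws from."""

    critical: tuple[ItemSpec, ...]
    fillers: tuple[ItemSpec, ...]
    practice: tuple[ItemSpec, ...]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.critical + self.fillers + self.practice]


def default_inventory(seed: int = 0) -> ItemInventory:
    """Standard pool: 34 /h/ + 37 glottal-stop critical items, 25 fillers, 5 practice.

    Target onsets are drawn uniformly over the stimulus range 0.73–3.26 s
    into the audio; audio continues 0.8–2.0 s past the onset.  Timings are
    item properties, fixed by the inventory seed and shared across orders.
    """
    rng = np.random.default_rng(seed)

    def _timing():
        onset = float(rng.uniform(0.73, 3.26))
        return onset, onset + float(rng.uniform(0.8, 2.0))

    critical = []
    for i in range(34):
        onset, dur = _timing()
        critical.append(ItemSpec(f"h{i + 1:02d}", "critical", "h", onset, dur))
    for i in range(37):
        onset, dur = _timing()
        critical.append(ItemSpec(f"g{i + 1:02d}", "critical", "glottal", onset, dur))
    fillers = []
    for i in range(25):
        onset, dur = _timing()
        fillers.append(ItemSpec(f"f{i + 1:02d}", "filler_semantic", None, onset, dur))
    practice = []
    for i in range(N_PRACTICE):
        onset, dur = _timing()
        practice.append(ItemSpec(f"p{i + 1:02d}", "filler_semantic", None, onset, dur))
    return ItemInventory(tuple(critical), tuple(fillers), tuple(practice))


@dataclass(frozen=True)
class SessionPlan:
    """One pre-compiled order: practice block, 96 experimental trials, pauses."""

    order_id: int
    practice: tuple[TrialConfig, ...]
    trials: tuple[TrialConfig, ...]

    def __post_init__(self) -> None:
        if len(self.trials) != N_EXPERIMENTAL:
            raise ValidationError(f"a session holds {N_EXPERIMENTAL} experimental trials")
        if len(self.practice) != N_PRACTICE:
            raise ValidationError(f"the practice block holds {N_PRACTICE} trials")
        items = [t.item_id for t in self.trials]
        if len(set(items)) != len(items):
            raise ValidationError("each item occurs exactly once per session")

    @property
    def feedback_at(self) -> tuple[int, ...]:
        """Trial indices with a performance-overview pause (index mod 30 == 0)."""
        return tuple(
            i for i in range(FEEDBACK_EVERY, len(self.trials) + 1, FEEDBACK_EVERY)
        )


def generate_orders(
    inventory: ItemInventory,
    n_orders: int = 32,
    seed: int = 0,
) -> list[SessionPlan]:
    """Pre-compile ``n_orders`` counterbalanced session plans.

    A pure function of (inventory, n_orders, seed).  Within-item factors
    alternate across orders so that with an even ``n_orders`` every critical
    item is reduced in exactly half of the plans (and every filler paired
    with its similar competitor in half); the per-plan trial sequence and
    target sides are seeded permutations.
    """
    deficits = []
    n_crit, n_fill = len(inventory.critical), len(inventory.fillers)
    if n_crit + n_fill != N_EXPERIMENTAL:
        deficits.append(
            f"need {N_EXPERIMENTAL} experimental items, inventory supplies "
            f"{n_crit} critical + {n_fill} filler"
        )
    if len(inventory.practice) != N_PRACTICE:
        deficits.append(
            f"need {N_PRACTICE} practice items, inventory supplies {len(inventory.practice)}"
        )
    if deficits:
        raise AssemblyError("; ".join(deficits))

    rng = np.random.default_rng(seed)
    parity_crit = {it.item_id: int(rng.integers(0, 2)) for it in inventory.critical}
    parity_fill = {it.item_id: int(rng.integers(0, 2)) for it in inventory.fillers}

    plans = []
    for order in range(1, n_orders + 1):
        configs = []
        for it in inventory.critical:
            reduced = "present" if (parity_crit[it.item_id] + order) % 2 == 0 else "deleted"
            configs.append((it, {"segment": it.segment, "reduced": reduced}))
        for it in inventory.fillers:
            comp = "similar" if (parity_fill[it.item_id] + order) % 2 == 0 else "different"
            configs.append((it, {"competitor": comp}))

        sides = np.array(["left", "right"])[
            rng.permutation(np.arange(N_EXPERIMENTAL) % 2)
        ]
        perm = rng.permutation(len(configs))
        trials = tuple(
            TrialConfig(
                trial_index=pos + 1,
                target_side=str(sides[pos]),
                trial_class=it.trial_class,
                segment=codes.get("segment"),
                reduced=codes.get("reduced"),
                competitor=codes.get("competitor"),
                target_onset_s=it.target_onset_s,
                audio_dur_s=it.audio_dur_s,
                item_id=it.item_id,
            )
            for pos, (it, codes) in enumerate(configs[i] for i in perm)
        )
        practice = tuple(
            TrialConfig(
                trial_index=i + 1,
                target_side="left" if rng.random() < 0.5 else "right",
                trial_class="filler_semantic",
                is_practice=True,
                competitor="different",
                target_onset_s=it.target_onset_s,
                audio_dur_s=it.audio_dur_s,
                item_id=it.item_id,
            )
            for i, it in enumerate(inventory.practice)
        )
        plans.append(SessionPlan(order_id=order, practice=practice, trials=trials))
    return plans


# --------------------------------------------------------------------------
# session log files: one frame per row, metadata repeated
# --------------------------------------------------------------------------

_META = [
    "participant",
    "trial_index",
    "is_practice",
    "trial_class",
    "target_side",
    "segment",
    "reduced",
    "competitor",
    "target_onset_s",
    "audio_dur_s",
    "item_id",
    "click_time_s",
    "end_reason",
    "caught",
]
_FRAME = ["t", "x", "y", "button", "obj_left_x", "obj_right_x", "obj_y"]


def write_session_log(logs: Sequence[TrialLog], path: str | Path) -> None:
    """Write trial logs as frame-per-row CSV (UTF-8, '.' decimals, header)."""
    chunks = []
    for log in logs:
        cfg = log.config
        n = len(log.t)
        chunks.append(
            pd.DataFrame(
                {
                    "participant": [log.participant or ""] * n,
                    "trial_index": cfg.trial_index,
                    "is_practice": cfg.is_practice,
                    "trial_class": cfg.trial_class,
                    "target_side": cfg.target_side,
                    "segment": cfg.segment or "",
                    "reduced": cfg.reduced or "",
                    "competitor": cfg.competitor or "",
                    "target_onset_s": cfg.target_onset_s,
                    "audio_dur_s": cfg.audio_dur_s,
                    "item_id": cfg.item_id,
                    "click_time_s": "" if log.click_time_s is None else repr(log.click_time_s),
                    "end_reason": log.end_reason,
                    "caught": log.caught,
                    "t": log.t,
                    "x": log.x,
                    "y": log.y,
                    "button": np.where(log.button_down, "down", "up"),
                    "obj_left_x": log.obj_left_x,
                    "obj_right_x": log.obj_right_x,
                    "obj_y": log.obj_y,
                }
            )
        )
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False, encoding="utf-8")


def read_session_log(path: str | Path) -> list[TrialLog]:
    """Read a session log, validating schema and per-trial invariants.

    Raises :class:`SchemaError` on missing columns and
    :class:`IntegrityError` (naming the trial) on non-monotone timestamps
    or unknown condition codes.
    """
    df = pd.read_csv(path, keep_default_na=False, encoding="utf-8", float_precision="round_trip")
    missing = [c for c in _META + _FRAME if c not in df.columns]
    if missing:
        raise SchemaError(missing, path)

    logs = []
    for (participant, trial_index), grp in df.groupby(
        ["participant", "trial_index"], sort=False
    ):
        first = grp.iloc[0]
        try:
            cfg = TrialConfig(
                trial_index=int(trial_index),
                target_side=first.target_side,
                trial_class=first.trial_class,
                is_practice=str(first.is_practice).lower() == "true",
                segment=first.segment or None,
                reduced=first.reduced or None,
                competitor=first.competitor or None,
                target_onset_s=float(first.target_onset_s),
                audio_dur_s=float(first.audio_dur_s),
                item_id=first.item_id,
            )
        except ValidationError as err:
            raise IntegrityError(f"trial {trial_index}: {err}") from err
        t = grp["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise IntegrityError(
                f"non-monotone timestamps in trial {trial_index} of {path}"
            )
        click_raw = str(first.click_time_s)
        logs.append(
            TrialLog(
                config=cfg,
                t=t,
                x=grp["x"].to_numpy(dtype=float),
                y=grp["y"].to_numpy(dtype=float),
                button_down=(grp["button"] == "down").to_numpy(),
                obj_left_x=grp["obj_left_x"].to_numpy(dtype=float),
                obj_right_x=grp["obj_right_x"].to_numpy(dtype=float),
                obj_y=grp["obj_y"].to_numpy(dtype=float),
                click_time_s=None if click_raw == "" else float(click_raw),
                end_reason=first.end_reason,
                caught=str(first.caught).lower() == "true",
                participant=str(participant) or None,
            )
        )
    return logs
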