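"""Regridding of variable-frame-rate cursor logs onto a fixed 60 Hz timeline.

Host machines sample the mouse at whatever refresh rate they run, so raw
logs from different sessions live on different, irregular timelines.  Each
trial is therefore mapped onto a fixed grid from 0.5 s before target-word
onset to 2 s after it at 60 Hz (151 points, one every ~16.67 ms) by taking,
for every grid point, the *temporally nearest* observed cursor position —
no interpolation.  Grid points after the last observation receive the last
observed position ("padding", e.g. after an early click ended the trial);
points before the first observation receive the first (participants start
clicked-in on the centred spaceship).  Ties between two equidistant samples
resolve to the earlier one.

Orientation then multiplies x by −1 on left-target trials so that positive
values always mean "closer to the target", making left- and right-target
trials directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FrameSample, TrialConfig, TrialLog
from .errors import PreprocessError, SchemaError, ValidationError

__all__ = [
    "GridSpec",
    "NormalizedTrajectory",
    "regrid",
    "regrid_log",
    "orient",
    "write_trajectories",
    "read_trajectories",
]


@dataclass(frozen=True)
class GridSpec:
    """Fixed output timeline relative to target-word onset.

    Defaults: −0.5 s to +2.0 s at 60 Hz, i.e. 151 points.  ``n_points`` is
    derived in exact rational arithmetic so it can never be off by one due
    to floating-point span/rate combinations.
    """

    t_start: float = -0.5
    t_end: float = 2.0
    rate: float = 60.0

    def __post_init__(self) -> None:
        if not (self.t_start < self.t_end and self.rate > 0):
            raise ValidationError("grid needs t_start < t_end and a positive rate")

    @property
    def n_points(self) -> int:
        span = Fraction(str(self.t_end)) - Fraction(str(self.t_start))
        n = span * Fraction(str(self.rate))
        return int(round(float(n))) + 1

    def times(self) -> np.ndarray:
        """Grid times ``t_start + i / rate`` for i = 0..n_points−1 (seconds)."""
        return self.t_start + np.arange(self.n_points) / self.rate

    def time_at(self, index: int) -> float:
        return self.t_start + index / self.rate


@dataclass
class NormalizedTrajectory:
    """A 151-point regridded cursor series for one trial.

    ``x`` is unoriented straight out of :func:`regrid`; after
    :func:`orient`, positive values are closer to the target.  ``pad_from``
    is the first grid index past the last raw observation (None when the
    raw log covers the whole grid).
    """

    x: np.ndarray
    grid: GridSpec
    config: TrialConfig | None = None
    pad_from: int | None = None
    participant: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (self.grid.n_points,):
            raise ValidationError(
                f"trajectory length {self.x.shape} != grid n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.x)) or np.any(np.abs(self.x) > 0.5 + 1e-9):
            raise ValidationError("trajectory positions must be finite and within [-0.5, 0.5]")


def regrid(
    frames: Sequence[FrameSample] | tuple[np.ndarray, np.ndarray],
    target_onset_s: float,
    grid: GridSpec | None = None,
) -> NormalizedTrajectory:
    """Nearest-in-time lookup of raw cursor samples onto the grid.

    ``frames`` is either a list of :class:`FrameSample` (times measured from
    animation-routine start, which is audio start) or a ``(t, x)`` array
    pair.  Raises :class:`PreprocessError` on an empty frame list.
    """
    grid = grid or GridSpec()
    if isinstance(frames, tuple):
        t_raw, x_raw = (np.asarray(a, dtype=float) for a in frames)
    else:
        t_raw = np.array([f.t for f in frames], dtype=float)
        x_raw = np.array([f.x for f in frames], dtype=float)
    if t_raw.size == 0:
        raise PreprocessError("cannot regrid an empty frame list")
    t_rel = t_raw - target_onset_s

    g = grid.times()
    right = np.searchsorted(t_rel, g, side="left")
    left = np.clip(right - 1, 0, t_rel.size - 1)
    right = np.clip(right, 0, t_rel.size - 1)
    d_left = np.abs(g - t_rel[left])
    d_right = np.abs(t_rel[right] - g)
    # tie (equidistant) resolves to the earlier sample
    nearest = np.where(d_left <= d_right, left, right)
    x = x_raw[nearest]

    past_end = np.nonzero(g > t_rel[-1])[0]
    pad_from = int(past_end[0]) if past_end.size else None
    return NormalizedTrajectory(x=x, grid=grid, pad_from=pad_from)


def regrid_log(log: TrialLog, grid: GridSpec | None = None) -> NormalizedTrajectory:
    """Regrid a trial log's cursor record, carrying its config along."""
    traj = regrid((log.t, log.x), log.config.target_onset_s, grid)
    traj.config = log.config
    traj.participant = log.participant
    return traj


def orient(traj: NormalizedTrajectory, target_side: str | None = None) -> NormalizedTrajectory:
    """Flip x for left-target trials so positive means closer to the target.

    An involution: applying it twice returns the original trajectory.
    """
    if target_side is None:
        if traj.config is None:
            raise ValidationError("orient needs a target_side or a config-bearing trajectory")
        target_side = traj.config.target_side
    if target_side not in ("left", "right"):
        raise ValidationError(f"unknown target_side {target_side!r}")
    x = -traj.x if target_side == "left" else traj.x.copy()
    return NormalizedTrajectory(
        x=x,
        grid=traj.grid,
        config=traj.config,
        pad_from=traj.pad_from,
        participant=traj.participant,
    )


# --------------------------------------------------------------------------
# persistence: wide delimited text, one row per trial
# --------------------------------------------------------------------------

_META_COLS = [
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
    "pad_from",
]


def write_trajectories(trajs: Sequence[NormalizedTrajectory], path: str | Path) -> None:
    """Persist trajectories as wide CSV: metadata columns then x_000..x_150."""
    if not trajs:
        raise ValidationError("nothing to write")
    n = trajs[0].grid.n_points
    xcols = [f"x_{i:03d}" for i in range(n)]
    rows = []
    for tr in trajs:
        cfg = tr.config
        if cfg is None:
            raise ValidationError("can only persist config-bearing trajectories")
        row = {
            "participant": tr.participant or "",
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
            "pad_from": -1 if tr.pad_from is None else tr.pad_from,
        }
        row.update(dict(zip(xcols, tr.x)))
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLS + xcols).to_csv(path, index=False)


def read_trajectories(path: str | Path, grid: GridSpec | None = None) -> list[NormalizedTrajectory]:
    """Read back trajectories written by :func:`write_trajectories`."""
    grid = grid or GridSpec()
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    xcols = [f"x_{i:03d}" for i in range(grid.n_points)]
    missing = [c for c in _META_COLS + xcols if c not in df.columns]
    if missing:
        raise SchemaError(missing, path)
    out = []
    for _, row in df.iterrows():
        cfg = TrialConfig(
            trial_index=int(row.trial_index),
            target_side=row.target_side,
            trial_class=row.trial_class,
            is_practice=str(row.is_practice).lower() == "true",
            segment=row.segment or None,
            reduced=row.reduced or None,
            competitor=row.competitor or None,
            target_onset_s=float(row.target_onset_s),
            audio_dur_s=float(row.audio_dur_s),
            item_id=row.item_id,
        )
        pad = int(row.pad_from)
        out.append(
            NormalizedTrajectory(
                x=row[xcols].to_numpy(dtype=float),
                grid=grid,
                config=cfg,
                pad_from=None if pad < 0 else pad,
                participant=row.participant or None,
            )
        )
    return out
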