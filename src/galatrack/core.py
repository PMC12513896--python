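"""Coordinate conventions, trial configuration, and condition coding.

The game screen is modelled in resolution-independent units: horizontal
position x ∈ [−0.5, +0.5] with 0 at screen centre (where the spaceship and
cursor start), vertical position y ∈ [0, 1] from bottom to top.  The two
falling objects each wiggle inside a fixed horizontal *corridor* on their
side of the screen; corridors are closed intervals and mirror-symmetric
about x = 0, so a cursor exactly on a corridor boundary counts as inside.

A trial is described by a :class:`TrialConfig` (condition codes plus the
audio timing that drives the fall-speed adaptation) and recorded as a
:class:`TrialLog` holding one :class:`FrameSample` per display frame.

Condition factors are contrast-coded on ±0.5 with the "more" level positive:
initial segment present (+0.5) vs deleted (−0.5), /h/ (+0.5, orthographically
coded) vs glottal stop (−0.5), and target semantically predictable — i.e. the
second on-screen object is an unrelated distractor (+0.5) — vs a similar
competitor (−0.5).  Shorter times mean better performance, so facilitatory
effects are expected to appear as negative regression weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import CodingError, IntegrityError, ValidationError

__all__ = [
    "ScreenGeometry",
    "TrialConfig",
    "FrameSample",
    "TrialLog",
    "CONTRAST_SCHEMES",
    "contrast_code",
    "contrast_codes_for",
    "mirror_config",
    "load_config",
    "dump_config",
    "default_config",
]


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen layout in normalized units.

    ``catch_frac`` is the catching tolerance: a trial counts as correct when
    the final horizontal distance between spaceship and target object is
    strictly less than this fraction of the screen width (default 5%).
    """

    width: float = 1.0
    ship_y: float = 0.05
    top_y: float = 0.95
    bottom_y: float = 0.10
    corridor_left: tuple[float, float] = (-0.40, -0.08)
    corridor_right: tuple[float, float] = (0.08, 0.40)
    catch_frac: float = 0.05

    def __post_init__(self) -> None:
        ll, lh = self.corridor_left
        rl, rh = self.corridor_right
        if not (-0.5 <= ll < lh < 0.0):
            raise ValidationError(f"left corridor {self.corridor_left} must lie in [-0.5, 0)")
        if not (0.0 < rl < rh <= 0.5):
            raise ValidationError(f"right corridor {self.corridor_right} must lie in (0, 0.5]")
        if not (np.isclose(ll, -rh) and np.isclose(lh, -rl)):
            raise ValidationError("corridors must be mirror-symmetric about x = 0")
        if not self.bottom_y < self.top_y:
            raise ValidationError("bottom_y must be below top_y")
        if not 0.0 < self.catch_frac < 0.5:
            raise ValidationError("catch_frac must be in (0, 0.5)")

    def corridor(self, side: str) -> tuple[float, float]:
        """Closed x-interval of the object corridor on ``side`` ('left'/'right')."""
        if side == "left":
            return self.corridor_left
        if side == "right":
            return self.corridor_right
        raise ValidationError(f"unknown side {side!r}")


# --------------------------------------------------------------------------
# trial configuration
# --------------------------------------------------------------------------

_SIDES = ("left", "right")
_CLASSES = ("critical", "filler_semantic")


@dataclass(frozen=True)
class TrialConfig:
    """Per-trial metadata: condition codes and audio timing.

    Critical trials carry the reduction design (``segment`` × ``reduced``);
    semantic filler trials carry only the ``competitor`` factor.  The target
    onset and the total audio duration are properties of the recorded
    sentence and drive the fall-speed adaptation.
    """

    trial_index: int
    target_side: str
    trial_class: str = "critical"
    is_practice: bool = False
    segment: str | None = None      # {"h", "glottal"} on critical trials
    reduced: str | None = None      # {"present", "deleted"} on critical trials
    competitor: str | None = None   # {"similar", "different"} on filler trials
    target_onset_s: float = 1.5
    audio_dur_s: float = 3.0
    item_id: str = "item"

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValidationError("trial_index is 1-based")
        if self.target_side not in _SIDES:
            raise ValidationError(f"unknown target_side {self.target_side!r}")
        if self.trial_class not in _CLASSES:
            raise ValidationError(f"unknown trial_class {self.trial_class!r}")
        if not 0.0 < self.target_onset_s < self.audio_dur_s:
            raise ValidationError(
                f"need 0 < target_onset_s < audio_dur_s, got "
                f"{self.target_onset_s} / {self.audio_dur_s}"
            )
        if self.trial_class == "critical":
            if self.segment not in ("h", "glottal") or self.reduced not in ("present", "deleted"):
                raise ValidationError("critical trials need segment and reduced codes")
            if self.competitor is not None:
                raise ValidationError("critical trials carry no competitor code")
        else:
            if self.competitor not in ("similar", "different"):
                raise ValidationError("filler trials need a competitor code")
            if self.segment is not None or self.reduced is not None:
                raise ValidationError("filler trials carry no segment/reduced codes")


def mirror_config(config: TrialConfig) -> TrialConfig:
    """Swap the target side.  An involution: mirroring twice is the identity."""
    other = "left" if config.target_side == "right" else "right"
    return replace(config, target_side=other)


# --------------------------------------------------------------------------
# frame samples and trial logs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSample:
    """One display frame: time since animation start, cursor position, button."""

    t: float
    x: float
    y: float
    button: str = "up"  # {"up", "down"}


_END_REASONS = ("click", "audio_tail", "objects_reached_bottom")


@dataclass
class TrialLog:
    """Frame-stamped record of one animation routine.

    Arrays are aligned per frame.  ``click_time_s`` is absent (None) iff the
    routine ended because the objects reached the lowest point.
    ``end_reason`` distinguishes a click after audio offset ("click") from a
    click while the sound was still playing ("audio_tail", routine ends
    200 ms after the sound finishes).
    """

    config: TrialConfig
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    button_down: np.ndarray
    obj_left_x: np.ndarray
    obj_right_x: np.ndarray
    obj_y: np.ndarray
    click_time_s: float | None
    end_reason: str
    caught: bool
    participant: str | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "button_down", "obj_left_x", "obj_right_x", "obj_y"):
            if len(getattr(self, name)) != n:
                raise IntegrityError(f"frame column {name} has wrong length")
        if n and (self.t[0] < 0 or np.any(np.diff(self.t) <= 0)):
            raise IntegrityError(
                f"timestamps must be non-negative and strictly increasing "
                f"(trial {self.config.trial_index})"
            )
        if self.end_reason not in _END_REASONS:
            raise ValidationError(f"unknown end_reason {self.end_reason!r}")
        if self.click_time_s is None and self.end_reason != "objects_reached_bottom":
            raise IntegrityError("no click implies end_reason = objects_reached_bottom")

    @property
    def frames(self) -> list[FrameSample]:
        return [
            FrameSample(float(t), float(x), float(y), "down" if b else "up")
            for t, x, y, b in zip(self.t, self.x, self.y, self.button_down)
        ]

    @property
    def duration_s(self) -> float:
        """Routine span from animation start to the last emitted frame."""
        return float(self.t[-1]) if len(self.t) else 0.0


# --------------------------------------------------------------------------
# contrast coding
# --------------------------------------------------------------------------

#: Factor-level → ±0.5 maps.  The "more" level is always positive: segment
#: present, /h/ (orthographically coded), and target-predictable (the second
#: object is an unrelated, hence "different", distractor).
CONTRAST_SCHEMES: Mapping[str, Mapping[str, float]] = {
    "reduced": {"present": +0.5, "deleted": -0.5},
    "segment": {"h": +0.5, "glottal": -0.5},
    "competitor": {"different": +0.5, "similar": -0.5},
}


def contrast_code(level: str, scheme: Mapping[str, float] | str) -> float:
    """Signed half-unit code for a factor level.

    ``scheme`` is either one of the named schemes in :data:`CONTRAST_SCHEMES`
    or an explicit level → code mapping.

    Raises
    ------
    CodingError
        If the level is not part of the scheme.
    """
    if isinstance(scheme, str):
        try:
            scheme = CONTRAST_SCHEMES[scheme]
        except KeyError:
            raise CodingError(f"unknown contrast scheme {scheme!r}") from None
    try:
        return scheme[level]
    except KeyError:
        raise CodingError(f"unknown factor level {level!r} for scheme {dict(scheme)}") from None


def contrast_codes_for(config: TrialConfig) -> dict[str, float]:
    """All applicable contrast codes for a trial, keyed by factor name."""
    if config.trial_class == "critical":
        return {
            "cuesC": contrast_code(config.reduced, "reduced"),
            "segmentC": contrast_code(config.segment, "segment"),
        }
    return {"competitorC": contrast_code(config.competitor, "competitor")}


# --------------------------------------------------------------------------
# flat key-value configuration files
# --------------------------------------------------------------------------


def _parse_scalar(text: str):
    text = text.strip()
    low = text.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def load_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` config file into a typed dict."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = _parse_scalar(value)
    return out


def dump_config(config: Mapping, path: str | Path) -> None:
    """Write a flat typed mapping as ``key = value`` lines (UTF-8)."""
    lines = [f"{k} = {v}" for k, v in config.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_config() -> dict:
    """All tunable defaults as one flat mapping (dumpable via the CLI).

    Keys are namespaced by module: ``geometry.*``, ``kinematics.*``,
    ``population.*``, ``screening.*``, ``grid.*``.
    """
    geom = ScreenGeometry()
    return {
        "geometry.ship_y": geom.ship_y,
        "geometry.top_y": geom.top_y,
        "geometry.bottom_y": geom.bottom_y,
        "geometry.corridor_inner": geom.corridor_right[0],
        "geometry.corridor_outer": geom.corridor_right[1],
        "geometry.catch_frac": geom.catch_frac,
        "kinematics.fps": 60,
        "kinematics.flip_prob": 1.0 / 40.0,
        "kinematics.min_post_onset_s": 2.0,
        "kinematics.base_fall_s": 3.0,
        "kinematics.tail_s": 0.2,
        "kinematics.speed_x": 0.25,
        "kinematics.timestamp_jitter_s": 0.0,
        "population.n_participants": 40,
        "population.clicker_frac": 0.8,
        "population.base_commit_mean_s": 0.55,
        "population.base_commit_sd_s": 0.08,
        "population.commit_noise_sd_s": 0.15,
        "population.track_lag_s": 0.15,
        "population.jitter_sd": 0.005,
        "population.click_delay_s": 0.35,
        "population.guess_prob": 0.05,
        "population.effect_reduced_s": 0.05,
        "population.effect_similar_competitor_s": 0.13,
        "population.item_sd_s": 0.05,
        "screening.accuracy_threshold": 0.70,
        "screening.max_trial_dur_s": 5.2,
        "screening.rt_resid_cutoff": 3.0,
        "grid.t_start": -0.5,
        "grid.t_end": 2.0,
        "grid.rate": 60,
        "decision.eps": 1e-3,
    }


def geometry_from_config(config: Mapping) -> ScreenGeometry:
    """Build a :class:`ScreenGeometry` from a flat config mapping."""
    inner = float(config.get("geometry.corridor_inner", 0.08))
    outer = float(config.get("geometry.corridor_outer", 0.40))
    return ScreenGeometry(
        ship_y=float(config.get("geometry.ship_y", 0.05)),
        top_y=float(config.get("geometry.top_y", 0.95)),
        bottom_y=float(config.get("geometry.bottom_y", 0.10)),
        corridor_left=(-outer, -inner),
        corridor_right=(inner, outer),
        catch_frac=float(config.get("geometry.catch_frac", 0.05)),
    )
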