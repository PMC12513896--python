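"""Frame-based generative model of the animation routine.

Two objects fall at a constant per-frame rate while wiggling horizontally
inside their corridors: on every frame each object draws a uniform number
and reverses direction when it is below ``flip_prob`` (default 1/40), or —
with precedence, and consuming the same draw — when the next step would
leave the corridor.  The fall duration adapts to the audio so that the
objects reach the lowest point no earlier than ``min_post_onset_s``
(default 2 s) after target-word onset.

The routine ends (a) 200 ms after a mouse click if the sound has finished,
(b) 200 ms after the sound finishes if the click came earlier, or (c) when
the objects reach the point just above the spaceship if no click occurs.
All animations freeze at the click.

Internally each trial is simulated in a *target-oriented* frame: both
objects live in the positive corridor, the cursor relaxes toward the chosen
object, and screen coordinates are obtained by a final sign flip for
left-target trials.  This makes a trial and its mirrored twin exact
negations of each other for the same seed, which the analysis relies on.

Randomness is drawn per trial from ``numpy.random.default_rng(seed)`` in a
fixed order (start fractions, initial headings, per-frame flip draws for
target then distractor, commitment draws, cursor noise, timestamp jitter),
so logs are bit-identical functions of (config, seed) and independent of
batch composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .agents import AgentProfile, agent_policy, draw_commitment
from .core import ScreenGeometry, TrialConfig, TrialLog
from .errors import SimulationError, ValidationError

__all__ = [
    "KinematicsParams",
    "ObjectState",
    "adjust_fall_duration",
    "step_object",
    "adjudicate_catch",
    "simulate_trial",
    "simulate_trials",
]


@dataclass(frozen=True)
class KinematicsParams:
    """Tunables of the animation routine.

    ``speed_x`` is in screen widths per second (0.25 lets an object traverse
    the default 0.32-wide corridor in about 1.3 s).  ``timestamp_jitter_s``
    emulates imprecise host frame clocks (±1 ms, off by default); set
    ``fps`` to 30/75/144 etc. to emulate heterogeneous host refresh rates.
    """

    fps: float = 60.0
    flip_prob: float = 1.0 / 40.0
    min_post_onset_s: float = 2.0
    base_fall_s: float = 3.0
    tail_s: float = 0.2
    speed_x: float = 0.25
    timestamp_jitter_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_prob < 1.0:
            raise ValidationError("flip_prob must be in (0, 1)")
        if self.min_post_onset_s <= 0 or self.fps <= 0 or self.base_fall_s <= 0:
            raise ValidationError("fps, base_fall_s and min_post_onset_s must be positive")
        if self.timestamp_jitter_s < 0 or self.timestamp_jitter_s >= 0.5 / self.fps:
            if self.timestamp_jitter_s != 0.0:
                raise ValidationError("timestamp jitter must be below half a frame period")


@dataclass(frozen=True)
class ObjectState:
    """One falling object; speeds are per frame, ``dir`` ∈ {−1, +1}."""

    x: float
    y: float
    dir: int
    speed_x: float
    speed_y: float


def adjust_fall_duration(
    target_onset_s: float, base_fall_s: float, min_post_onset_s: float
) -> float:
    """Fall duration guaranteeing at least ``min_post_onset_s`` after onset.

    Returns ``max(base_fall_s, target_onset_s + min_post_onset_s)``; the
    per-frame descent is then ``(top_y - bottom_y) / (result * fps)``.
    """
    if target_onset_s <= 0 or base_fall_s <= 0 or min_post_onset_s <= 0:
        raise ValidationError("fall-duration inputs must be positive")
    return max(base_fall_s, target_onset_s + min_post_onset_s)


def step_object(
    state: ObjectState,
    corridor: tuple[float, float],
    params: KinematicsParams,
    u: float,
) -> ObjectState:
    """Advance one object by one frame given the uniform draw ``u``.

    The direction flips iff the candidate position would leave the corridor
    (boundary flip, takes precedence) or ``u < flip_prob``; at most one flip
    per frame.  x then advances with the post-flip heading and is clamped to
    the corridor; y decreases by the per-frame fall speed.
    """
    lo, hi = corridor
    if not lo <= state.x <= hi:
        raise SimulationError(f"object x={state.x} outside corridor {corridor}")
    cand = state.x + state.dir * state.speed_x
    if cand < lo or cand > hi:
        d = -state.dir
    elif u < params.flip_prob:
        d = -state.dir
    else:
        d = state.dir
    x = min(max(state.x + d * state.speed_x, lo), hi)
    return ObjectState(x, max(state.y - state.speed_y, 0.0), d, state.speed_x, state.speed_y)


def adjudicate_catch(ship_x: float, target_x: float, catch_frac: float) -> bool:
    """True iff |ship − target| is *strictly* below the catch tolerance."""
    if not (-0.5 <= ship_x <= 0.5 and -0.5 <= target_x <= 0.5):
        raise ValidationError("positions must lie in [-0.5, 0.5]")
    return abs(ship_x - target_x) < catch_frac


# --------------------------------------------------------------------------
# trial simulation
# --------------------------------------------------------------------------


def _n_steps(fall_s: float, fps: float) -> int:
    # ceil so the last frame time n/fps is never earlier than the nominal
    # fall end; the >=2 s post-onset guarantee then holds on the emitted log.
    return math.ceil(fall_s * fps - 1e-9)


def _object_paths_batch(
    x0: np.ndarray,
    dir0: np.ndarray,
    u: np.ndarray,
    speed_x_frame: float,
    corridor: tuple[float, float],
    flip_prob: float,
) -> np.ndarray:
    """Positive-corridor wiggle paths, vectorized across trials.

    Shapes: ``x0``/``dir0`` (K, 2), ``u`` (K, n_max, 2); returns
    (K, n_max+1, 2).  Must replicate :func:`step_object` exactly.
    """
    lo, hi = corridor
    K = x0.shape[0]
    n_max = u.shape[1]
    out = np.empty((K, n_max + 1, 2))
    x = x0.copy()
    d = dir0.astype(float).copy()
    out[:, 0, :] = x
    for i in range(n_max):
        cand = x + d * speed_x_frame
        flip = (cand < lo) | (cand > hi) | (u[:, i, :] < flip_prob)
        d = np.where(flip, -d, d)
        x = np.clip(x + d * speed_x_frame, lo, hi)
        out[:, i + 1, :] = x
    return out


def simulate_trials(
    configs: Sequence[TrialConfig],
    geometry: ScreenGeometry,
    params: KinematicsParams,
    agents: Sequence[AgentProfile],
    seeds: Sequence[int],
    participant: str | None = None,
    item_shifts: dict | None = None,
    item_effect_shifts: dict | None = None,
) -> list[TrialLog]:
    """Simulate a batch of trials (vectorized object stepping across trials).

    Each trial's randomness comes only from its own seed, so the result for
    a given (config, seed) pair is identical whether simulated alone or in a
    batch.  ``item_shifts`` optionally maps item_id to an additive
    commitment shift shared across participants (item random intercepts);
    ``item_effect_shifts`` adds a per-item deviation applied only on
    reduced (segment-deleted) trials (item random slopes for the reduction
    effect).
    """
    if not (len(configs) == len(agents) == len(seeds)):
        raise ValidationError("configs, agents and seeds must have equal length")
    K = len(configs)
    if K == 0:
        return []
    fps = params.fps
    corridor = geometry.corridor_right  # positive-space corridor, both roles
    lo, hi = corridor
    sx = params.speed_x / fps

    falls = np.array(
        [
            adjust_fall_duration(c.target_onset_s, params.base_fall_s, params.min_post_onset_s)
            for c in configs
        ]
    )
    nsteps = np.array([_n_steps(f, fps) for f in falls])
    n_max = int(nsteps.max())

    x0 = np.empty((K, 2))
    dir0 = np.empty((K, 2), dtype=int)
    u_all = np.ones((K, n_max, 2))  # padded draws are never < flip_prob-relevant
    commits = np.empty(K)
    sides = []
    noise = np.zeros((K, n_max + 1))
    tjit = np.zeros((K, n_max + 1))
    for k, (cfg, agent, seed) in enumerate(zip(configs, agents, seeds)):
        rng = np.random.default_rng(seed)
        frac = rng.random(2)
        x0[k] = lo + frac * (hi - lo)
        dir0[k] = rng.integers(0, 2, size=2) * 2 - 1
        n = nsteps[k]
        u_all[k, :n, :] = rng.random((n, 2))
        shift = (item_shifts or {}).get(cfg.item_id, 0.0)
        if cfg.trial_class == "critical" and cfg.reduced == "deleted":
            shift += (item_effect_shifts or {}).get(cfg.item_id, 0.0)
        commit_rel, side = draw_commitment(agent, cfg, rng, extra_shift=shift)
        commits[k] = cfg.target_onset_s + commit_rel
        sides.append(side)
        noise[k, : n + 1] = rng.standard_normal(n + 1)
        if params.timestamp_jitter_s > 0:
            tjit[k, 1 : n + 1] = rng.uniform(
                -params.timestamp_jitter_s, params.timestamp_jitter_s, n
            )

    paths = _object_paths_batch(x0, dir0, u_all, sx, corridor, params.flip_prob)

    logs: list[TrialLog] = []
    for k, (cfg, agent) in enumerate(zip(configs, agents)):
        n = int(nsteps[k])
        times = np.arange(n + 1) / fps + tjit[k, : n + 1]
        p_target = paths[k, : n + 1, 0]
        p_distr = paths[k, : n + 1, 1]
        dy = (geometry.top_y - geometry.bottom_y) / (falls[k] * fps)
        obj_y = np.maximum(geometry.top_y - np.arange(n + 1) * dy, geometry.bottom_y)

        # oriented chosen-object path: distractor lives on the negative side
        chosen = p_target if sides[k] == cfg.target_side else -p_distr
        c = agent_policy(agent, commits[k], times, chosen, fps)
        if np.any(np.abs(c) > 0.5 + 1e-9):
            raise SimulationError("agent produced a cursor position outside [-0.5, 0.5]")
        emitted = np.clip(c + agent.jitter_sd * noise[k, : n + 1], -0.5, 0.5)

        ic = None
        if agent.is_clicker:
            eligible = (times >= commits[k] + agent.click_delay_s) & (
                np.abs(c - chosen) < geometry.catch_frac
            )
            hits = np.nonzero(eligible)[0]
            if hits.size:
                ic = int(hits[0])

        sign = 1.0 if cfg.target_side == "right" else -1.0
        if ic is None:
            last = n
            click_t = None
            end_reason = "objects_reached_bottom"
            t_out = times
            e_out = emitted
            pt_out, pd_out = p_target, p_distr
            y_out = obj_y
            button = np.zeros(n + 1, dtype=bool)
        else:
            click_t = float(times[ic])
            if click_t >= cfg.audio_dur_s:
                end_reason = "click"
                end_time = click_t + params.tail_s
            else:
                end_reason = "audio_tail"
                end_time = cfg.audio_dur_s + params.tail_s
            # frozen padding frames on the nominal frame grid, final frame
            # exactly at the routine end
            pad_idx = np.arange(ic + 1, math.floor(end_time * fps - 1e-9) + 1)
            pad_t = pad_idx / fps
            pad_t = pad_t[pad_t > times[ic]]
            if pad_t.size == 0 or end_time - pad_t[-1] > 1e-9:
                pad_t = np.append(pad_t, end_time)
            npad = pad_t.size
            t_out = np.concatenate([times[: ic + 1], pad_t])
            e_out = np.concatenate([emitted[: ic + 1], np.full(npad, emitted[ic])])
            pt_out = np.concatenate([p_target[: ic + 1], np.full(npad, p_target[ic])])
            pd_out = np.concatenate([p_distr[: ic + 1], np.full(npad, p_distr[ic])])
            y_out = np.concatenate([obj_y[: ic + 1], np.full(npad, obj_y[ic])])
            button = np.zeros(t_out.size, dtype=bool)
            button[ic:] = True

        target_screen = sign * pt_out
        distr_screen = -sign * pd_out
        if cfg.target_side == "right":
            obj_left, obj_right = distr_screen, target_screen
        else:
            obj_left, obj_right = target_screen, distr_screen

        caught = adjudicate_catch(
            float(e_out[-1]), float(pt_out[-1]), geometry.catch_frac
        )
        logs.append(
            TrialLog(
                config=cfg,
                t=t_out,
                x=sign * e_out,
                y=np.full(t_out.size, geometry.ship_y),
                button_down=button,
                obj_left_x=obj_left,
                obj_right_x=obj_right,
                obj_y=y_out,
                click_time_s=click_t,
                end_reason=end_reason,
                caught=caught,
                participant=participant,
            )
        )
    return logs


def simulate_trial(
    config: TrialConfig,
    geometry: ScreenGeometry,
    params: KinematicsParams,
    agent: AgentProfile,
    seed: int,
) -> TrialLog:
    """Simulate one trial; a thin wrapper over :func:`simulate_trials`."""
    return simulate_trials([config], geometry, params, [agent], [seed])[0]
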