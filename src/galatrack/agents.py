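"""Synthetic participants with latent commitment times.

An agent keeps the cursor at the screen centre until its *commitment time*
(a latent latency after target-word onset, shifted additively by the
experimental condition), then relaxes the cursor exponentially toward the
chosen object's current position with time constant ``track_lag_s``.
Clickers fire the tractor beam ``click_delay_s`` after committing, as soon
as the cursor is within the catch tolerance of the chosen object;
non-clickers wait for the objects to fall, so their trials end without a
reaction time — reproducing the structural missingness of participants who
never click.

With probability ``guess_prob`` the agent guesses a side before the target
word is heard; correct guesses produce always-on-target trials (decision
time undefined), wrong guesses produce misses, and guess-driven clicks can
land before target onset, exercising the early-click screen.

The commitment times are the ground truth against which pipeline recovery
is tested: condition shifts injected here should reappear (negated for the
+0.5 coding of the facilitating level) in the fitted decision-time models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .core import TrialConfig
from .errors import ValidationError

__all__ = [
    "AgentProfile",
    "draw_commitment",
    "agent_policy",
    "sample_population",
    "draw_item_shifts",
]

#: effect_map keys and the trial predicate that makes each shift applicable
_EFFECT_PREDICATES = {
    "reduced": lambda c: c.trial_class == "critical" and c.reduced == "deleted",
    "glottal": lambda c: c.trial_class == "critical" and c.segment == "glottal",
    "similar_competitor": lambda c: c.trial_class == "filler_semantic"
    and c.competitor == "similar",
}


@dataclass(frozen=True)
class AgentProfile:
    """Latent response parameters of one simulated participant.

    All latencies are in seconds; ``jitter_sd`` is white positional noise on
    the emitted cursor sample in screen-width units.  ``effect_map`` holds
    additive commitment shifts keyed by condition ("reduced" applies on
    trials with the initial segment deleted, "similar_competitor" on filler
    trials whose second object also fits the sentence).
    """

    base_commit_s: float = 0.55
    effect_map: Mapping[str, float] = field(default_factory=dict)
    track_lag_s: float = 0.15
    jitter_sd: float = 0.005
    is_clicker: bool = True
    click_delay_s: float = 0.35
    guess_prob: float = 0.05
    commit_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if min(self.base_commit_s, self.track_lag_s, self.click_delay_s) < 0:
            raise ValidationError("agent latencies must be non-negative")
        if not 0.0 <= self.guess_prob <= 1.0:
            raise ValidationError("guess_prob must be in [0, 1]")
        if self.jitter_sd < 0 or self.commit_noise_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        unknown = set(self.effect_map) - set(_EFFECT_PREDICATES)
        if unknown:
            raise ValidationError(f"unknown effect_map keys: {sorted(unknown)}")

    def applicable_shift(self, config: TrialConfig) -> float:
        """Sum of effect_map shifts whose condition holds on this trial."""
        return sum(
            shift for key, shift in self.effect_map.items() if _EFFECT_PREDICATES[key](config)
        )


def draw_commitment(
    agent: AgentProfile,
    config: TrialConfig,
    rng: np.random.Generator,
    extra_shift: float = 0.0,
) -> tuple[float, str]:
    """Draw (commitment time relative to target onset, chosen side).

    Normally ``base + condition shifts + extra_shift + N(0, commit_noise_sd)``
    toward the target side.  With probability ``guess_prob`` the agent
    instead commits to a uniformly random side at a uniform time before
    onset (returned as a negative latency).
    """
    if rng.random() < agent.guess_prob:
        # the guessed side is drawn in role space (target vs distractor, each
        # p = 1/2) so a trial and its mirrored twin share the same outcome
        other = "left" if config.target_side == "right" else "right"
        side = config.target_side if rng.random() < 0.5 else other
        commit_abs = rng.uniform(0.0, config.target_onset_s)
        return commit_abs - config.target_onset_s, side
    noise = rng.normal(0.0, agent.commit_noise_sd) if agent.commit_noise_sd > 0 else 0.0
    shift = agent.applicable_shift(config) + extra_shift
    return agent.base_commit_s + shift + noise, config.target_side


def agent_policy(
    agent: AgentProfile,
    commitment_abs_s: float,
    times: np.ndarray,
    target_x: np.ndarray,
    fps: float,
) -> np.ndarray:
    """Noise-free cursor state at each frame time.

    Zero (screen centre) while ``t <= commitment``; afterwards the first-order
    relaxation ``c_i = alpha * c_{i-1} + (1 - alpha) * o_i`` toward the chosen
    object's current position ``o_i``, with ``alpha = exp(-1 / (fps * lag))``.
    In the ``track_lag_s -> 0`` limit the cursor equals the object position
    at every post-commitment frame.
    """
    times = np.asarray(times, dtype=float)
    target_x = np.asarray(target_x, dtype=float)
    c = np.zeros_like(times)
    m = int(np.searchsorted(times, commitment_abs_s, side="right"))
    if m >= len(times):
        return c
    if agent.track_lag_s <= 0:
        c[m:] = target_x[m:]
        return c
    alpha = math.exp(-1.0 / (fps * agent.track_lag_s))
    c[m:] = lfilter([1.0 - alpha], [1.0, -alpha], target_x[m:])
    return c


def sample_population(
    n: int,
    seed: int,
    clicker_frac: float = 0.8,
    base_commit_mean_s: float = 0.55,
    base_commit_sd_s: float = 0.08,
    effect_map: Mapping[str, float] | None = None,
    effect_sd_s: float = 0.02,
    track_lag_s: float = 0.15,
    jitter_sd: float = 0.005,
    click_delay_s: float = 0.35,
    guess_prob: float = 0.05,
    commit_noise_sd: float = 0.15,
) -> list[AgentProfile]:
    """Seeded population of agents with participant-level baseline variation.

    Baselines are normal around ``base_commit_mean_s`` (truncated at 50 ms so
    latencies stay positive); roughly ``clicker_frac`` of agents are
    clickers, echoing the observed preponderance of click-enders.  Condition
    effects vary across participants around the population ``effect_map``
    with SD ``effect_sd_s`` (participant random slopes).
    """
    rng = np.random.default_rng(seed)
    effect_map = dict(effect_map or {})
    agents = []
    for _ in range(n):
        base = max(0.05, rng.normal(base_commit_mean_s, base_commit_sd_s))
        is_clicker = bool(rng.random() < clicker_frac)
        emap = {
            k: v + (rng.normal(0.0, effect_sd_s) if effect_sd_s > 0 else 0.0)
            for k, v in effect_map.items()
        }
        agents.append(
            AgentProfile(
                base_commit_s=base,
                effect_map=emap,
                track_lag_s=track_lag_s,
                jitter_sd=jitter_sd,
                is_clicker=is_clicker,
                click_delay_s=click_delay_s,
                guess_prob=guess_prob,
                commit_noise_sd=commit_noise_sd,
            )
        )
    return agents


def draw_item_shifts(item_ids: Sequence[str], sd_s: float, seed: int) -> dict[str, float]:
    """Zero-mean normal commitment shifts per item, shared across participants."""
    rng = np.random.default_rng(seed)
    return {item: float(rng.normal(0.0, sd_s)) for item in item_ids}
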