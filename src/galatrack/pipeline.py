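"""End-to-end orchestration: simulate → preprocess → decide → screen → analyze.

Library-level stage functions used both by the command-line interface and
by recovery experiments.  Each stage consumes and produces plain data
(lists of logs, trajectories, DataFrames), so any stage can be resumed
from files written by the previous one.

All randomness of a study flows from one master seed through named
sub-seeds (inventory, orders, population, item effects, per-trial), so a
study is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agents import draw_item_shifts, sample_population
from .core import ScreenGeometry, TrialLog
from .decision import DEFAULT_EPS, decision_table
from .dynamics import KinematicsParams, simulate_trials
from .preprocess import GridSpec, NormalizedTrajectory, orient, regrid_log
from .screening import ScreeningReport, screen_logs
from .session import ItemInventory, default_inventory, generate_orders

__all__ = [
    "StudySettings",
    "simulate_study",
    "trajectories_from_logs",
    "decisions_from_logs",
    "screen_and_tabulate",
    "reaction_time_table",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class StudySettings:
    """Study-level generator settings (the simulated population and stimuli).

    Defaults emulate the paradigm's observed regime: ~550 ms mean
    commitment latency after target onset, a +50 ms reduction cost and a
    +130 ms similar-competitor cost on commitment, 80% clickers, 5%
    pre-onset guessers, and 50 ms between-item variability.
    """

    n_participants: int = 40
    n_orders: int = 32
    clicker_frac: float = 0.8
    base_commit_mean_s: float = 0.55
    base_commit_sd_s: float = 0.08
    commit_noise_sd_s: float = 0.15
    effect_map: Mapping[str, float] = field(
        default_factory=lambda: {"reduced": 0.05, "similar_competitor": 0.13}
    )
    effect_sd_s: float = 0.02
    track_lag_s: float = 0.15
    jitter_sd: float = 0.005
    click_delay_s: float = 0.35
    guess_prob: float = 0.05
    item_sd_s: float = 0.05
    item_effect_sd_s: float = 0.02
    include_practice: bool = False


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, _SEED_MOD, size=n)]


def simulate_study(
    seed: int,
    settings: StudySettings | None = None,
    geometry: ScreenGeometry | None = None,
    params: KinematicsParams | None = None,
    inventory: ItemInventory | None = None,
) -> list[TrialLog]:
    """Simulate a whole multi-participant study from one master seed.

    Participant ``p`` runs pre-compiled order ``p mod n_orders`` with their
    own agent profile; item random intercepts (and reduction-effect
    deviations) are shared across participants.
    """
    settings = settings or StudySettings()
    geometry = geometry or ScreenGeometry()
    params = params or KinematicsParams()
    s_inv, s_orders, s_pop, s_item, s_item_eff, s_trials = _subseeds(seed, 6)
    inventory = inventory or default_inventory(s_inv)
    plans = generate_orders(inventory, settings.n_orders, s_orders)
    agents = sample_population(
        settings.n_participants,
        s_pop,
        clicker_frac=settings.clicker_frac,
        base_commit_mean_s=settings.base_commit_mean_s,
        base_commit_sd_s=settings.base_commit_sd_s,
        effect_map=dict(settings.effect_map),
        effect_sd_s=settings.effect_sd_s,
        track_lag_s=settings.track_lag_s,
        jitter_sd=settings.jitter_sd,
        click_delay_s=settings.click_delay_s,
        guess_prob=settings.guess_prob,
        commit_noise_sd=settings.commit_noise_sd_s,
    )
    item_shifts = draw_item_shifts(inventory.item_ids, settings.item_sd_s, s_item)
    critical_ids = [it.item_id for it in inventory.critical]
    item_effect_shifts = draw_item_shifts(critical_ids, settings.item_effect_sd_s, s_item_eff)

    trial_rng = np.random.default_rng(s_trials)
    logs: list[TrialLog] = []
    for p, agent in enumerate(agents):
        plan = plans[p % len(plans)]
        configs = list(plan.practice) + list(plan.trials) if settings.include_practice else list(
            plan.trials
        )
        seeds = [int(s) for s in trial_rng.integers(0, _SEED_MOD, size=len(configs))]
        logs.extend(
            simulate_trials(
                configs,
                geometry,
                params,
                [agent] * len(configs),
                seeds,
                participant=f"p{p + 1:03d}",
                item_shifts=item_shifts,
                item_effect_shifts=item_effect_shifts,
            )
        )
    return logs


def trajectories_from_logs(
    logs: Sequence[TrialLog], grid: GridSpec | None = None, oriented: bool = True
) -> list[NormalizedTrajectory]:
    """Regrid (and by default orient) every log's cursor record."""
    grid = grid or GridSpec()
    trajs = [regrid_log(log, grid) for log in logs]
    return [orient(tr) for tr in trajs] if oriented else trajs


def decisions_from_logs(
    logs: Sequence[TrialLog],
    grid: GridSpec | None = None,
    geometry: ScreenGeometry | None = None,
    eps: float = DEFAULT_EPS,
) -> pd.DataFrame:
    """Regrid, orient, and extract the per-trial decision table."""
    geometry = geometry or ScreenGeometry()
    trajs = trajectories_from_logs(logs, grid, oriented=True)
    return decision_table(trajs, corridor=geometry.corridor_right, eps=eps, oriented=True)


def screen_and_tabulate(
    logs: Sequence[TrialLog],
    grid: GridSpec | None = None,
    geometry: ScreenGeometry | None = None,
    eps: float = DEFAULT_EPS,
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Participant gate + trial filters, then decision extraction.

    The returned table contains only surviving trials; always-on-target
    losses are counted into the report (their rows stay, with NA decision
    times, for loss accounting downstream).
    """
    kept, report = screen_logs(logs)
    table = decisions_from_logs(kept, grid, geometry, eps)
    report.trials_lost_always_on_target = int((table.na_reason == "always_on_target").sum())
    return table, report


def reaction_time_table(logs: Sequence[TrialLog]) -> pd.DataFrame:
    """Clicker reaction times: click time − target onset, in seconds.

    Only trials ended by a click contribute; non-clickers are structurally
    absent.  Columns: participant, item, rt (plus condition codes for
    grouping).
    """
    rows = []
    for log in logs:
        if log.click_time_s is None or log.config.is_practice:
            continue
        cfg = log.config
        rows.append(
            {
                "participant": log.participant,
                "item": cfg.item_id,
                "trial_class": cfg.trial_class,
                "reduced": cfg.reduced,
                "segment": cfg.segment,
                "competitor": cfg.competitor,
                "rt": log.click_time_s - cfg.target_onset_s,
            }
        )
    return pd.DataFrame(rows)
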