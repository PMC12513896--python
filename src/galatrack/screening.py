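"""Participant- and trial-level exclusions and reaction-time trimming.

Steps apply in a fixed order:

1. participants with **less than** 70% correct catches are excluded
   (strict: exactly 70% is kept);
2. trials are dropped when the mouse click occurred before target-word
   onset, or when the whole animation routine lasted **longer than** 5.2 s
   (strict: exactly 5.2 s is kept);
3. decision-time extraction loses always-on-target trials (counted, not
   filtered here — the decision table carries the NA reason);
4. reaction times (click time − target onset, clickers only) are trimmed
   by an intercept-only model with crossed participant and item random
   effects: rows with a standardized conditional residual above 3 in
   magnitude are removed.  If the crossed fit fails, trimming falls back to
   grand-mean standardization and says so.

Screening is idempotent: re-running any step on its own output removes
nothing further.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import TrialLog
from .errors import ScreeningError

__all__ = [
    "ACCURACY_THRESHOLD",
    "MAX_TRIAL_DUR_S",
    "RT_RESID_CUTOFF",
    "ScreeningReport",
    "gate_participants",
    "filter_trials",
    "trim_reaction_times",
    "screen_logs",
]

ACCURACY_THRESHOLD = 0.70
MAX_TRIAL_DUR_S = 5.2
RT_RESID_CUTOFF = 3.0


@dataclass
class ScreeningReport:
    """Counts and fractions for every screening step."""

    participants_dropped: list[tuple[str, float]] = field(default_factory=list)
    n_participants_in: int = 0
    trials_in: int = 0
    trials_dropped_early_click: int = 0
    trials_dropped_slow: int = 0
    trials_lost_always_on_target: int = 0
    n_rt_trimmed: int = 0
    rt_trim_method: str = ""

    @property
    def trials_after_filters(self) -> int:
        return self.trials_in - self.trials_dropped_early_click - self.trials_dropped_slow

    def fractions(self) -> dict[str, float]:
        """Fraction of data surviving / lost at each step (0 when undefined)."""
        n_in = max(self.trials_in, 1)
        kept = self.trials_after_filters
        return {
            "participants_kept": (
                (self.n_participants_in - len(self.participants_dropped))
                / max(self.n_participants_in, 1)
            ),
            "trials_dropped_fast_slow": (
                (self.trials_dropped_early_click + self.trials_dropped_slow) / n_in
            ),
            "trials_lost_always_on_target": (
                self.trials_lost_always_on_target / max(kept, 1)
            ),
        }

    def to_lines(self) -> list[str]:
        frac = self.fractions()
        lines = [
            f"participants: {self.n_participants_in} in, "
            f"{len(self.participants_dropped)} below {ACCURACY_THRESHOLD:.0%} accuracy",
        ]
        for pid, acc in self.participants_dropped:
            lines.append(f"  dropped {pid} (accuracy {acc:.1%})")
        lines += [
            f"trials: {self.trials_in} in, {self.trials_dropped_early_click} early-click, "
            f"{self.trials_dropped_slow} slow (>{MAX_TRIAL_DUR_S} s) "
            f"({frac['trials_dropped_fast_slow']:.1%} of data)",
            f"always-on-target losses: {self.trials_lost_always_on_target} "
            f"({frac['trials_lost_always_on_target']:.1%} of remaining)",
            f"reaction times trimmed: {self.n_rt_trimmed} ({self.rt_trim_method})",
        ]
        return lines

    def to_dict(self) -> dict:
        return {
            "participants_dropped": [
                {"participant": p, "accuracy": a} for p, a in self.participants_dropped
            ],
            "n_participants_in": self.n_participants_in,
            "trials_in": self.trials_in,
            "trials_dropped_early_click": self.trials_dropped_early_click,
            "trials_dropped_slow": self.trials_dropped_slow,
            "trials_lost_always_on_target": self.trials_lost_always_on_target,
            "n_rt_trimmed": self.n_rt_trimmed,
            "rt_trim_method": self.rt_trim_method,
            "fractions": self.fractions(),
        }


def gate_participants(
    accuracy: Mapping[str, float], threshold: float = ACCURACY_THRESHOLD
) -> tuple[list[str], list[tuple[str, float]]]:
    """Partition participants into (kept, dropped-with-accuracy).

    Dropped iff accuracy is *strictly* below the threshold.
    """
    kept, dropped = [], []
    for pid, acc in accuracy.items():
        if not 0.0 <= acc <= 1.0:
            raise ScreeningError(f"accuracy for {pid} outside [0, 1]: {acc}")
        (dropped if acc < threshold else kept).append(
            (pid, acc) if acc < threshold else pid
        )
    return kept, dropped


def filter_trials(log: TrialLog, max_dur_s: float = MAX_TRIAL_DUR_S) -> str | None:
    """Trial-level filter: returns a drop reason or None to keep.

    "early_click" when the click preceded target-word onset; "slow_trial"
    when the routine (animation start to last frame) exceeded ``max_dur_s``.
    """
    if log.click_time_s is not None and log.click_time_s < log.config.target_onset_s:
        return "early_click"
    if log.duration_s > max_dur_s:
        return "slow_trial"
    return None


# --------------------------------------------------------------------------
# reaction-time trimming
# --------------------------------------------------------------------------


def _crossed_conditional_residuals(df: pd.DataFrame) -> np.ndarray | None:
    """Standardized conditional residuals of an intercept-only crossed model.

    Fits rt ~ 1 + (1|participant) + (1|item) by REML (variance components),
    predicts the random effects (BLUPs) in closed form, and standardizes
    the conditional residuals by the residual SD.  Returns None when the
    fit fails or is degenerate, signalling the caller to fall back.
    """
    import statsmodels.api as sm

    y = df["rt"].to_numpy(dtype=float)
    data = df.assign(_g=1)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                "rt ~ 1",
                groups="_g",
                re_formula="0",
                vc_formula={
                    "participant": "0 + C(participant)",
                    "item": "0 + C(item)",
                },
                data=data,
            )
            res = model.fit(reml=True)
    except Exception:
        return None
    if not np.all(np.isfinite(res.params)):
        return None
    sigma2 = float(res.scale)
    if sigma2 <= 1e-12 * max(float(np.var(y)), 1.0) + 1e-30:
        return np.zeros(len(y))

    names = list(model.exog_vc.names)
    var_p = float(res.vcomp[names.index("participant")])
    var_i = float(res.vcomp[names.index("item")])
    Zp = pd.get_dummies(df["participant"]).to_numpy(dtype=float)
    Zi = pd.get_dummies(df["item"]).to_numpy(dtype=float)
    Z = np.hstack([Zp, Zi])
    psi = np.concatenate(
        [np.full(Zp.shape[1], max(var_p, 1e-12)), np.full(Zi.shape[1], max(var_i, 1e-12))]
    )
    r = y - float(res.fe_params.iloc[0])
    # BLUP via Woodbury: b = Psi Z' V^-1 r with V = sigma2 I + Z Psi Z'
    M = np.diag(1.0 / psi) + (Z.T @ Z) / sigma2
    Ztr = Z.T @ r
    V_inv_r = (r - Z @ np.linalg.solve(M, Ztr / sigma2)) / sigma2
    b = psi * (Z.T @ V_inv_r)
    cond = r - Z @ b
    return cond / np.sqrt(sigma2)


def trim_reaction_times(
    rt_table: pd.DataFrame, cutoff: float = RT_RESID_CUTOFF
) -> tuple[pd.DataFrame, int, str]:
    """Remove reaction times with |standardized residual| > ``cutoff``.

    ``rt_table`` needs columns ``rt``, ``participant``, ``item`` (clickers
    only; non-clickers contribute no reaction times by construction).
    Returns (trimmed table, rows removed, method used) where the method is
    "crossed_lmm" or the documented fallback "grand_mean".
    """
    if rt_table.empty:
        raise ScreeningError("cannot trim an empty reaction-time table")
    for col in ("rt", "participant", "item"):
        if col not in rt_table.columns:
            raise ScreeningError(f"rt table lacks required column {col!r}")

    z = None
    method = "crossed_lmm"
    if rt_table["participant"].nunique() >= 2 and rt_table["item"].nunique() >= 2:
        z = _crossed_conditional_residuals(rt_table)
    if z is None:
        method = "grand_mean"
        y = rt_table["rt"].to_numpy(dtype=float)
        sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
        z = np.zeros(len(y)) if sd == 0.0 else (y - y.mean()) / sd
    keep = np.abs(z) <= cutoff
    return rt_table.loc[keep].reset_index(drop=True), int((~keep).sum()), method


# --------------------------------------------------------------------------
# orchestration over raw logs
# --------------------------------------------------------------------------


def screen_logs(
    logs: Sequence[TrialLog],
    threshold: float = ACCURACY_THRESHOLD,
    max_dur_s: float = MAX_TRIAL_DUR_S,
) -> tuple[list[TrialLog], ScreeningReport]:
    """Apply the participant gate then the trial filters to a set of logs.

    Accuracy per participant is the caught fraction over experimental
    (non-practice) trials.  Practice trials never enter the analysis set.
    """
    if not logs:
        raise ScreeningError("no logs to screen")
    experimental = [lg for lg in logs if not lg.config.is_practice]
    by_participant: dict[str, list[TrialLog]] = {}
    for lg in experimental:
        by_participant.setdefault(lg.participant or "anon", []).append(lg)

    report = ScreeningReport(n_participants_in=len(by_participant))
    accuracy = {
        pid: float(np.mean([lg.caught for lg in trials]))
        for pid, trials in by_participant.items()
    }
    kept_ids, report.participants_dropped = gate_participants(accuracy, threshold)

    kept_logs: list[TrialLog] = []
    pool = [lg for pid in kept_ids for lg in by_participant[pid]]
    report.trials_in = len(pool)
    for lg in pool:
        reason = filter_trials(lg, max_dur_s)
        if reason == "early_click":
            report.trials_dropped_early_click += 1
        elif reason == "slow_trial":
            report.trials_dropped_slow += 1
        else:
            kept_logs.append(lg)
    return kept_logs, report
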