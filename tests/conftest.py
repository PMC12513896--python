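"""Shared fixtures: geometry, kinematics, agents, and small synthetic logs."""

from __future__ import annotations

import numpy as np
import pytest

from galatrack import (
    AgentProfile,
    GridSpec,
    KinematicsParams,
    ScreenGeometry,
    TrialConfig,
)


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


@pytest.fixture(scope="session")
def kinematics() -> KinematicsParams:
    return KinematicsParams()


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture
def quiet_agent() -> AgentProfile:
    """Deterministic clicker: no jitter, no guessing, no commitment noise."""
    return AgentProfile(
        base_commit_s=0.5,
        jitter_sd=0.0,
        guess_prob=0.0,
        commit_noise_sd=0.0,
        track_lag_s=0.1,
        click_delay_s=0.3,
    )


@pytest.fixture
def non_clicker() -> AgentProfile:
    return AgentProfile(is_clicker=False, jitter_sd=0.0, guess_prob=0.0, commit_noise_sd=0.0)


def make_config(
    side: str = "right",
    onset: float = 1.2,
    audio: float = 2.5,
    reduced: str = "present",
    segment: str = "h",
    item: str = "h01",
    index: int = 1,
) -> TrialConfig:
    return TrialConfig(
        trial_index=index,
        target_side=side,
        segment=segment,
        reduced=reduced,
        target_onset_s=onset,
        audio_dur_s=audio,
        item_id=item,
    )


@pytest.fixture
def config() -> TrialConfig:
    return make_config()


def oracle_decision_index(s: str) -> tuple[str, int | None, str | None]:
    """Brute-force oracle for decision-time extraction.

    Enumerates *every* index, collects all 'lt' and 'st' bigram positions,
    and applies the selection rules literally: prefer the latest 'lt' with a
    backtrack through contiguous 'l'; use the latest 'st' (its 't' sample)
    when it lies later than the latest 'lt' or no 'lt' exists.  Returns
    (na_reason, grid index or None, source or None).
    """
    if "t" not in s:
        return "never_reached_target", None, None
    if s == "t" * len(s):
        return "always_on_target", None, None
    lt = [i for i in range(len(s) - 1) if s[i] == "l" and s[i + 1] == "t"]
    st = [i for i in range(len(s) - 1) if s[i] == "s" and s[i + 1] == "t"]
    if not lt and not st:
        return "never_reached_target", None, None
    if st and (not lt or st[-1] > lt[-1]):
        return "none", st[-1] + 1, "st_jump"
    i = lt[-1]
    while i > 0 and s[i - 1] == "l":
        i -= 1
    return "none", i, "lt_backtrack"
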