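"""Condition summaries, within-participant CIs, mixed models, time courses.

Decision times (ms, relative to target-word onset) are summarized per
condition cell with within-participant confidence intervals: cell values
are centered per participant (subtract the participant mean, add the grand
mean) and the cell standard error of the centered values is inflated by
Morey's correction sqrt(J/(J-1)) for J conditions before applying the t
quantile.

The inferential model is a linear mixed-effects model with crossed
participant and item random effects, contrast-coded ±0.5 predictors, and
the standard simplification ladder (see :mod:`galatrack._lmer`): full
random-effect structure first, then correlations removed, then the
smallest random slope (interactions first) until convergence.  Degrees of
freedom are Satterthwaite approximations (named in the output).

The time-course analysis is a cluster bootstrap on participant mean
trajectories: the per-participant condition difference curve is resampled
over participants (B=2000, percentile intervals) and maximal runs of grid
points whose interval excludes zero are reported.  This is a deliberately
simple stand-in for a GAMM binary-smooth analysis; its significant windows
are not expected to coincide with GAMM windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._lmer import lmer_available, run_lmer_ladder
from .errors import AnalysisError
from .preprocess import GridSpec, NormalizedTrajectory

__all__ = [
    "morey_ci",
    "condition_summary",
    "ModelFit",
    "fit_decision_model",
    "TimecourseDifference",
    "timecourse_difference",
    "timecourse_from_trajectories",
]


# --------------------------------------------------------------------------
# within-participant (Morey) confidence intervals
# --------------------------------------------------------------------------


def morey_ci(
    table: pd.DataFrame,
    value: str = "decision_time_ms",
    participant: str = "participant",
    condition: str = "condition",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-condition cell means with Morey within-participant CI half-widths.

    Participants with incomplete cells are dropped from the CI computation
    (their count is returned in the ``n_dropped_incomplete`` attribute of
    the result).  Raises :class:`AnalysisError` with fewer than two complete
    participants or fewer than two conditions.
    """
    cells = table.pivot_table(index=participant, columns=condition, values=value, aggfunc="mean")
    complete = cells.dropna()
    n_dropped = len(cells) - len(complete)
    n, J = complete.shape
    if J < 2:
        raise AnalysisError("Morey CIs need at least two conditions")
    if n < 2:
        raise AnalysisError("Morey CIs are undefined for fewer than two complete participants")

    grand = complete.to_numpy().mean()
    centered = complete.sub(complete.mean(axis=1), axis=0) + grand
    se = centered.std(axis=0, ddof=1) / np.sqrt(n)
    correction = np.sqrt(J / (J - 1))
    tq = sps.t.ppf(0.5 + level / 2.0, n - 1)
    out = pd.DataFrame(
        {
            "mean": complete.mean(axis=0),
            "n": n,
            "ci_half_width": se * correction * tq,
        }
    )
    out.attrs["n_dropped_incomplete"] = n_dropped
    return out


def condition_summary(
    table: pd.DataFrame,
    factors: Sequence[str],
    value: str = "decision_time_ms",
    clicker_col: str | None = None,
) -> pd.DataFrame:
    """Cell means (optionally split by clicker status) with Morey CIs.

    ``factors`` are condition columns in the decision table (e.g.
    ``["reduced", "segment"]``); rows with a missing value (NA decision
    times) are excluded first.
    """
    df = table.dropna(subset=[value]).copy()
    df["condition"] = df[list(factors)].astype(str).agg(" × ".join, axis=1)
    groups = [("all", df)] if clicker_col is None else list(df.groupby(clicker_col))
    frames = []
    for label, grp in groups:
        ci = morey_ci(grp, value=value)
        ci.insert(0, "group", str(label))
        frames.append(ci.reset_index())
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# mixed-effects model ladder
# --------------------------------------------------------------------------

_DESIGNS = {
    "reduction_x_segment": {
        "fixed_rhs": "cuesC * segmentC",
        "predictors": ["cuesC", "segmentC"],
        # segment is a between-item factor, and the by-item interaction slope
        # is collinear with the by-item cue slope, so the maximal by-item
        # structure holds the cue slope only
        "participant_slopes": ["cuesC", "segmentC", "cuesC:segmentC"],
        "item_slopes": ["cuesC"],
    },
    "competitor": {
        "fixed_rhs": "competitorC",
        "predictors": ["competitorC"],
        "participant_slopes": ["competitorC"],
        "item_slopes": ["competitorC"],
    },
}


@dataclass
class ModelFit:
    """A converged mixed-model fit plus its simplification trail."""

    coefficients: pd.DataFrame  # term, estimate, se, df, t, p
    formula: str
    trail: list[dict]
    n_obs: int
    df_method: str
    backend: str
    accepted_singular: bool = False

    def coef(self, term: str) -> pd.Series:
        row = self.coefficients.loc[self.coefficients.term == term]
        if row.empty:
            raise AnalysisError(f"no coefficient named {term!r}")
        return row.iloc[0]

    @property
    def simplified(self) -> bool:
        return len(self.trail) > 1


def _fit_statsmodels(data: pd.DataFrame, fixed_rhs: str) -> ModelFit:
    """Crossed random *intercepts* fit via statsmodels variance components.

    A cross-check backend: uncorrelated intercept-only random structure,
    Wald z-based p-values (df reported as infinity).
    """
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            f"dt ~ {fixed_rhs}",
            groups="_g",
            re_formula="0",
            vc_formula={"participant": "0 + C(participant)", "item": "0 + C(item)"},
            data=data.assign(_g=1),
        )
        res = model.fit(reml=True)
    k = model.k_fe
    terms = res.params.index[:k]
    coefs = pd.DataFrame(
        {
            "term": [t.replace(":", ":") for t in terms],
            "estimate": res.params.values[:k],
            "se": res.bse.values[:k],
            "df": np.inf,
            "t": res.params.values[:k] / res.bse.values[:k],
            "p": 2 * sps.norm.sf(np.abs(res.params.values[:k] / res.bse.values[:k])),
        }
    )
    formula = f"dt ~ {fixed_rhs} + (1|participant) + (1|item)"
    return ModelFit(
        coefficients=coefs,
        formula=formula,
        trail=[{"formula": formula, "status": "converged" if res.converged else "non-convergence"}],
        n_obs=int(res.nobs),
        df_method="normal approximation (z)",
        backend="statsmodels",
    )


def fit_decision_model(
    table: pd.DataFrame,
    design: str = "reduction_x_segment",
    response: str = "decision_time_ms",
    backend: str = "lmer",
) -> ModelFit:
    """Fit the decision-time LMM with the random-effect simplification ladder.

    ``table`` is a screened, contrast-coded decision table; rows with a
    missing response are excluded.  ``design`` selects the fixed/random
    layout: "reduction_x_segment" (cuesC × segmentC) on critical trials or
    "competitor" on semantic fillers.  The default backend is lme4/lmerTest
    through Rscript; "statsmodels" fits a crossed-intercepts cross-check.
    """
    try:
        spec = _DESIGNS[design]
    except KeyError:
        raise AnalysisError(f"unknown design {design!r}") from None
    cols = ["participant", "item", *spec["predictors"], response]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise AnalysisError(f"decision table lacks columns: {missing}")
    data = table.dropna(subset=[response])[cols].rename(columns={response: "dt"})
    if data.empty:
        raise AnalysisError("no usable rows for the decision model")

    if backend == "statsmodels" or (backend == "auto" and not lmer_available()):
        return _fit_statsmodels(data, spec["fixed_rhs"])
    result = run_lmer_ladder(
        data,
        fixed=f"dt ~ {spec['fixed_rhs']}",
        participant_slopes=spec["participant_slopes"],
        item_slopes=spec["item_slopes"],
    )
    coefs = pd.DataFrame(result["coefficients"])
    return ModelFit(
        coefficients=coefs,
        formula=result["formula"],
        trail=list(result["trail"]),
        n_obs=int(result["n_obs"]),
        df_method=result.get("df_method", "Satterthwaite"),
        backend="lmer",
        accepted_singular=bool(result.get("accepted_singular", False)),
    )


# --------------------------------------------------------------------------
# bootstrap time-course difference
# --------------------------------------------------------------------------


@dataclass
class TimecourseDifference:
    """Mean condition-difference curve with a cluster-bootstrap band."""

    times: np.ndarray
    difference: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    intervals: list[tuple[float, float]]
    n_participants: int
    n_boot: int


def timecourse_from_trajectories(
    trajs: Sequence[NormalizedTrajectory], factor: str
) -> dict[str, dict[str, np.ndarray]]:
    """Participant mean curves per level of ``factor`` ('reduced'/'competitor').

    Input trajectories must already be oriented (positive toward target).
    """
    sums: dict[str, dict[str, np.ndarray]] = {}
    counts: dict[str, dict[str, int]] = {}
    for tr in trajs:
        if tr.config is None or tr.participant is None:
            raise AnalysisError("time-course analysis needs participant/config metadata")
        lvl = getattr(tr.config, factor)
        if lvl is None:
            continue
        sums.setdefault(lvl, {})
        counts.setdefault(lvl, {})
        if tr.participant not in sums[lvl]:
            sums[lvl][tr.participant] = np.zeros_like(tr.x)
            counts[lvl][tr.participant] = 0
        sums[lvl][tr.participant] += tr.x
        counts[lvl][tr.participant] += 1
    return {
        lvl: {pid: sums[lvl][pid] / counts[lvl][pid] for pid in sums[lvl]}
        for lvl in sums
    }


def timecourse_difference(
    curves_a: Mapping[str, np.ndarray],
    curves_b: Mapping[str, np.ndarray],
    grid: GridSpec | None = None,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> TimecourseDifference:
    """Percentile cluster bootstrap of the mean difference curve (A − B).

    Participants present in both conditions contribute one difference
    curve each; the bootstrap resamples participants with replacement.
    Maximal runs of grid points whose interval excludes zero are reported
    as (start, end) times.
    """
    grid = grid or GridSpec()
    shared = sorted(set(curves_a) & set(curves_b))
    if len(shared) < 2:
        raise AnalysisError("time-course difference needs at least two shared participants")
    D = np.stack([np.asarray(curves_a[p]) - np.asarray(curves_b[p]) for p in shared])
    diff = D.mean(axis=0)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(shared), size=(n_boot, len(shared)))
    boot = D[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(boot, alpha, axis=0)
    upper = np.quantile(boot, 1.0 - alpha, axis=0)

    times = grid.times()
    sig = (lower > 0) | (upper < 0)
    intervals: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(times[start]), float(times[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(times[start]), float(times[-1])))
    return TimecourseDifference(
        times=times,
        difference=diff,
        lower=lower,
        upper=upper,
        intervals=intervals,
        n_participants=len(shared),
        n_boot=n_boot,
    )
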