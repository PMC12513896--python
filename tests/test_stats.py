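"""Morey CIs, the mixed-model ladder, and the bootstrap time course."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from galatrack import (
    GridSpec,
    StudySettings,
    fit_decision_model,
    morey_ci,
    screen_and_tabulate,
    simulate_study,
    timecourse_difference,
)
from galatrack.errors import AnalysisError
from galatrack.stats import condition_summary


def _long(cells: np.ndarray) -> pd.DataFrame:
    """participant × condition matrix -> long table."""
    n, J = cells.shape
    rows = [
        {"participant": f"p{i}", "condition": f"c{j}", "decision_time_ms": cells[i, j]}
        for i in range(n)
        for j in range(J)
    ]
    return pd.DataFrame(rows)


class TestMoreyCI:
    def test_pure_participant_offsets_give_zero_width(self):
        # both conditions equal within participant: centering removes everything
        offsets = np.array([100.0, 250.0, 400.0])
        cells = np.stack([offsets, offsets], axis=1)
        out = morey_ci(_long(cells))
        assert np.allclose(out.ci_half_width, 0.0)

    def test_hand_computed_3x2_table(self):
        """Frozen hand calculation with the √2 correction for J = 2."""
        cells = np.array([[500.0, 560.0], [520.0, 600.0], [480.0, 530.0]])
        grand = cells.mean()
        centered = cells - cells.mean(axis=1, keepdims=True) + grand
        se = centered.std(axis=0, ddof=1) / np.sqrt(3)
        expected = se * np.sqrt(2.0) * sps.t.ppf(0.975, 2)
        out = morey_ci(_long(cells))
        assert np.allclose(out.ci_half_width.to_numpy(), expected)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        cells = 500 + rng.normal(0, 40, size=(8, 3))
        one = morey_ci(_long(cells)).ci_half_width.to_numpy()
        two = morey_ci(_long(2 * cells)).ci_half_width.to_numpy()
        assert np.allclose(two, 2 * one)

    def test_equals_scaled_classical_ci_without_participant_offsets(self):
        """When every participant's row mean is identical, centering is inert
        and the Morey half-width is exactly √(J/(J−1)) times the classical
        between-participant CI."""
        rng = np.random.default_rng(4)
        d = rng.normal(0, 30, size=10)
        cells = np.stack([500 + d, 500 - d], axis=1)  # row means all 500
        out = morey_ci(_long(cells))
        classical = cells.std(axis=0, ddof=1) / np.sqrt(10) * sps.t.ppf(0.975, 9)
        assert np.allclose(out.ci_half_width.to_numpy(), classical * np.sqrt(2.0))

    def test_single_participant_is_an_error(self):
        with pytest.raises(AnalysisError):
            morey_ci(_long(np.array([[1.0, 2.0]])))

    def test_incomplete_participants_are_dropped_and_counted(self):
        df = _long(np.array([[500.0, 560.0], [520.0, 600.0], [480.0, 530.0]]))
        df = df.drop(df.index[-1])  # p2 loses condition c1
        out = morey_ci(df)
        assert out.attrs["n_dropped_incomplete"] == 1
        assert (out.n == 2).all()


@pytest.fixture(scope="module")
def small_study():
    logs = simulate_study(21, StudySettings(n_participants=10))
    table, _ = screen_and_tabulate(logs)
    return table


class TestDecisionModel:
    def test_sign_flips_with_label_permutation(self, small_study):
        crit = small_study[small_study.trial_class == "critical"]
        fit = fit_decision_model(crit, backend="statsmodels")
        flipped = crit.assign(cuesC=-crit.cuesC)
        fit2 = fit_decision_model(flipped, backend="statsmodels")
        assert fit.coef("cuesC").estimate == pytest.approx(-fit2.coef("cuesC").estimate)

    def test_balanced_intercept_near_grand_cell_mean(self, small_study):
        crit = small_study[small_study.trial_class == "critical"].dropna(
            subset=["decision_time_ms"]
        )
        fit = fit_decision_model(crit, backend="statsmodels")
        cell_means = crit.groupby(["cuesC", "segmentC"]).decision_time_ms.mean()
        assert fit.coef("(Intercept)" if "(Intercept)" in list(fit.coefficients.term) else "Intercept").estimate == pytest.approx(cell_means.mean(), rel=0.05)

    def test_lmer_ladder_recovers_injected_competitor_cost(self, small_study):
        """The similar-competitor commitment shift (+130 ms) reappears as a
        negative competitor-predictability coefficient of about that size."""
        fillers = small_study[small_study.trial_class == "filler_semantic"]
        fit = fit_decision_model(fillers, design="competitor")
        coef = fit.coef("competitorC")
        assert coef.estimate < 0
        assert abs(coef.estimate - (-130.0)) < 3 * coef.se
        assert fit.df_method == "Satterthwaite"
        assert fit.trail  # the ladder reports every structure it tried

    def test_backends_agree_on_fixed_effects(self, small_study):
        fillers = small_study[small_study.trial_class == "filler_semantic"]
        lmer = fit_decision_model(fillers, design="competitor")
        sm = fit_decision_model(fillers, design="competitor", backend="statsmodels")
        a = lmer.coef("competitorC").estimate
        b = sm.coef("competitorC").estimate
        assert a == pytest.approx(b, abs=0.1 * abs(b) + 5.0)

    def test_unknown_design_rejected(self, small_study):
        with pytest.raises(AnalysisError):
            fit_decision_model(small_study, design="priming")


class TestTimecourse:
    grid = GridSpec()

    def _curves(self, rng, n_part, shift=0.0, onset_index=30):
        out = {}
        for p in range(n_part):
            base = np.cumsum(rng.normal(0, 0.005, self.grid.n_points))
            curve = base + rng.normal(0, 0.02)
            curve[onset_index:] += shift
            out[f"p{p}"] = curve
        return out

    def test_self_difference_is_identically_zero(self):
        rng = np.random.default_rng(0)
        curves = self._curves(rng, 8)
        res = timecourse_difference(curves, curves, self.grid, n_boot=200, seed=1)
        assert np.all(res.difference == 0.0)
        assert res.intervals == []

    def test_injected_separation_yields_post_onset_interval(self):
        rng = np.random.default_rng(1)
        a = self._curves(rng, 20, shift=0.1)
        b = self._curves(rng, 20, shift=0.0)
        res = timecourse_difference(a, b, self.grid, n_boot=500, seed=2)
        assert res.intervals, "expected a significant window"
        # some significant stretch must start after target onset
        assert any(lo >= 0.0 for lo, _ in res.intervals)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        a = self._curves(rng, 10, shift=0.05)
        b = self._curves(rng, 10)
        r1 = timecourse_difference(a, b, self.grid, n_boot=300, seed=9)
        r2 = timecourse_difference(a, b, self.grid, n_boot=300, seed=9)
        assert np.array_equal(r1.lower, r2.lower) and r1.intervals == r2.intervals

    def test_single_participant_is_degenerate(self):
        rng = np.random.default_rng(4)
        a = self._curves(rng, 1)
        with pytest.raises(AnalysisError):
            timecourse_difference(a, a, self.grid)


def test_condition_summary_splits_cells(small_study):
    crit = small_study[small_study.trial_class == "critical"]
    out = condition_summary(crit, ["reduced", "segment"])
    assert set(out.condition) == {
        "present × h",
        "present × glottal",
        "deleted × h",
        "deleted × glottal",
    }
    assert (out.ci_half_width >= 0).all()
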