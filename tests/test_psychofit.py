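"""Psychometric fitting: binning, logit MLE, PSE/WR, exclusion, calibration."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import expit

from magest import (
    CalibrationCriteria,
    PsychometricModel,
    binarize,
    calibrate,
    exclude_participants,
    fit_logit,
    magnitude_levels,
    outlier_replace,
    pse,
    weber_ratio,
)
from magest.psychofit import CalibrationError, FitError, make_observer_probe

from conftest import logistic_plus_counts

LEVELS = magnitude_levels(1.0)


class TestBinarize:
    @pytest.mark.parametrize(
        "pos,polarity,expected",
        [
            (62, "plus_top", "plus"),
            (62, "plus_bottom", "minus"),
            (38, "plus_bottom", "plus"),
            (50, "plus_top", "minus"),  # tie rule: cursor start counts as '-'
            (50, "plus_bottom", "minus"),
            (0, "plus_top", "minus"),
            (100, "plus_top", "plus"),
        ],
    )
    def test_binning(self, pos, polarity, expected):
        assert binarize(pos, polarity) == expected

    def test_mirror_symmetry_over_grid(self):
        """Counts of '+' over the 0..100 grid are polarity-symmetric."""
        grid = range(0, 101)
        n_top = sum(binarize(v, "plus_top") == "plus" for v in grid)
        n_bot = sum(binarize(v, "plus_bottom") == "plus" for v in grid)
        assert n_top == n_bot == 50

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize(101, "plus_top")
        with pytest.raises(ValueError):
            binarize(-1, "plus_top")


class TestLogitFit:
    def test_parameter_recovery(self, rng):
        """Median recovery over 100 seeded replicates: PSE within 3 %, WR within 15 %."""
        mu_true, s_true = 1.0, 0.08
        wr_true = s_true * math.log(3.0) / mu_true
        pse_err, wr_err = [], []
        for _ in range(100):
            k = logistic_plus_counts(LEVELS, mu_true, s_true, 12, rng)
            fit = fit_logit(LEVELS, k, [12] * 6)
            if not fit.converged:
                continue
            pse_err.append(abs(fit.pse - mu_true) / mu_true)
            wr_err.append(abs(fit.wr - wr_true) / wr_true)
        assert np.median(pse_err) < 0.03
        assert np.median(wr_err) < 0.15

    def test_agrees_with_glm_oracle(self, rng):
        """Independent route: statsmodels Binomial GLM with logit link."""
        import statsmodels.api as sm

        k = logistic_plus_counts(LEVELS, 1.0, 0.1, 20, rng)
        fit = fit_logit(LEVELS, k, [20] * 6)
        glm = sm.GLM(
            np.column_stack([k, 20 - np.asarray(k)]),
            sm.add_constant(np.asarray(LEVELS)),
            family=sm.families.Binomial(),
        ).fit()
        b0, b1 = glm.params
        assert fit.mu == pytest.approx(-b0 / b1, rel=1e-3)
        assert fit.s == pytest.approx(1.0 / b1, rel=1e-3)
        assert fit.deviance == pytest.approx(glm.deviance, abs=1e-4)

    def test_nll_trace_monotone_nonincreasing(self, rng):
        k = logistic_plus_counts(LEVELS, 1.0, 0.1, 12, rng)
        fit = fit_logit(LEVELS, k, [12] * 6)
        trace = fit.nll_trace
        assert len(trace) > 1
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_perfect_separation_flagged(self):
        fit = fit_logit(LEVELS, [0, 0, 0, 12, 12, 12], [12] * 6)
        assert not fit.converged
        assert "separation" in fit.flags or fit.s < 1e-3

    def test_one_sided_data_unusable(self):
        fit = fit_logit(LEVELS, [12] * 6, [12] * 6)
        assert not fit.converged
        with pytest.raises(FitError):
            pse(fit)

    def test_flat_proportions_unusable(self):
        fit = fit_logit(LEVELS, [6] * 6, [12] * 6)
        assert not fit.converged

    def test_input_validation(self):
        with pytest.raises(ValueError):
            PsychometricModel([1.0] * 6, [1] * 6, [2] * 6)  # one distinct level
        with pytest.raises(ValueError):
            PsychometricModel(LEVELS, [0] * 6, [1] * 6)  # fewer than 12 trials

    def test_summary_renders(self, rng):
        k = logistic_plus_counts(LEVELS, 1.0, 0.1, 12, rng)
        text = fit_logit(LEVELS, k, [12] * 6).summary()
        assert "PSE" in text and "Weber" in text


class TestPseWr:
    def test_pse_equals_location(self, rng):
        for mu, s in [(1.0, 0.05), (800.0, 60.0)]:
            k = logistic_plus_counts(magnitude_levels(mu), mu, s, 50, rng)
            fit = fit_logit(magnitude_levels(mu), k, [50] * 6)
            assert pse(fit) == fit.mu

    def test_pse_matches_numeric_inversion(self, rng):
        """f^{-1}(0.5) found by root-finding equals mu to 1e-9."""
        for _ in range(100):
            mu = rng.uniform(0.5, 2.0)
            s = rng.uniform(0.02, 0.3)
            f = lambda x: expit((x - mu) / s) - 0.5
            root = brentq(f, mu - 10, mu + 10, xtol=1e-12)
            assert abs(root - mu) < 1e-9

    def test_wr_closed_form(self, rng):
        """WR = 0.5 (f^{-1}(0.75) - f^{-1}(0.25)) / PSE = s ln3 / mu."""
        for _ in range(100):
            mu = rng.uniform(0.5, 2.0)
            s = rng.uniform(0.02, 0.3)
            inv = lambda p: brentq(lambda x: expit((x - mu) / s) - p, mu - 50, mu + 50,
                                   xtol=1e-13)
            numeric = 0.5 * (inv(0.75) - inv(0.25)) / mu
            assert abs(numeric - s * math.log(3.0) / mu) < 1e-9

    def test_wr_example_value(self, rng):
        k = logistic_plus_counts(LEVELS, 1.0, 0.1, 2000, rng)
        fit = fit_logit(LEVELS, k, [2000] * 6)
        assert weber_ratio(fit) == pytest.approx(0.1098612, abs=0.01)

    def test_wr_scale_invariant(self, rng):
        """(mu, s) -> (c mu, c s) leaves the Weber Ratio unchanged."""
        for _ in range(20):
            c = rng.uniform(0.1, 100)
            mu, s = 1.0, 0.1
            k = logistic_plus_counts(magnitude_levels(mu), mu, s, 200, rng)
            fit1 = fit_logit(magnitude_levels(mu), k, [200] * 6)
            fit2 = fit_logit([c * x for x in magnitude_levels(mu)], k, [200] * 6)
            assert fit2.wr == pytest.approx(fit1.wr, rel=1e-3)


class TestExcludeParticipants:
    def _ok(self):
        return {"top_plus_prop": 0.9, "gof_p": 0.5}

    def test_max_level_rule(self):
        controls = {
            "a": {"duration": {"top_plus_prop": 0.4, "gof_p": 0.5},
                  "numerosity": self._ok(), "surface": self._ok()},
            "b": {d: self._ok() for d in ("duration", "numerosity", "surface")},
        }
        kept, dropped = exclude_participants(controls, gof_rule="less")
        assert kept == ["b"]
        assert dropped["a"] == ["max-level:duration"]

    def test_all_criteria_satisfied_kept(self):
        controls = {"p": {d: self._ok() for d in ("duration", "numerosity", "surface")}}
        kept, dropped = exclude_participants(controls, gof_rule="less")
        assert kept == ["p"] and not dropped

    def test_gof_rule_direction(self):
        controls = {"p": {"duration": {"top_plus_prop": 0.9, "gof_p": 0.3}}}
        _, dropped_verbatim = exclude_participants(controls, gof_rule="greater")
        _, dropped_conv = exclude_participants(controls, gof_rule="less")
        assert "p" in dropped_verbatim and not dropped_conv

    def test_engineered_cohort_drops_exactly_violators(self, rng):
        """45 synthetic participants, 10 engineered to violate: exactly those drop."""
        controls = {}
        violators = set(rng.choice(45, size=10, replace=False).tolist())
        for pid in range(45):
            dims = {d: self._ok() for d in ("duration", "numerosity", "surface")}
            if pid in violators:
                if pid % 2:
                    dims["numerosity"]["top_plus_prop"] = 0.3
                else:
                    dims["surface"]["gof_p"] = 0.01
            controls[pid] = dims
        kept, dropped = exclude_participants(controls, gof_rule="less")
        assert set(dropped) == violators
        assert len(kept) == 35

    def test_idempotent_on_kept(self):
        controls = {p: {"duration": self._ok()} for p in range(5)}
        kept, _ = exclude_participants(controls, gof_rule="less")
        kept2, dropped2 = exclude_participants({p: controls[p] for p in kept},
                                               gof_rule="less")
        assert kept2 == kept and not dropped2

    def test_missing_controls_rejected(self):
        with pytest.raises(ValueError):
            exclude_participants({"p": {}})


class TestOutlierReplace:
    def test_borderline_kept(self):
        # 10 sits 1.79 sample-SDs from the mean of [1,1,1,1,10]: no replacement
        out, k = outlier_replace([1, 1, 1, 1, 10])
        assert k == 0 and list(out) == [1, 1, 1, 1, 10]

    def test_all_equal_unchanged(self):
        out, k = outlier_replace([5.0] * 6)
        assert k == 0 and list(out) == [5.0] * 6

    def test_two_outliers_replaced_by_group_mean(self):
        vals = [10.0] * 20 + [30.0, -10.0]
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        assert abs(30.0 - mean) > 2 * sd and abs(-10.0 - mean) > 2 * sd
        out, k = outlier_replace(vals)
        assert k == 2
        assert out[-1] == out[-2] == pytest.approx(mean)

    def test_idempotent(self):
        vals = [10.0] * 20 + [30.0, -10.0]
        once, _ = outlier_replace(vals)
        twice, k2 = outlier_replace(once)
        assert k2 == 0 and np.allclose(once, twice)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            outlier_replace([1.0, 2.0])


def biased_probe(bias: float, wr_scale: float = 0.05, n_per_level: int = 500,
                 seed: int = 0):
    """Synthetic calibration hook: an observer whose percept is bias*x (for the
    accumulated dimensions) compared against a fixed internal reference."""
    rng = np.random.default_rng(seed)
    references = {"duration": 800.0, "numerosity": 32.0, "surface": 476.0}

    def probe(dim, mean_value):
        ref = references[dim]
        b = 1.0 if dim == "duration" else bias
        levels = magnitude_levels(mean_value)
        p = expit((np.asarray(levels) * b - ref) / (wr_scale * ref))
        k = rng.binomial(n_per_level, p)
        return levels, k, [n_per_level] * 6

    return probe


class TestCalibrate:
    def test_ideal_observer_converges_immediately(self):
        result = calibrate(biased_probe(1.0), means={"duration": 800,
                                                     "numerosity": 32, "surface": 476})
        assert result.iterations == 1
        assert result.n_mean == 32 and result.s_mean == 476

    def test_overestimation_bias_rescales_mean(self):
        """A 10 % overestimator ends up with N_mean near initial/1.1."""
        result = calibrate(
            biased_probe(1.10, seed=1),
            means={"duration": 800, "numerosity": 32, "surface": 476},
        )
        assert result.n_mean == pytest.approx(32 / 1.10, rel=0.03)

    def test_persistent_wr_violation_fails(self):
        criteria = CalibrationCriteria(wr_abs_max=0.01)  # unattainably strict
        with pytest.raises(CalibrationError) as err:
            calibrate(biased_probe(1.0), criteria=criteria, max_iter=5)
        assert err.value.last_state  # failure carries the last state

    def test_success_implies_criteria_met(self):
        criteria = CalibrationCriteria()
        result = calibrate(biased_probe(1.05, seed=2), criteria=criteria)
        last = result.history[-1]
        assert criteria.satisfied(last["pse"], last["wr"], last["means"])

    def test_observer_backed_probe_converges(self):
        """The synthetic Bayesian observer passes calibration unchanged."""
        from magest import ObserverParams

        params = ObserverParams.default(sensory_cv=0.08, lapse_rate=0.0)
        probe = make_observer_probe(params, seed=0, n_per_level=25)
        result = calibrate(
            probe, means={"duration": 800, "numerosity": 32, "surface": 476}
        )
        assert result.iterations <= 3
        assert 0.9 * 32 <= result.n_mean <= 1.1 * 32
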