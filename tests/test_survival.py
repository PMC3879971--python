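import math

import numpy as np
import pytest

from paraloc.divergence import DivergenceEstimate
from paraloc.localization import RelocalizationStatus, Status
from paraloc.survival import (
    CoxConvergenceError,
    SurvivalRecord,
    cox_fit,
    cox_snell_residuals,
    excess_hazard_percent,
    hazard_ratio,
    ks_window_hazard_table,
    records_from_pairs,
    significance_stars,
)
from paraloc.synthetic_data import RetentionSimParams, simulate_retention_dataset

from oracles import grid_max_beta


def _records(times0, times1):
    return [SurvivalRecord(t, 0) for t in times0] + [
        SurvivalRecord(t, 1) for t in times1
    ]


class TestCoxFit:
    def test_identical_group_time_multisets_give_beta_zero(self):
        times = [0.1, 0.2, 0.3, 0.7]
        fit = cox_fit(_records(times, times))
        assert fit.beta == pytest.approx(0.0, abs=1e-9)
        assert fit.hazard_ratio == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_on_interleaved_toy(self):
        recs = _records([0.20, 0.35, 0.60], [0.10, 0.25, 0.45])
        fit = cox_fit(recs)
        beta_star = grid_max_beta(
            [r.time for r in recs], [r.dp for r in recs]
        )
        assert fit.beta == pytest.approx(beta_star, abs=1e-3)

    def test_matches_grid_search_on_random_datasets(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 40))
            times = rng.uniform(0.01, 1.0, size=n)  # continuous: tie-free
            x = rng.integers(0, 2, size=n)
            if x.sum() in (0, n):
                x[0] = 1 - x[0]
            recs = [SurvivalRecord(t, int(d)) for t, d in zip(times, x)]
            fit = cox_fit(recs)
            assert fit.beta == pytest.approx(
                grid_max_beta(times, x), abs=1e-3
            )

    def test_label_swap_negates_beta(self, rng):
        times = rng.uniform(0.01, 1.0, size=60)
        x = rng.integers(0, 2, size=60)
        recs = [SurvivalRecord(t, int(d)) for t, d in zip(times, x)]
        flipped = [SurvivalRecord(t, 1 - int(d)) for t, d in zip(times, x)]
        f1, f2 = cox_fit(recs), cox_fit(flipped)
        assert f1.beta == pytest.approx(-f2.beta, abs=1e-8)
        assert f1.hazard_ratio == pytest.approx(1 / f2.hazard_ratio, rel=1e-8)

    def test_time_rescaling_leaves_beta_unchanged(self, rng):
        times = rng.uniform(0.01, 1.0, size=60)
        x = rng.integers(0, 2, size=60)
        x[0], x[1] = 0, 1
        f1 = cox_fit([SurvivalRecord(t, int(d)) for t, d in zip(times, x)])
        f2 = cox_fit([SurvivalRecord(7.3 * t, int(d)) for t, d in zip(times, x)])
        assert f1.beta == pytest.approx(f2.beta, abs=1e-9)

    def test_efron_equals_breslow_without_ties(self, rng):
        times = rng.uniform(0.01, 1.0, size=50)
        x = rng.integers(0, 2, size=50)
        x[0], x[1] = 0, 1
        recs = [SurvivalRecord(t, int(d)) for t, d in zip(times, x)]
        fe = cox_fit(recs, ties="efron")
        fb = cox_fit(recs, ties="breslow")
        assert fe.beta == pytest.approx(fb.beta, abs=1e-9)

    def test_cross_check_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(5)
        # tied times exercise the Efron correction
        times = np.round(rng.uniform(0.05, 1.0, size=120), 2)
        x = rng.integers(0, 2, size=120)
        recs = [SurvivalRecord(t, int(d)) for t, d in zip(times, x)]
        fit = cox_fit(recs)
        cph = lifelines.CoxPHFitter()
        df = pd.DataFrame({"T": times, "E": 1, "dp": x})
        cph.fit(df, duration_col="T", event_col="E")
        assert fit.beta == pytest.approx(cph.params_["dp"], abs=1e-6)
        assert fit.se == pytest.approx(cph.standard_errors_["dp"], abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cox_fit([SurvivalRecord(0.1, 1), SurvivalRecord(0.2, 1)])

    def test_complete_separation_flagged(self):
        # dp=1 all die strictly before dp=0: monotone likelihood
        recs = _records([10.0, 11.0, 12.0, 13.0], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(CoxConvergenceError):
            cox_fit(recs)


class TestHazardInterpretation:
    @pytest.mark.parametrize(
        "beta,expected", [(0.0, 1.0), (math.log(2), 2.0)]
    )
    def test_hazard_ratio(self, beta, expected):
        assert hazard_ratio(beta) == pytest.approx(expected)

    def test_table_printed_ratio(self):
        assert hazard_ratio(math.log(1.58)) == pytest.approx(1.58)

    @pytest.mark.parametrize(
        "hr,expected", [(1.58, 58), (1.0, 0), (0.5, -50)]
    )
    def test_excess_hazard_percent(self, hr, expected):
        assert round(excess_hazard_percent(hr)) == expected

    @pytest.mark.parametrize(
        "p,mark", [(0.04, "*"), (0.0005, "**"), (0.2, ""), (0.05, "")]
    )
    def test_stars(self, p, mark):
        assert significance_stars(p) == mark


class TestParameterRecovery:
    def test_null_rate_ratio_recovered(self):
        params = RetentionSimParams(
            n_pairs=4000, death_rate_reloc=1.0, death_rate_nonreloc=1.0,
            ks_window=(0.0, 10.0), seed=3,
        )
        recs, truth = simulate_retention_dataset(params)
        fit = cox_fit(recs)
        assert abs(fit.beta - math.log(truth.true_hr)) < 3 * fit.se

    def test_rate_ratio_two_recovered(self):
        params = RetentionSimParams(
            n_pairs=5000, death_rate_reloc=1.0, death_rate_nonreloc=2.0,
            ks_window=(0.0, 10.0), seed=1,
        )
        recs, truth = simulate_retention_dataset(params)
        fit = cox_fit(recs)
        assert abs(fit.beta - math.log(2.0)) < 3 * fit.se
        # exponential-MLE oracle: ratio of group death-rate estimates
        t = np.array([r.time for r in recs])
        x = np.array([r.dp for r in recs])
        mle_ratio = t[x == 0].mean() / t[x == 1].mean()
        assert fit.hazard_ratio == pytest.approx(mle_ratio, rel=0.05)


class TestCoxSnell:
    def _fitted(self, n=2000, seed=2):
        params = RetentionSimParams(
            n_pairs=n, death_rate_reloc=1.0, death_rate_nonreloc=1.5,
            ks_window=(0.0, 10.0), seed=seed,
        )
        recs, _ = simulate_retention_dataset(params)
        return cox_fit(recs), recs

    def test_residuals_nonnegative_and_sum_to_events(self):
        fit, recs = self._fitted()
        res, _ = cox_snell_residuals(fit, recs)
        assert (res >= 0).all()
        assert res.sum() == pytest.approx(len(recs), rel=1e-9)

    def test_well_specified_model_close_to_unit_exponential(self):
        fit, recs = self._fitted(n=5000, seed=4)
        _, ks_dist = cox_snell_residuals(fit, recs)
        assert ks_dist < 0.05


def _joint(ks_dp):
    out = []
    for i, (ks, dp) in enumerate(ks_dp):
        est = DivergenceEstimate(
            id_a=f"a{i}", id_b=f"b{i}", ks=ks, ka=0.1, omega=None, valid=True
        )
        status = Status.RELOCALIZED if dp == 0 else Status.NONRELOCALIZED
        out.append((est, RelocalizationStatus(f"a{i}", f"b{i}", status)))
    return out


class TestWindowTable:
    def test_sample_sizes_nondecreasing_over_nested_windows(self, rng):
        ks = rng.uniform(0.001, 0.999, size=400)
        dp = rng.integers(0, 2, size=400)
        rows = ks_window_hazard_table(_joint(list(zip(ks, dp))))
        ns = [row["n"] for row in rows]
        assert ns == sorted(ns)

    def test_equal_rate_groups_not_significant(self, rng):
        ks = rng.uniform(0.01, 0.99, size=300)
        dp = np.array([0, 1] * 150)
        rows = ks_window_hazard_table(
            _joint(list(zip(ks, dp))), windows=[(0.0, 1.0)]
        )
        fit = rows[0]["fit"]
        assert fit is not None
        assert abs(fit.beta) < 3 * fit.se

    def test_empty_group_window_yields_na_row(self):
        joint = _joint(
            [(0.5, 0), (0.6, 0), (0.05, 1), (0.06, 1), (0.55, 1), (0.65, 1)]
        )
        rows = ks_window_hazard_table(joint, windows=[(0.0, 0.1), (0.0, 1.0)])
        assert rows[0]["fit"] is None and "reason" in rows[0]
        assert rows[1]["fit"] is not None

    def test_records_from_pairs_skips_invalid(self):
        est_bad = DivergenceEstimate("a", "b", float("nan"), 0.0, None, valid=False)
        st = RelocalizationStatus("a", "b", Status.RELOCALIZED)
        assert records_from_pairs([(est_bad, st)]) == []
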