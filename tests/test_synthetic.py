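"""Synthetic cohort generator: reproducibility, calibration and the bias
structure the corrections are designed to remove."""

import numpy as np
import pandas as pd
import pytest

from screenbias.cohort import validate_cohort
from screenbias.simulate import (SimConfig, observed_summaries,
                                 simulate_cohort)
from tests.conftest import make_cohort_frame


class TestGeneration:
    def test_bit_reproducible_from_seed(self):
        cfg = SimConfig(n=500)
        a, ta = simulate_cohort(cfg, seed=42)
        b, tb = simulate_cohort(cfg, seed=42)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)
        c, _ = simulate_cohort(cfg, seed=43)
        assert not a["time_days"].equals(c["time_days"])

    def test_output_passes_cohort_validation(self):
        cohort, truth = simulate_cohort(SimConfig(n=400), seed=1)
        validated = validate_cohort(cohort)
        assert len(validated) == 400
        assert list(truth["id"]) == list(cohort["id"])

    def test_zero_screen_probability_gives_no_screened(self):
        cfg = SimConfig(n=2000, screen_prob_xf=0.0, screen_prob_nonxf=0.0)
        cohort, _ = simulate_cohort(cfg, seed=2)
        assert not cohort["screened"].any()

    def test_marginal_rates_converge_to_config(self):
        cfg = SimConfig(n=50_000)
        cohort, truth = simulate_cohort(cfg, seed=3)
        xf = cohort["region"] == "XF"
        assert cohort.loc[xf, "screened"].mean() == pytest.approx(0.176, abs=0.01)
        assert cohort.loc[~xf, "screened"].mean() == pytest.approx(0.053, abs=0.01)
        assert xf.mean() == pytest.approx(0.204, abs=0.01)
        assert truth["aggressive"].mean() == pytest.approx(0.9, abs=0.01)

    def test_screened_cases_shifted_to_earlier_stage(self):
        cohort, _ = simulate_cohort(SimConfig(n=20_000), seed=4)
        scr = cohort["screened"]
        early_scr = cohort.loc[scr, "stage"].isin(["I", "II"]).mean()
        early_sym = cohort.loc[~scr, "stage"].isin(["I", "II"]).mean()
        assert early_scr > 2 * early_sym

    def test_lead_time_only_for_screened(self):
        cohort, truth = simulate_cohort(SimConfig(n=5000), seed=5)
        scr = cohort["screened"].to_numpy()
        assert (truth.loc[~scr, "lead_time_days"] == 0).all()
        assert (truth.loc[scr, "lead_time_days"] > 0).all()
        # recorded time = lead + symptomatic survival when uncensored
        uncens = cohort["event"].to_numpy()
        total = truth["lead_time_days"] + truth["t_symptomatic_days"]
        assert np.allclose(cohort.loc[uncens, "time_days"],
                           total[uncens], rtol=1e-9)

    def test_subtype_fatality_ratio_matches_theta(self):
        cfg = SimConfig(n=150_000, theta=0.4, aggressive_fraction=0.5,
                        covariate_effects={}, censor_rate=0.0,
                        screen_prob_xf=0.0, screen_prob_nonxf=0.0,
                        baseline_hazard=0.2)
        cohort, truth = simulate_cohort(cfg, seed=6)
        dead5 = cohort["event"].to_numpy() & \
            (cohort["time_days"].to_numpy() <= 5 * 365.25)
        agg = truth["aggressive"].to_numpy()
        ratio = dead5[~agg].mean() / dead5[agg].mean()
        assert ratio == pytest.approx(0.4, abs=0.02)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(theta=0.0)
        with pytest.raises(ValueError):
            SimConfig(region_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(baseline_hazard=-1.0)
        # (q, theta) making the non-aggressive detection prob exceed 1
        cfg = SimConfig(screen_prob_xf=0.9, screen_prob_nonxf=0.9,
                        aggressive_fraction=0.9, theta=0.05)
        with pytest.raises(ValueError, match="detection probability"):
            simulate_cohort(cfg, seed=1)


class TestObservedSummaries:
    def test_hand_built_counting_fixture(self):
        rows = []
        # 3 screened, 1 dead within 5y; 7 symptomatic, 4 dead within 5y
        rows.append({"screened": True, "time_days": 400.0, "event": True})
        rows += [{"screened": True, "time_days": 2200.0, "event": False}] * 2
        rows += [{"screened": False, "time_days": 300.0, "event": True}] * 4
        rows += [{"screened": False, "time_days": 2100.0, "event": False}] * 3
        obs = observed_summaries(make_cohort_frame(rows))
        assert obs.p1 == pytest.approx(4 / 7)
        assert obs.p2 == pytest.approx(1 / 3)
        assert obs.p3 == pytest.approx(0.3)

    def test_death_after_horizon_not_counted(self):
        rows = [{"screened": True, "time_days": 6 * 365.25, "event": True},
                {"screened": False, "time_days": 300.0, "event": True}]
        obs = observed_summaries(make_cohort_frame(rows))
        assert obs.p2 == 0.0 and obs.degenerate

    def test_published_counts(self):
        from screenbias.lengthbias import ObservedFatalities
        from screenbias.study import FATALITY_COUNTS as C
        obs = ObservedFatalities.from_counts(
            C["symptomatic_deaths_5y"], C["symptomatic_n"],
            C["screened_deaths_5y"], C["screened_n"], C["cohort_n"])
        assert round(obs.p1, 2) == 0.58
        assert round(obs.p2, 2) == 0.21
        assert round(obs.p3, 3) == 0.079

    def test_all_alive_flagged_degenerate(self):
        rows = [{"screened": True, "time_days": 100.0, "event": False},
                {"screened": False, "time_days": 100.0, "event": False}]
        with pytest.warns(UserWarning, match="degenerate"):
            obs = observed_summaries(make_cohort_frame(rows))
        assert obs.p1 == 0.0 and obs.p2 == 0.0 and obs.degenerate

    def test_single_detection_group_rejected(self):
        rows = [{"screened": False, "time_days": 100.0, "event": True}] * 3
        with pytest.raises(ValueError):
            observed_summaries(make_cohort_frame(rows))

    def test_km_variant_exceeds_crude_under_censoring(self):
        cohort, _ = simulate_cohort(SimConfig(n=30_000), seed=9)
        crude = observed_summaries(cohort, method="crude")
        km = observed_summaries(cohort, method="km")
        assert km.p1 > crude.p1  # censoring deflates the crude ratio


class TestBiasStructure:
    def test_screening_biases_naive_hazard_down_and_corrections_recover(self):
        """With no true benefit (psi = 1), lead time plus the non-aggressive
        subtype make screening look protective; correcting at the generative
        lambda and solving at the true (q, theta) both move toward null."""
        from screenbias.leadtime import apply_sojourn_correction
        from screenbias.lengthbias import (solve_subtype_model,
                                           uncorrected_relative_hazard)
        from screenbias.survival import SIM_MODEL_SPEC, build_design, fit_cox
        cfg = SimConfig(n=20_000, true_psi=1.0, theta=0.2,
                        aggressive_fraction=0.5, sojourn_lambda=0.45)
        cohort, _ = simulate_cohort(cfg, seed=123)
        X, names = build_design(cohort, SIM_MODEL_SPEC)
        js = names.index("screened")
        t = cohort["time_days"].to_numpy()
        e = cohort["event"].to_numpy(bool)
        naive = fit_cox(t, e, X, names=names)
        assert naive.ci_high[js] < 1.0          # spurious benefit

        corr, _ = apply_sojourn_correction(
            cohort, np.full(int(cohort["screened"].sum()), 0.45))
        lead_fixed = fit_cox(corr["time_days"].to_numpy(), e, X, names=names)
        assert abs(np.log(lead_fixed.hr[js])) < abs(np.log(naive.hr[js]))

        obs = observed_summaries(cohort)
        sol = solve_subtype_model(obs, q=0.5, theta=0.2)
        assert sol.solved
        assert abs(np.log(sol.psi)) < abs(np.log(uncorrected_relative_hazard(obs)))
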