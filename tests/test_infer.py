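"""Group-level inference: penalized spline curves + CCD bands, epoch mixed
models, BHY adjustment, marginal-means contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liftucm.infer import (
    adjust_pvalues_bhy,
    ccd_contrast,
    ccd_critical_value,
    emm_contrasts,
    estimated_marginal_means,
    fit_cycle_curves,
    fit_epoch_model,
)
from liftucm.synth import generate_epoch_table, generate_h_table


class TestBhyAdjustment:
    def test_hand_computed_step_up_with_c6(self):
        p = [0.001, 0.01, 0.02, 0.04, 0.2, 0.5]
        # oracle: raw_i = 6 * c(6) * p_(i) / i with c(6) = 2.45, then
        # step-up suffix minimum, capped at 1
        expect = [0.0147, 0.0735, 0.098, 0.147, 0.588, 1.0]
        c6 = sum(1.0 / i for i in range(1, 7))
        raw = [6 * c6 * pi / (i + 1) for i, pi in enumerate(p)]
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        assert np.allclose(np.minimum(stepped, 1.0), expect, atol=1e-10)
        assert np.allclose(adjust_pvalues_bhy(np.array(p)), expect, atol=1e-10)

    def test_all_ones_stay_one(self):
        assert np.all(adjust_pvalues_bhy(np.ones(6)) == 1.0)

    def test_single_p_value_unchanged(self):
        assert adjust_pvalues_bhy(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, 6)
        adj = adjust_pvalues_bhy(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_monotone_in_the_p_values(self, pvals):
        p = np.array(pvals)
        adj = adjust_pvalues_bhy(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues_bhy(np.array([0.1, 1.5]))


class TestCurveModel:
    @pytest.fixture(scope="class")
    def null_table(self):
        return generate_h_table(n_per_group=8, seed=11)

    def test_identical_cells_give_equal_predictions(self, rng):
        rows = []
        curve = 0.5 + 0.1 * np.sin(np.linspace(0, np.pi, 50))
        for g in ("a", "b"):
            for s in range(3):
                for ph in ("lift", "lower"):
                    rows.append(
                        pd.DataFrame(
                            dict(subject=f"{g}{s}", group=g, phase=ph,
                                 cycle=np.arange(1, 51), value=curve)
                        )
                    )
        fit = fit_cycle_curves(pd.concat(rows, ignore_index=True))
        assert np.allclose(fit.predict("a", "lift"), fit.predict("b", "lift"), atol=1e-6)
        res = ccd_contrast(fit, "a", "b", "lift", g=1)
        assert not res.significant.any()

    def test_constant_shift_equivariance(self, null_table):
        shifted = null_table.copy()
        mask = shifted["group"] == "cLBP"
        shifted.loc[mask, "value"] += 1.0
        f0 = fit_cycle_curves(null_table)
        f1 = fit_cycle_curves(shifted)
        d_shift = f1.predict("cLBP", "lift") - f0.predict("cLBP", "lift")
        d_other = f1.predict("con", "lift") - f0.predict("con", "lift")
        assert np.allclose(d_shift, 1.0, atol=0.05)
        assert np.allclose(d_other, 0.0, atol=0.05)

    def test_smooth_truth_recovered_within_noise_tolerance(self):
        tab = generate_h_table(n_per_group=12, seed=3, sd_subject=0.0, sd_noise=0.1)
        fit = fit_cycle_curves(tab)
        t = np.linspace(0.0, 1.0, 100)
        truth = 0.5 + 0.35 * np.exp(-((t - 0.35) ** 2) / (2 * 0.15**2))
        pred = fit.predict("con", "lift")
        assert np.max(np.abs(pred - truth)) < 5 * 0.1 / np.sqrt(12)

    def test_singular_design_rejected(self):
        tab = generate_h_table(n_per_group=1, seed=0)
        with pytest.raises(ValueError, match="singular"):
            fit_cycle_curves(tab)

    def test_same_group_contrast_identically_zero(self, null_table):
        fit = fit_cycle_curves(null_table)
        res = ccd_contrast(fit, "con", "con", "lift")
        assert np.all(res.delta == 0) and not res.significant.any()

    def test_unknown_group_raises(self, null_table):
        fit = fit_cycle_curves(null_table)
        with pytest.raises(KeyError):
            ccd_contrast(fit, "con", "nope", "lift")

    def test_band_covers_planted_offset(self):
        tab = generate_h_table(n_per_group=16, seed=5, group_offsets={"cLBP": 0.35})
        fit = fit_cycle_curves(tab)
        res = ccd_contrast(fit, "cLBP", "con", "lift")
        assert res.significant.mean() > 0.9
        covered = (res.ci_low <= 0.45) & (0.45 <= res.ci_high)
        # the realized group difference for this draw is ~0.45
        assert covered.mean() > 0.9

    def test_critical_value_frozen_reference(self):
        # 1 - 0.05/12 quantile of t with 47 df, evaluated independently
        assert ccd_critical_value(0.05, 6, 47) == pytest.approx(2.754542, abs=1e-6)


class TestEpochModel:
    @pytest.fixture(scope="class")
    def phase_effect_table(self):
        return generate_epoch_table(n_per_group=16, seed=9,
                                    ima_effects={"phase:lower": 0.4})

    def test_planted_phase_effect_detected_group_null_not(self, phase_effect_table):
        res = fit_epoch_model(phase_effect_table, "ima", segment="pelvis")
        eff = res.effects.set_index("effect")
        assert eff.loc["phase", "p_adjusted"] < 0.05
        assert eff.loc["group", "p_adjusted"] > 0.05
        assert res.converged

    def test_adjusted_p_at_least_raw(self, phase_effect_table):
        res = fit_epoch_model(phase_effect_table, "ima", segment="trunk")
        assert np.all(res.effects["p_adjusted"] >= res.effects["p"] - 1e-12)
        assert np.all(res.effects["p_adjusted"] <= 1.0)

    def test_duplicating_every_subject_leaves_estimates_unchanged(self, phase_effect_table):
        dup = phase_effect_table.copy()
        dup["subject"] = dup["subject"] + "_copy"
        both = pd.concat([phase_effect_table, dup], ignore_index=True)
        r1 = fit_epoch_model(phase_effect_table, "ima", segment="pelvis")
        r2 = fit_epoch_model(both, "ima", segment="pelvis")
        assert np.allclose(r1.params, r2.params, atol=1e-6)

    def test_permuted_response_mostly_null(self):
        tab = generate_epoch_table(n_per_group=16, seed=21,
                                   ima_effects={"phase:lower": 0.4})
        sub = tab[tab.segment == "pelvis"].copy().reset_index(drop=True)
        r = np.random.default_rng(4)
        sub["ima"] = r.permutation(sub["ima"].to_numpy())
        res = fit_epoch_model(sub, "ima")
        assert not res.significant_effects(alpha=0.05)

    def test_missing_cells_rejected(self, phase_effect_table):
        broken = phase_effect_table[
            ~((phase_effect_table.group == "con") & (phase_effect_table.phase == "lift"))
        ]
        with pytest.raises(ValueError, match="unbalanced"):
            fit_epoch_model(broken, "ima", segment="pelvis")


class TestEmmContrasts:
    @pytest.fixture(scope="class")
    def fitted(self):
        tab = generate_epoch_table(n_per_group=16, seed=9,
                                   ima_effects={"phase:lower": 0.4})
        return tab, fit_epoch_model(tab, "ima", segment="pelvis")

    def test_balanced_marginal_means_equal_raw_cell_averages(self, fitted):
        tab, res = fitted
        emm = estimated_marginal_means(res, "phase").set_index("level")
        raw = tab[tab.segment == "pelvis"].groupby("phase")["ima"].mean()
        for lev in raw.index:
            assert emm.loc[lev, "emmean"] == pytest.approx(raw[lev], abs=1e-6)

    def test_planted_lift_lower_difference_recovered(self, fitted):
        _, res = fitted
        out = emm_contrasts(res, "phase")
        row = out.iloc[0]
        assert row["contrast"] == "lift - lower"
        assert row["estimate"] == pytest.approx(-0.4, abs=3 * row["se"])
        assert row["p"] < 0.05

    def test_gating_blocks_nonsignificant_factor(self, fitted):
        _, res = fitted
        with pytest.raises(ValueError, match="no significant effect"):
            emm_contrasts(res, "group")
        forced = emm_contrasts(res, "group", force=True)
        assert len(forced) == 3  # 3 pairwise group contrasts
        assert (forced["p"] > 0.05).all()

    def test_unknown_factor_rejected(self, fitted):
        _, res = fitted
        with pytest.raises(KeyError):
            emm_contrasts(res, "segment")
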