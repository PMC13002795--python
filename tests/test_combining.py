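"""GCA/SCA estimators, the reference-level fit, and effect significance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncd2.combining import (
    combining_ability_table,
    effect_t_test,
    gca_sca_reference_ls,
    gca_simple,
    sca_simple,
)
from ncd2.trial import CrossMeanTable, TraitCatalog, cross_mean_table

from .conftest import make_trial


def means_from_cells(cells):
    rows = [{"female": f, "male": m, "y": float(v)} for (f, m), v in cells.items()]
    return CrossMeanTable(pd.DataFrame(rows), TraitCatalog(("y",)))


ADDITIVE_2X2 = {("F1", "M1"): 10, ("F1", "M2"): 14, ("F2", "M1"): 6, ("F2", "M2"): 10}
CROSSED_2X2 = {("F1", "M1"): 12, ("F1", "M2"): 8, ("F2", "M1"): 8, ("F2", "M2"): 12}


class TestSimpleEstimators:
    def test_equal_means_give_zero_effects(self):
        means = means_from_cells({k: 5.0 for k in ADDITIVE_2X2})
        for g in gca_simple(means, "female", "y"):
            assert g.effect == pytest.approx(0.0)

    def test_hand_computed_gca(self):
        means = means_from_cells(ADDITIVE_2X2)
        effects = {g.parent: g.effect for g in gca_simple(means, "female", "y")}
        assert effects == {"F1": pytest.approx(2.0), "F2": pytest.approx(-2.0)}

    def test_example_trial_female_gca(self, example_means):
        effects = {
            g.parent: g.effect for g in gca_simple(example_means, "female", "GYPP_g")
        }
        # mean(19.0, 12.1) - mean of all 8 cross means
        assert effects["Kudya"] == pytest.approx(15.55 - 13.8625)

    def test_additive_table_sca_zero(self):
        means = means_from_cells(ADDITIVE_2X2)
        gf = gca_simple(means, "female", "y")
        gm = gca_simple(means, "male", "y")
        for s in sca_simple(means, gf, gm, "y"):
            assert s.effect == pytest.approx(0.0, abs=1e-12)

    def test_pure_interaction_table(self):
        means = means_from_cells(CROSSED_2X2)
        gf = gca_simple(means, "female", "y")
        gm = gca_simple(means, "male", "y")
        sca = {(s.cross.female, s.cross.male): s.effect for s in sca_simple(means, gf, gm, "y")}
        assert sca[("F1", "M1")] == pytest.approx(2.0)
        assert sca[("F1", "M2")] == pytest.approx(-2.0)
        assert sca[("F2", "M1")] == pytest.approx(-2.0)
        assert sca[("F2", "M2")] == pytest.approx(2.0)

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=25, deadline=None)
    def test_decomposition_identity_random(self, seed):
        """mu + g_i + g_j + s_ij reconstructs every cross mean exactly."""
        means = cross_mean_table(make_trial(p=3, q=3, r=2, seed=seed))
        table = combining_ability_table(means, "y")
        for c in means.crosses:
            assert table.fitted_value(c.female, c.male) == pytest.approx(
                means.value(c.female, c.male, "y"), abs=1e-9
            )

    def test_sum_to_zero_on_complete_design(self):
        means = cross_mean_table(make_trial(p=4, q=3, r=2, seed=3))
        table = combining_ability_table(means, "y")
        assert sum(g.effect for g in table.gca_female) == pytest.approx(0.0, abs=1e-9)
        assert sum(g.effect for g in table.gca_male) == pytest.approx(0.0, abs=1e-9)
        # SCA sums vanish along every row and column
        for f in means.females:
            assert sum(
                s.effect for s in table.sca if s.cross.female == f
            ) == pytest.approx(0.0, abs=1e-9)
        for m in means.males:
            assert sum(
                s.effect for s in table.sca if s.cross.male == m
            ) == pytest.approx(0.0, abs=1e-9)

    def test_weighted_sum_zero_on_incomplete_margins(self, example_means):
        """With unequal cross counts the GCA deviations cancel only when
        weighted by each parent's number of realized crosses."""
        counts = example_means.data.groupby("male").size()
        effects = {g.parent: g.effect for g in gca_simple(example_means, "male", "GYPP_g")}
        weighted = sum(counts[p] * e for p, e in effects.items())
        assert weighted == pytest.approx(0.0, abs=1e-9)


class TestReferenceLevelFit:
    def test_reference_effects_are_zero(self, example_means):
        table = gca_sca_reference_ls(
            example_means, "GYPP_g", "Makafaci", "Kayanjamalo"
        )
        gf = {g.parent: g.effect for g in table.gca_female}
        gm = {g.parent: g.effect for g in table.gca_male}
        assert gf["Makafaci"] == 0.0
        assert gm["Kayanjamalo"] == 0.0

    def test_additive_table_reparameterization(self):
        means = means_from_cells(ADDITIVE_2X2)
        table = gca_sca_reference_ls(means, "y", "F1", "M1")
        gf = {g.parent: g.effect for g in table.gca_female}
        assert gf["F2"] == pytest.approx(-4.0)
        # centering the reference-level effects recovers the sum-to-zero ones
        centered = {p: e - np.mean(list(gf.values())) for p, e in gf.items()}
        stz = {g.parent: g.effect for g in gca_simple(means, "female", "y")}
        for p in gf:
            assert centered[p] == pytest.approx(stz[p], abs=1e-9)

    def test_saturated_fit_reproduces_means(self, example_means):
        table = gca_sca_reference_ls(
            example_means, "GYPP_g", "Makafaci", "Kayanjamalo"
        )
        for c in example_means.crosses:
            assert table.fitted_value(c.female, c.male) == pytest.approx(
                example_means.value(c.female, c.male, "GYPP_g"), abs=1e-9
            )

    def test_structural_zeros_on_incomplete_grid(self, example_means):
        table = gca_sca_reference_ls(
            example_means, "GYPP_g", "Makafaci", "Kayanjamalo"
        )
        n_structural = sum(s.structural_zero for s in table.sca)
        # 8 cells - 6 main-effect parameters = 2 identifiable interactions
        assert n_structural == 6
        assert all(s.effect == 0.0 for s in table.sca if s.structural_zero)

    def test_estimator_agreement_on_complete_design(self):
        """Reference-level and sum-to-zero fits describe the same cell means."""
        means = cross_mean_table(make_trial(p=3, q=2, r=2, seed=21))
        ref = gca_sca_reference_ls(means, "y")
        stz = combining_ability_table(means, "y")
        for c in means.crosses:
            assert ref.fitted_value(c.female, c.male) == pytest.approx(
                stz.fitted_value(c.female, c.male), abs=1e-9
            )

    def test_unknown_reference_rejected(self, example_means):
        with pytest.raises(ValueError, match="reference"):
            gca_sca_reference_ls(example_means, "GYPP_g", "Nobody", None)


class TestEffectTTest:
    def test_null_effect(self):
        t, sig = effect_t_test(0.0, 1.0, 10)
        assert t == 0.0 and not sig

    def test_borderline_t_table_case(self):
        # |t| = 2.14 vs two-sided critical 2.145 at 14 df
        t, sig = effect_t_test(4.28, 2.0, 14, alpha=0.05)
        assert t == pytest.approx(2.14)
        assert not sig

    def test_effect_equal_to_se(self):
        t, _ = effect_t_test(3.3, 3.3, 5)
        assert t == pytest.approx(1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            effect_t_test(1.0, 0.0, 10)

    def test_attached_significance(self, example_means, example_ms):
        gca = gca_simple(
            example_means,
            "female",
            "GYPP_g",
            ms_error=float(example_ms.loc["error", "GYPP_g"]),
            r=3,
            df_error=14,
        )
        for g in gca:
            assert g.se == pytest.approx(np.sqrt(12.84 / (2 * 3)))
            assert g.t_value == pytest.approx(g.effect / g.se)


class TestParameterRecovery:
    def test_gca_effects_track_simulated_truth(self):
        """With many blocks and tiny error the simple-means GCA estimates
        correlate almost perfectly with the simulated true effects."""
        from ncd2.simulate import SimulationConfig, simulate_trial
        from ncd2.trial import cross_mean_table

        cfg = SimulationConfig(
            mu=50.0, sigma2_f=4.0, sigma2_m=4.0, sigma2_fm=0.05,
            sigma2_block=0.1, sigma2_e=0.01, p=6, q=6, r=20, seed=77,
        )
        trial, effects = simulate_trial(cfg, ("y",), return_effects=True)
        means = cross_mean_table(trial)
        est = np.array([g.effect for g in gca_simple(means, "female", "y")])
        truth = effects["y"]["female"]
        truth = truth - truth.mean()  # estimator is centered by construction
        assert np.corrcoef(est, truth)[0, 1] > 0.99
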