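"""RCBD ANOVA, factorial partition, and trial statistics.

The factorial sums of squares are checked against an exhaustive
deviation-sum oracle that knows nothing about the implementation: it
computes every SS directly from marginal means by brute-force summation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncd2.anova import (
    factorial_partition,
    rcbd_anova,
    significance_stars,
    trial_stats,
    trial_stats_from_ms,
)
from ncd2.trial import TraitCatalog, TrialDataset

from .conftest import make_trial, trial_from_cells


def oracle_factorial_ss(trial, trait="y"):
    """Brute-force marginal deviation sums for a complete balanced grid."""
    df = trial.data
    grand = df[trait].mean()
    p, q, r = trial.p, trial.q, trial.r
    ss = {}
    ss["female"] = r * q * sum(
        (df[df["female"] == f][trait].mean() - grand) ** 2 for f in trial.females
    )
    ss["male"] = r * p * sum(
        (df[df["male"] == m][trait].mean() - grand) ** 2 for m in trial.males
    )
    ss["block"] = p * q * sum(
        (df[df["block"] == b][trait].mean() - grand) ** 2 for b in trial.blocks
    )
    inter = 0.0
    for f in trial.females:
        for m in trial.males:
            cell = df[(df["female"] == f) & (df["male"] == m)][trait].mean()
            fbar = df[df["female"] == f][trait].mean()
            mbar = df[df["male"] == m][trait].mean()
            inter += (cell - fbar - mbar + grand) ** 2
    ss["interaction"] = r * inter
    total = ((df[trait] - grand) ** 2).sum()
    cells = r * sum(
        (df[(df["female"] == f) & (df["male"] == m)][trait].mean() - grand) ** 2
        for f in trial.females
        for m in trial.males
    )
    ss["error"] = total - ss["block"] - cells
    return ss


class TestRcbdAnova:
    def test_hand_computed_two_by_two(self):
        ds = trial_from_cells({("F1", "M1"): [10, 12], ("F2", "M1"): [14, 16]})
        rows = {r.source: r for r in rcbd_anova(ds, "y")}
        assert rows["genotype"].ss == pytest.approx(16.0)
        assert rows["block"].ss == pytest.approx(4.0)
        assert rows["error"].ss == pytest.approx(0.0, abs=1e-12)

    def test_constant_data_gives_nan_f(self):
        ds = trial_from_cells({("F1", "M1"): [7, 7], ("F2", "M1"): [7, 7]})
        rows = {r.source: r for r in rcbd_anova(ds, "y")}
        assert rows["genotype"].ss == pytest.approx(0.0)
        assert np.isnan(rows["genotype"].f_value)

    def test_single_block_rejected(self):
        ds = trial_from_cells({("F1", "M1"): [1], ("F2", "M1"): [2]}, r=1)
        with pytest.raises(ValueError, match="2 blocks"):
            rcbd_anova(ds, "y")

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=20, deadline=None)
    def test_ss_match_bruteforce(self, seed):
        trial = make_trial(p=4, q=2, r=3, seed=seed)
        rows = {r.source: r for r in rcbd_anova(trial, "y")}
        df = trial.data
        grand = df["y"].mean()
        geno = trial.r * sum(
            (df[(df["female"] == f) & (df["male"] == m)]["y"].mean() - grand) ** 2
            for f in trial.females
            for m in trial.males
        )
        assert rows["genotype"].ss == pytest.approx(geno, rel=1e-9)


class TestFactorialPartition:
    @pytest.mark.parametrize("p,q,r", [(2, 2, 2), (2, 3, 2), (3, 3, 3), (3, 2, 3)])
    def test_ss_match_oracle_small_complete_designs(self, p, q, r):
        for seed in (1, 2, 3):
            trial = make_trial(p=p, q=q, r=r, seed=seed)
            anova = factorial_partition(trial, "y")
            oracle = oracle_factorial_ss(trial)
            for name in ("female", "male", "interaction", "error", "block"):
                row = getattr(anova, name)
                assert row.ss == pytest.approx(oracle[name], abs=1e-8), name

    def test_sequential_equals_balanced_on_complete_grid(self):
        from ncd2.anova import _balanced_partition, _sequential_partition

        trial = make_trial(p=3, q=3, r=2, seed=9)
        bal = _balanced_partition(trial, "y")
        seq = _sequential_partition(trial, "y")
        for name in bal:
            assert bal[name][0] == pytest.approx(seq[name][0], abs=1e-8)
            assert bal[name][1] == seq[name][1]

    def test_equal_female_margins_zero_female_ss(self):
        # values depend on male only -> no female marginal variance
        cells = {
            (f, m): [v, v]
            for f in ("F1", "F2")
            for m, v in (("M1", 3.0), ("M2", 8.0))
        }
        anova = factorial_partition(trial_from_cells(cells), "y")
        assert anova.female.ss == pytest.approx(0.0, abs=1e-12)

    def test_strata_sum_to_rcbd_genotype_ss(self, small_trial):
        anova = factorial_partition(small_trial, "y")
        geno = {r.source: r for r in rcbd_anova(small_trial, "y")}["genotype"]
        strata = anova.female.ss + anova.male.ss + anova.interaction.ss
        assert strata == pytest.approx(geno.ss, rel=1e-6)

    def test_df_bookkeeping(self, small_trial):
        anova = factorial_partition(small_trial, "y")
        n = len(small_trial.data)
        total_df = (
            anova.female.df
            + anova.male.df
            + anova.interaction.df
            + anova.error.df
            + anova.block.df
        )
        assert total_df == n - 1

    def test_incomplete_grid_rank_based_df(self):
        # 8 realized cells of a 4x3 grid: interaction df = 7 - 3 - 2 = 2
        from ncd2.simulate import example_trial_config, simulate_trial

        trial = simulate_trial(example_trial_config(3), ("y",))
        anova = factorial_partition(trial, "y")
        assert (anova.female.df, anova.male.df) == (3, 2)
        assert anova.interaction.df == 2
        assert anova.error.df == 14  # RCBD residual (8-1)(3-1)

    def test_interaction_f_is_ms_ratio(self, small_trial):
        anova = factorial_partition(small_trial, "y")
        assert anova.interaction.f_value == pytest.approx(
            anova.interaction.ms / anova.error.ms
        )

    def test_denominator_switch(self, small_trial):
        ems = factorial_partition(small_trial, "y", denominator="ems")
        err = factorial_partition(small_trial, "y", denominator="error")
        assert ems.female.f_value == pytest.approx(ems.female.ms / ems.interaction.ms)
        assert err.female.f_value == pytest.approx(err.female.ms / err.error.ms)

    def test_orphan_parent_warns(self):
        ds = trial_from_cells(
            {("F1", "M1"): [1, 2], ("F1", "M2"): [2, 3],
             ("F2", "M1"): [3, 4], ("F2", "M2"): [4, 5]}
        )
        ds.females.append("F3")  # declared but never crossed
        with pytest.warns(UserWarning, match="F3"):
            factorial_partition(ds, "y")


class TestTrialStats:
    def test_se_from_error_ms(self):
        st_ = trial_stats_from_ms(ms_error=12.84, df_error=14, r=3, grand_mean=13.8625)
        assert round(st_.se_mean, 2) == 2.07

    def test_se_for_tall_trait(self):
        st_ = trial_stats_from_ms(ms_error=42.45, df_error=14, r=3, grand_mean=84.5)
        assert round(st_.se_mean, 2) == 3.76

    def test_zero_error_degenerate(self):
        st_ = trial_stats_from_ms(ms_error=0.0, df_error=14, r=3, grand_mean=5.0)
        assert st_.se_mean == 0.0 and st_.lsd_5 == 0.0

    def test_zero_grand_mean_cv_nan(self):
        st_ = trial_stats_from_ms(ms_error=1.0, df_error=10, r=2, grand_mean=0.0)
        assert np.isnan(st_.cv_pct)

    def test_from_dataset_consistent(self, small_trial):
        rows = rcbd_anova(small_trial, "y")
        st_ = trial_stats(small_trial, "y", rows)
        err = {r.source: r for r in rows}["error"]
        assert st_.se_mean == pytest.approx(np.sqrt(err.ms / small_trial.r))
        assert st_.cv_pct == pytest.approx(
            100 * np.sqrt(err.ms) / small_trial.data["y"].mean()
        )


def test_significance_stars_thresholds():
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.2) == "ns"
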