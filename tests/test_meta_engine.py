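"""Effect sizes, DerSimonian-Laird pooling and the cumulative Z-curve.

The pooling oracle is statsmodels' independent DL implementation; hand
arithmetic anchors the 2x2 effect sizes.
"""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from tsameta import (
    Design,
    NoInformationError,
    Outcome,
    OutcomeDataset,
    TwoByTwoTrial,
    cumulative_curve,
    effect_from_2x2,
    forest_table,
    pool_dl,
)

from test_trial_data import make_trial


class TestEffectFrom2x2:
    def test_hand_computed_log_or(self):
        # 34/39 vs 32/40 events: OR = (34*8)/(5*32) = 1.700
        t = make_trial(n_int=39, e_int=34, n_ctl=40, e_ctl=32)
        e = effect_from_2x2(t)
        assert e.log_or == pytest.approx(math.log(1.7), abs=1e-12)
        assert e.var == pytest.approx(1 / 34 + 1 / 5 + 1 / 8 + 1 / 32, abs=1e-12)
        assert not e.corrected

    def test_symmetric_table_is_null(self):
        e = effect_from_2x2(make_trial(n_int=20, e_int=10, n_ctl=20, e_ctl=10))
        assert e.log_or == 0.0

    def test_zero_cell_gets_half_integer_correction(self):
        # 0/19 vs 2/80 events: corrected cells (0.5, 19.5, 2.5, 78.5)
        t = make_trial(n_int=19, e_int=0, n_ctl=80, e_ctl=2)
        e = effect_from_2x2(t)
        assert e.corrected
        assert e.log_or == pytest.approx(math.log((0.5 * 78.5) / (19.5 * 2.5)), abs=1e-12)
        assert e.log_or == pytest.approx(-0.2167, abs=5e-4)

    def test_double_zero_signals_no_information(self):
        with pytest.raises(NoInformationError):
            effect_from_2x2(make_trial(e_int=0, e_ctl=0))
        with pytest.raises(NoInformationError):
            effect_from_2x2(make_trial(e_int=10, n_int=10, e_ctl=20, n_ctl=20))


class TestPoolDL:
    def test_single_effect_identity(self):
        e = effect_from_2x2(make_trial())
        p = pool_dl([e])
        assert p.theta == pytest.approx(e.log_or)
        assert p.tau2 == 0.0 and p.d2 == 0.0 and p.i2 == 0.0

    def test_identical_effects_are_homogeneous(self):
        e = effect_from_2x2(make_trial())
        p = pool_dl([e, e])
        assert p.q == pytest.approx(0.0, abs=1e-12)
        assert p.tau2 == 0.0
        assert p.theta == pytest.approx(e.log_or)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_dl([])

    def test_ci_brackets_pooled_or(self, lvt):
        for ds in lvt.values():
            eff = [effect_from_2x2(t) for t in ds.trials if not t.no_information]
            p = pool_dl(eff)
            assert p.ci_low <= p.odds_ratio <= p.ci_high
            assert 0.0 <= p.i2 <= 1.0 and 0.0 <= p.d2 < 1.0
            if p.tau2 > 0:
                assert p.d2 >= p.i2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_statsmodels_dl(self, seed):
        """Independent oracle: statsmodels combine_effects, DL variant."""
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 12)
        eff = rng.normal(0.3, 0.5, k)
        var = rng.uniform(0.05, 0.6, k)
        ours = pool_dl(
            [type("E", (), {"log_or": e, "var": v})() for e, v in zip(eff, var)]
        )
        ref = combine_effects(eff, var, method_re="dl")
        # statsmodels reports the raw method-of-moments tau2, which may be
        # negative; DL truncates at zero, where random = fixed effect
        assert ours.tau2 == pytest.approx(max(0.0, ref.tau2), abs=1e-10)
        frame = ref.summary_frame()
        row = frame.loc["random effect" if ref.tau2 > 0 else "fixed effect"]
        assert ours.theta == pytest.approx(row["eff"], abs=1e-10)
        assert ours.se == pytest.approx(row["sd_eff"], abs=1e-10)
        assert ours.q == pytest.approx(ref.q, abs=1e-10)


def _random_dataset(rng, k=6, desirable=False):
    trials = []
    for i in range(k):
        n1, n2 = rng.randint(5, 60), rng.randint(5, 60)
        trials.append(
            TwoByTwoTrial(
                study_id=f"s{i}", year=2000 + i, design=Design.RCT,
                n_int=n1, e_int=rng.randint(0, n1),
                n_ctl=n2, e_ctl=rng.randint(0, n2),
            )
        )
    return OutcomeDataset(
        outcome=Outcome.STROKE, trials=tuple(trials), events_desirable=desirable
    )


class TestCumulativeCurve:
    def test_cumulative_n_strictly_increasing(self, lvt):
        for ds in lvt.values():
            curve = cumulative_curve(ds)
            ns = [p.cumulative_n for p in curve]
            assert all(b > a for a, b in zip(ns, ns[1:]))
            assert ns[-1] == ds.n_total

    def test_final_point_equals_full_pooling(self, resolution):
        curve = cumulative_curve(resolution)
        eff = [effect_from_2x2(t) for t in resolution.trials if not t.no_information]
        full = pool_dl(eff)
        assert curve[-1].theta_cum == pytest.approx(full.theta)
        assert curve[-1].z_signed == pytest.approx(full.z)  # events desirable: no flip

    def test_sign_flip_for_undesirable_events(self, lvt):
        ds = lvt[Outcome.STROKE]
        curve = cumulative_curve(ds)
        eff = [effect_from_2x2(t) for t in ds.trials if not t.no_information]
        assert curve[-1].z_signed == pytest.approx(-pool_dl(eff).z)

    def test_single_symmetric_trial_gives_zero(self):
        ds = OutcomeDataset(
            outcome=Outcome.STROKE,
            trials=(make_trial(n_int=20, e_int=10, n_ctl=20, e_ctl=10),),
        )
        (point,) = cumulative_curve(ds)
        assert point.z_signed == 0.0

    def test_double_zero_trials_accrue_patients_only(self):
        ds = OutcomeDataset(
            outcome=Outcome.STROKE,
            trials=(
                make_trial("a", 2019),
                make_trial("b", 2020, e_int=0, e_ctl=0),
            ),
        )
        curve = cumulative_curve(ds)
        assert len(curve) == 2
        assert curve[1].cumulative_n == 60
        assert curve[1].z_signed == pytest.approx(curve[0].z_signed)

    def test_all_no_information_gives_empty_curve(self):
        ds = OutcomeDataset(
            outcome=Outcome.STROKE, trials=(make_trial(e_int=0, e_ctl=0),)
        )
        assert cumulative_curve(ds) == []

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_arm_swap_orientation_invariance(self, seed):
        """Relabelling arms and toggling desirability preserves |z| per look."""
        rng = random.Random(seed)
        ds = _random_dataset(rng, k=4, desirable=bool(rng.getrandbits(1)))
        swapped = OutcomeDataset(
            outcome=ds.outcome,
            trials=tuple(t.swapped_arms() for t in ds.trials),
            events_desirable=not ds.events_desirable,
        )
        za = [p.z_signed for p in cumulative_curve(ds)]
        zb = [p.z_signed for p in cumulative_curve(swapped)]
        assert len(za) == len(zb)
        for a, b in zip(za, zb):
            assert abs(a) == pytest.approx(abs(b), abs=1e-9)

    def test_same_year_permutation_is_canonical(self):
        a = make_trial("alpha", 2020, e_int=2)
        b = make_trial("beta", 2020, e_int=7)
        d1 = OutcomeDataset(outcome=Outcome.STROKE, trials=(a, b))
        d2 = OutcomeDataset(outcome=Outcome.STROKE, trials=(b, a))
        z1 = [p.z_signed for p in cumulative_curve(d1)]
        z2 = [p.z_signed for p in cumulative_curve(d2)]
        assert z1 == z2

    def test_monotone_information_under_homogeneity(self):
        """Fixed-effect cumulative SE never grows when tau2 stays zero."""
        e = effect_from_2x2(make_trial())
        ses = [pool_dl([e] * k).se for k in range(1, 8)]
        assert all(b <= a for a, b in zip(ses, ses[1:]))


class TestForestTable:
    def test_pooled_row_and_weights(self, any_bleeding):
        tab = forest_table(any_bleeding)
        assert tab.iloc[-1]["study_id"] == "RE pooled"
        weights = tab.iloc[:-1]["weight_pct"]
        assert weights.sum() == pytest.approx(100.0)
        assert (tab.iloc[:-1]["ci_low"] <= tab.iloc[:-1]["or"]).all()
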