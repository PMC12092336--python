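import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from mapse3d import (
    HemoInputs,
    MonitoringSeries,
    bland_altman,
    compare_correlations,
    derived_hemodynamics,
    fit_linked_replicates,
    lsc,
    simulate_test_retest,
    spearman,
    time_weighted_average,
)
from mapse3d import TestRetestParams as RetestParams
from mapse3d.stats import CHEN_END_POLY, CHEN_END_REGRESSION, chen_normalized_elastance


class TestLsc:
    def test_zero_sd_gives_zero_for_all_n(self):
        for n in (1, 2, 3, 10):
            assert lsc(0.0, n) == 0.0

    def test_quadrupling_n_halves_lsc(self):
        assert lsc(0.7, 4) == pytest.approx(lsc(0.7, 1) / 2.0)

    @settings(derandomize=True, max_examples=40)
    @given(sd=st.floats(0, 10), n=st.integers(1, 50))
    def test_sqrt_n_scaling_invariant(self, sd, n):
        assert lsc(sd, n) * math.sqrt(n) == pytest.approx(lsc(sd, 1), rel=1e-12)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            lsc(1.0, 0)


class TestBlandAltman:
    def test_identical_columns_collapse(self):
        r = bland_altman([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert r.bias == r.loa_low == r.loa_high == 0.0

    def test_constant_offset(self):
        a = np.array([3.0, 4.0, 5.0])
        r = bland_altman(a, a + 1.0)
        assert r.bias == pytest.approx(-1.0)
        assert r.sd_diff == 0.0

    def test_five_pair_hand_computation(self):
        # differences: 0.2, -0.5, 0.6, -0.1, -0.6 -> mean -0.08,
        # sample SD sqrt(0.988/4) = 0.4969909...
        a = [5.0, 6.0, 7.0, 8.0, 9.0]
        b = [4.8, 6.5, 6.4, 8.1, 9.6]
        r = bland_altman(a, b)
        assert r.bias == pytest.approx(-0.08)
        assert r.sd_diff == pytest.approx(0.49699095, abs=1e-7)
        assert r.loa_low == pytest.approx(-0.08 - 1.96 * 0.49699095, abs=1e-6)
        assert r.loa_high == pytest.approx(-0.08 + 1.96 * 0.49699095, abs=1e-6)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(
            st.tuples(st.floats(-20, 20), st.floats(-20, 20)), min_size=2, max_size=40
        ).filter(lambda ps: len({round(a - b, 9) for a, b in ps}) > 1)
    )
    def test_loa_midpoint_equals_bias(self, pairs):
        a, b = zip(*pairs)
        r = bland_altman(a, b)
        assert 0.5 * (r.loa_low + r.loa_high) == pytest.approx(r.bias, abs=1e-9)


def _brute_force_components(table):
    """Independent method-of-moments oracle via explicit ANOVA loops."""
    wide = table.pivot_table(
        index=["subject", "replicate"], columns="method", values="value_mm"
    )
    subjects = sorted({s for s, _ in wide.index})
    R = len(wide.loc[subjects[0]])
    d = {s: (wide.loc[s, "A"] - wide.loc[s, "B"]).to_numpy() for s in subjects}
    I = len(subjects)
    grand = np.mean([x for s in subjects for x in d[s]])
    msb = sum(len(d[s]) * (d[s].mean() - grand) ** 2 for s in subjects) / (I - 1)
    msw = sum(((d[s] - d[s].mean()) ** 2).sum() for s in subjects) / (I * (R - 1))
    two_tau2 = max(0.0, (msb - msw) / R)

    def within(method):
        return sum(
            ((wide.loc[s, method] - wide.loc[s, method].mean()) ** 2).sum()
            for s in subjects
        ) / (I * (R - 1))

    wa, wb = within("A"), within("B")
    sa2 = max(0.0, 0.5 * (msw + wa - wb))
    sb2 = max(0.0, 0.5 * (msw - wa + wb))
    omega2 = max(0.0, 0.5 * ((wa - sa2) + (wb - sb2)))
    return {
        "bias": grand,
        "sd_diff": math.sqrt(two_tau2 + msw),
        "sigma_a": math.sqrt(sa2),
        "sigma_b": math.sqrt(sb2),
        "var_replicate": omega2,
        "var_interaction": two_tau2 / 2,
    }


class TestFitLinkedReplicates:
    def test_zero_noise_collapses_to_zero(self):
        p = RetestParams(
            n_subjects=4, true_mapse_sd=0.0, within_subject_sd=0.0, method_bias=0.0,
            method_sd_a=0.0, method_sd_b=0.0,
        )
        table, _ = simulate_test_retest(p)
        r = fit_linked_replicates(table)
        assert r.bias == r.sd_diff == r.loa_low == r.loa_high == 0.0
        assert r.var_replicate == r.var_interaction == 0.0
        assert r.resid_sd == {"A": 0.0, "B": 0.0}

    def test_recovers_simulated_bias_within_3_se(self):
        p = RetestParams(n_subjects=2000, method_bias=-1.4, seed=10)
        table, _ = simulate_test_retest(p)
        r = fit_linked_replicates(table)
        assert abs(r.bias - (-1.4)) < 3 * r.bias_se

    def test_matches_brute_force_anova_on_small_fixture(self):
        rng = np.random.default_rng(5)
        rows = []
        for s in range(3):
            for rep in range(3):
                base = 5 + s + 0.3 * rep
                rows.append({"subject": s, "method": "A", "replicate": rep,
                             "value_mm": base + rng.normal(0, 0.5)})
                rows.append({"subject": s, "method": "B", "replicate": rep,
                             "value_mm": base + 1.0 + rng.normal(0, 0.2)})
        table = pd.DataFrame(rows)
        r = fit_linked_replicates(table)
        expect = _brute_force_components(table)
        assert r.bias == pytest.approx(expect["bias"], abs=1e-9)
        assert r.sd_diff == pytest.approx(expect["sd_diff"], abs=1e-9)
        assert r.resid_sd["A"] == pytest.approx(expect["sigma_a"], abs=1e-9)
        assert r.resid_sd["B"] == pytest.approx(expect["sigma_b"], abs=1e-9)
        assert r.var_replicate == pytest.approx(expect["var_replicate"], abs=1e-9)
        assert r.var_interaction == pytest.approx(expect["var_interaction"], abs=1e-9)

    def test_recovers_interaction_and_replicate_components(self):
        p = RetestParams(
            n_subjects=4000, within_subject_sd=0.6, interaction_sd=0.5, seed=11
        )
        table, _ = simulate_test_retest(p)
        r = fit_linked_replicates(table)
        assert r.var_replicate == pytest.approx(0.36, abs=0.05)
        assert r.var_interaction == pytest.approx(0.25, abs=0.05)
        assert r.resid_sd["A"] == pytest.approx(p.method_sd_a, abs=0.03)
        assert r.resid_sd["B"] == pytest.approx(p.method_sd_b, abs=0.03)

    def test_agrees_with_bland_altman_on_subject_means_when_unlinked_effects_absent(self):
        p = RetestParams(n_subjects=500, within_subject_sd=0.0, seed=12)
        table, _ = simulate_test_retest(p)
        r = fit_linked_replicates(table)
        wide = table.pivot_table(index="subject", columns="method", values="value_mm")
        ba = bland_altman(wide["A"], wide["B"])
        assert r.bias == pytest.approx(ba.bias, abs=1e-9)

    def test_single_replicate_rejected_with_named_assumption(self):
        table = pd.DataFrame(
            {"subject": [0, 0, 1, 1], "method": ["A", "B", "A", "B"],
             "replicate": [0, 0, 0, 0], "value_mm": [5.0, 6.0, 5.5, 6.5]}
        )
        with pytest.raises(ValueError, match="replicate"):
            fit_linked_replicates(table)

    def test_unlinked_design_rejected(self):
        # method A measured replicates 0-2, method B replicates 3-5: no link
        rows = [
            {"subject": s, "method": m, "replicate": rep + (3 if m == "B" else 0),
             "value_mm": 5.0}
            for s in range(3) for m in "AB" for rep in range(3)
        ]
        with pytest.raises(ValueError, match="unlinked|pair"):
            fit_linked_replicates(pd.DataFrame(rows))

    def test_per_method_lsc_from_residual_sd(self):
        p = RetestParams(n_subjects=3000, seed=13)
        table, _ = simulate_test_retest(p)
        r = fit_linked_replicates(table)
        assert r.lsc_for("A", 1) == pytest.approx(1.6, abs=0.1)
        assert r.lsc_for("B", 1) == pytest.approx(0.9, abs=0.1)
        assert r.lsc_for("A", 3) == pytest.approx(r.lsc_for("A", 1) / math.sqrt(3))


class TestTimeWeightedAverage:
    def test_constant_series(self):
        s = MonitoringSeries([0.0, 5.0, 10.0], [5.0, 5.0, 5.0])
        assert time_weighted_average(s) == 5.0

    def test_linear_ramp_midpoint(self):
        s = MonitoringSeries([0.0, 10.0], [2.0, 8.0])
        assert time_weighted_average(s) == pytest.approx(5.0)

    def test_piecewise_profile_hand_computation(self):
        # trapezoids: (4+6)/2*10 + (6+2)/2*20 = 130 over 30 min -> 4.3333
        s = MonitoringSeries([0.0, 10.0, 30.0], [4.0, 6.0, 2.0])
        assert time_weighted_average(s) == pytest.approx(130.0 / 30.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            time_weighted_average(MonitoringSeries([0.0], [5.0]))
        with pytest.raises(ValueError):
            MonitoringSeries([0.0, 0.0, 1.0], [5.0, 5.0, 5.0])

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(0, 12), min_size=2, max_size=20, unique=True),
        st.data(),
    )
    def test_bounded_by_series_extremes(self, t, data):
        t = sorted(t)
        v = data.draw(
            st.lists(st.floats(-5, 15), min_size=len(t), max_size=len(t))
        )
        s = MonitoringSeries(t, v)
        twa = time_weighted_average(s)
        assert min(v) - 1e-9 <= twa <= max(v) + 1e-9


class TestSpearman:
    def test_monotone_is_plus_one(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 20, 25, 50, 100])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2.0 / 120.0)  # exact: 2 of 5! permutations

    def test_reversed_is_minus_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_fixture_matches_brute_force_ranks(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 2.0, 3.0, 5.0, 4.0, 6.0]
        rho, _ = spearman(x, y)
        # brute-force midranks: y -> [1.5, 1.5, 3, 5, 4, 6]
        rx = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        ry = np.array([1.5, 1.5, 3.0, 5.0, 4.0, 6.0])
        expect = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_large_n_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = spearman(x, y)
        ref = scipy.stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [1.0, 4.0, 9.0, np.nan, 25.0, 36.0]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError, match="undefined|constant"):
            spearman([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])


class TestDerivedHemodynamics:
    def _inputs(self, **kw):
        base = dict(sbp=120.0, dbp=80.0, mean_ap=93.0, hr=70.0, sv=70.0,
                    lvef=0.6, pre_ejection_s=0.08, ejection_s=0.30)
        base.update(kw)
        return HemoInputs(**base)

    def test_ea_from_stated_formula(self):
        d = derived_hemodynamics(self._inputs(sbp=120.0, sv=60.0))
        assert d.ea == pytest.approx(0.9 * 120.0 / 60.0)  # 1.8 mmHg/mL

    def test_cpo_approximately_one_watt(self):
        d = derived_hemodynamics(self._inputs(hr=70.0, sv=71.4, mean_ap=90.2))
        assert d.co_l_min == pytest.approx(70.0 * 71.4 / 1000.0)
        assert d.cpo_w == pytest.approx(1.0, abs=0.01)

    def test_doubling_sv_halves_ea(self):
        d1 = derived_hemodynamics(self._inputs(sv=50.0))
        d2 = derived_hemodynamics(self._inputs(sv=100.0))
        assert d2.ea == pytest.approx(d1.ea / 2.0)

    def test_normalized_elastance_transcription(self):
        # independent evaluation of the published polynomial + regression
        t_nd = 0.08 / 0.38
        powers = [t_nd**i for i in range(8)]
        e_avg = sum(c * p for c, p in zip(CHEN_END_POLY, powers))
        b0, b1, b2, b3 = CHEN_END_REGRESSION
        expect = b0 + b1 * 0.6 + b2 * (80.0 / (0.9 * 120.0)) + b3 * e_avg
        assert chen_normalized_elastance(t_nd, 0.6, 80.0, 120.0) == pytest.approx(
            expect, abs=1e-12
        )
        # at t_nd = 0 the polynomial reduces to its constant term
        assert sum(c * 0**i if i else c for i, c in enumerate(CHEN_END_POLY)) == CHEN_END_POLY[0]

    def test_ees_physiological_at_normal_hemodynamics(self):
        d = derived_hemodynamics(self._inputs())
        assert d.valid
        assert 0.5 < d.ees < 4.0
        assert 0.3 < d.ea_ees < 3.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            self._inputs(sv=0.0)
        with pytest.raises(ValueError):
            self._inputs(lvef=1.2)


class TestCompareCorrelations:
    def test_continuous_ranked_stronger_than_lvef(self):
        out = compare_correlations({"continuous": -0.37, "LVEF": -0.31})
        assert out.iloc[0]["label"] == "continuous"
        assert out.iloc[0]["rank"] == 1
        assert not out["tied"].any()

    def test_single_element_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations({"only": 0.4})

    def test_equal_magnitudes_tied(self):
        out = compare_correlations({"a": 0.3, "b": -0.3, "c": 0.1})
        assert out[out["label"].isin(["a", "b"])]["tied"].all()
        assert (out[out["label"].isin(["a", "b"])]["rank"] == 1).all()
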