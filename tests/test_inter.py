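"""Lagged inter-network correlation: the package's core statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from netlag.cohort import simulate_network_timecourses
from netlag.inter import (
    behavior_partial_correlation,
    circular_lagged_r,
    detrend_timecourse,
    fisher_z,
    group_anova_z,
    inter_network_anova_table,
    ledd_fc_check,
    max_lagged_correlation,
    network_pairs,
    pairwise_contrasts,
    subject_pair_table,
)


def brute_force_scan(x, y, max_lag=12):
    """Independent exhaustive oracle: same Pearson primitive, own scan logic.

    Sorts candidates by (|r| desc, |lag| asc, lag asc) and takes the head.
    """
    cands = []
    for lag in range(-max_lag, max_lag + 1):
        r = float(np.corrcoef(x, np.roll(y, -lag))[0, 1])
        cands.append((lag, r))
    cands.sort(key=lambda c: (-abs(c[1]), abs(c[0]), c[0]))
    return cands[0]


class TestDetrend:
    def test_exact_line_to_zero(self):
        t = np.arange(100, dtype=float)
        out = detrend_timecourse(2.0 * t + 5.0)
        assert np.abs(out).max() < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = detrend_timecourse(rng.standard_normal(80))
        np.testing.assert_allclose(detrend_timecourse(x), x, atol=1e-9)

    def test_sine_recovered_from_ramp(self):
        t = np.arange(216, dtype=float)
        sine = np.sin(2 * np.pi * 8 * t / 216)
        out = detrend_timecourse(sine + 0.05 * t)
        # amplitude via quadrature projection (a ramp is not orthogonal to a
        # sine in L2, but the recovered oscillation amplitude is preserved)
        basis = np.column_stack([np.sin(2 * np.pi * 8 * t / 216),
                                 np.cos(2 * np.pi * 8 * t / 216)])
        coef = np.linalg.lstsq(basis, out, rcond=None)[0]
        amp = np.hypot(*coef)
        assert amp == pytest.approx(1.0, abs=0.01)

    def test_constant_warns_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            out = detrend_timecourse(np.full(10, 2.0))
        assert np.all(out == 0)


class TestCircularLaggedR:
    def test_lag_zero_is_plain_pearson(self, rng):
        x, y = rng.standard_normal((2, 50))
        assert circular_lagged_r(x, y, 0) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12
        )

    def test_perfect_alignment_at_shift(self, rng):
        x = rng.standard_normal(100)
        y = np.roll(x, 3)  # y_t = x_(t-3); y_(t+3) = x_t
        assert circular_lagged_r(x, y, 3) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_in_lag(self, rng):
        x, y = rng.standard_normal((2, 60))
        for k in range(-12, 13):
            assert circular_lagged_r(x, y, k) == pytest.approx(
                circular_lagged_r(y, x, -k), abs=1e-12
            )

    def test_constant_series_raises(self):
        with pytest.raises(ValueError, match="constant"):
            circular_lagged_r(np.ones(10), np.arange(10.0), 0)

    def test_shift_conservation(self, rng):
        """Multiset of r over all lags is invariant to a common circular shift."""
        x, y = rng.standard_normal((2, 64))
        rs1 = sorted(circular_lagged_r(x, y, k) for k in range(-12, 13))
        xs, ys = np.roll(x, 9), np.roll(y, 9)
        rs2 = sorted(circular_lagged_r(xs, ys, k) for k in range(-12, 13))
        np.testing.assert_allclose(rs1, rs2, atol=1e-12)


class TestMaxLaggedCorrelation:
    def test_constructed_optimum(self, rng):
        x = rng.standard_normal(216)
        y = np.roll(x, -5)  # y_(t-5)=x_t -> optimum at lag -5? verify via oracle
        lag, r, p = max_lagged_correlation(x, y, 12)
        olag, orr = brute_force_scan(x, y, 12)
        assert (lag, r) == (olag, orr)
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(100):
            x, y = rng.standard_normal((2, 216))
            lag, r, p = max_lagged_correlation(x, y, 12)
            olag, orr = brute_force_scan(x, y, 12)
            assert lag == olag
            assert r == orr  # bit-exact

    def test_max_dominates_lag_zero(self, rng):
        for _ in range(50):
            x, y = rng.standard_normal((2, 100))
            _, r, _ = max_lagged_correlation(x, y, 12)
            assert abs(r) >= abs(circular_lagged_r(x, y, 0))

    def test_p_is_t_transform(self, rng):
        x, y = rng.standard_normal((2, 216))
        lag, r, p = max_lagged_correlation(x, y, 12)
        t = abs(r) * np.sqrt(214 / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(t, 214), rel=1e-10)

    def test_too_short_raises(self, rng):
        with pytest.raises(ValueError, match="max_lag"):
            max_lagged_correlation(rng.standard_normal(20), rng.standard_normal(20), 12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_property_max_over_lags(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 60))
        lag, r, _ = max_lagged_correlation(x, y, 8)
        all_r = [abs(circular_lagged_r(x, y, k)) for k in range(-8, 9)]
        assert abs(r) == pytest.approx(max(all_r), abs=1e-14)
        assert -8 <= lag <= 8


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_value(self):
        # z = atanh(-0.451) = 0.5 ln(0.549/1.451)
        assert fisher_z(-0.451) == pytest.approx(-0.48595, abs=1e-4)
        assert fisher_z(-0.451) == pytest.approx(0.5 * np.log(0.549 / 1.451), rel=1e-12)

    def test_antisymmetry(self):
        for r in np.linspace(-0.95, 0.95, 21):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-14)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_variance_stabilization_at_fixed_lag(self):
        """SD of z at lag 0 across null simulations ~ 1/sqrt(T-3)."""
        T = 216
        zs = []
        for s in range(300):
            rng = np.random.default_rng(s)
            x, y = rng.standard_normal((2, T))
            zs.append(fisher_z(float(np.corrcoef(x, y)[0, 1])))
        assert np.std(zs) == pytest.approx(1 / np.sqrt(T - 3), rel=0.15)


class TestGroupStats:
    @staticmethod
    def _null_data(rng, n=(12, 8, 6)):
        groups = np.repeat(["HC", "HET", "HOM"], n)
        return rng.standard_normal(sum(n)), groups

    def test_two_group_F_equals_t_squared(self, rng):
        z = rng.standard_normal(20)
        groups = np.repeat(["A", "B"], 10)
        F, (df1, df2), p = group_anova_z(z, groups, None)
        t = stats.ttest_ind(z[:10], z[10:]).statistic
        assert F == pytest.approx(t**2, rel=1e-8)
        assert df1 == 1

    def test_anova_matches_statsmodels_ancova(self, rng):
        """Cross-check against a formula-interface ANCOVA fit."""
        import pandas as pd
        import statsmodels.formula.api as smf

        z, groups = self._null_data(rng)
        edu = rng.normal(12, 3, z.size)
        gm = rng.normal(600, 50, z.size)
        F, dfs, p = group_anova_z(z, groups, np.column_stack([edu, gm]))
        df = pd.DataFrame({"z": z, "g": groups, "edu": edu, "gm": gm})
        fit = smf.ols("z ~ C(g) + edu + gm", df).fit()
        import statsmodels.api as sm

        table = sm.stats.anova_lm(fit, typ=2)
        assert F == pytest.approx(float(table.loc["C(g)", "F"]), rel=1e-8)
        assert p == pytest.approx(float(table.loc["C(g)", "PR(>F)"]), rel=1e-6)

    def test_pairwise_contrast_signs(self, rng):
        z, groups = self._null_data(rng)
        z[groups == "HOM"] += 2.0
        res = pairwise_contrasts(z, groups, None)
        t, df, p = res[("HOM", "HC")]
        assert t > 0 and p < 0.01
        assert res[("HOM", "HET")][0] > 0

    def test_needs_two_groups(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            group_anova_z(rng.standard_normal(5), np.repeat("A", 5), None)


class TestPairTables:
    def test_ten_pairs_for_five_networks(self):
        assert len(network_pairs(("DMN", "SN", "ExN", "rFP", "lFP"))) == 10

    def test_subject_pair_table_shape_and_z(self, rng):
        tcs = {f"s{i}": rng.standard_normal((60, 3)) for i in range(4)}
        tbl = subject_pair_table(tcs, ["A", "B", "C"], max_lag=5)
        assert len(tbl) == 4 * 3
        np.testing.assert_allclose(tbl["z"], np.arctanh(tbl["r"]), atol=1e-12)
        assert tbl["lag"].between(-5, 5).all()

    def test_anova_table_bonferroni(self, rng):
        import pandas as pd

        n = 18
        tcs = {f"s{i}": rng.standard_normal((80, 3)) for i in range(n)}
        part = pd.DataFrame({
            "participant_id": [f"s{i}" for i in range(n)],
            "group": np.repeat(["HC", "HET", "HOM"], 6),
            "education": rng.normal(12, 2, n),
            "gm_volume": rng.normal(600, 40, n),
        })
        tbl = subject_pair_table(tcs, ["A", "B", "C"], max_lag=5)
        an = inter_network_anova_table(tbl, part)
        assert len(an) == 3
        np.testing.assert_allclose(
            an["p_bonferroni"], np.minimum(1.0, an["p"] * 3), atol=1e-12
        )


class TestBehaviourAndLEDD:
    def test_partial_equals_plain_when_orthogonal(self, rng):
        n = 200
        z = rng.standard_normal(n)
        score = z * 0.5 + rng.standard_normal(n)
        nuis = rng.standard_normal(n)  # independent of both
        r_partial, p, n_used = behavior_partial_correlation(z, score, nuis)
        r_plain = stats.pearsonr(z, score).statistic
        assert n_used == n
        assert r_partial == pytest.approx(r_plain, abs=0.02)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        n = 40
        z = rng.standard_normal(n)
        score = 0.6 * z + rng.standard_normal(n)
        gm = 0.3 * z + rng.standard_normal(n)
        r, p, _ = behavior_partial_correlation(z, score, gm)
        ref = pg.partial_corr(
            pd.DataFrame({"z": z, "s": score, "gm": gm}), x="z", y="s", covar="gm"
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_sign_recovery(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            z = rng.standard_normal(20)
            score = 0.8 * z + 0.5 * rng.standard_normal(20)
            gm = rng.standard_normal(20)
            r, _, _ = behavior_partial_correlation(z, score, gm)
            hits += int(r > 0)
        assert hits >= 95

    def test_ledd_affine_gives_unit_r(self, rng):
        fc = rng.standard_normal(8)
        tbl = ledd_fc_check({"DMN": fc}, 100 + 3 * fc)
        assert abs(tbl["r"].iloc[0]) == pytest.approx(1.0, abs=1e-12)

    def test_ledd_constant_raises(self, rng):
        with pytest.raises(ValueError, match="constant"):
            ledd_fc_check({"DMN": rng.standard_normal(8)}, np.full(8, 400.0))

    def test_ledd_null_calibration(self):
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            tbl = ledd_fc_check({"N": rng.standard_normal(8)}, rng.normal(500, 100, 8))
            hits += int(tbl["p"].iloc[0] < 0.05)
        assert hits / n_sim == pytest.approx(0.05, abs=0.04)
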