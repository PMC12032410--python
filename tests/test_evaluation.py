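"""Statistical battery vs independent brute-force implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from leadrecon.leads import LEADS_12, MultiLeadSignal
from leadrecon.measure import MarkerTable
from leadrecon.evaluation import (EvaluationError, bland_altman,
                                  bland_altman_table, compare_means_variances,
                                  error_percentiles, evaluate, f_test_variance,
                                  interlead_correlation, real_vs_recon_r2,
                                  regression_to_mean_verdict, rmse_per_lead)

# ---------------------------------------------------------------------------
# brute-force oracles (straight-line, loop-based)
# ---------------------------------------------------------------------------

def brute_rmse(a, b):
    total = 0.0
    n = 0
    for x, y in zip(np.ravel(a), np.ravel(b)):
        total += (x - y) ** 2
        n += 1
    return np.sqrt(total / n)


def brute_percentile(values, q):
    """Linear interpolation between closest order statistics."""
    v = sorted(values)
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def brute_pearson_r2(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return (sxy / np.sqrt(sxx * syy)) ** 2


def brute_paired_t_p(a, b):
    d = [y - x for x, y in zip(a, b)]
    n = len(d)
    md = sum(d) / n
    sd = np.sqrt(sum((x - md) ** 2 for x in d) / (n - 1))
    t = md / (sd / np.sqrt(n))
    return 2 * stats.t(n - 1).sf(abs(t))


def brute_f_p(a, b):
    n, m = len(a), len(b)
    va = sum((x - sum(a) / n) ** 2 for x in a) / (n - 1)
    vb = sum((x - sum(b) / m) ** 2 for x in b) / (m - 1)
    f = va / vb
    dist = stats.f(n - 1, m - 1)
    return min(1.0, 2 * min(dist.cdf(f), dist.sf(f)))


def _marker_tables(real_cols: dict, recon_cols: dict):
    ids = [f"rec_{i:04d}" for i in range(len(next(iter(real_cols.values()))))]
    defaults = {f"{m}_ms": 0.0 for m in ("RR", "QT", "PR", "QRS")}

    def build(cols):
        frame = pd.DataFrame({**defaults, **cols},
                             index=pd.Index(ids, name="record_id"))
        return MarkerTable(frame)

    return build(real_cols), build(recon_cols)


class TestRmse:
    def _signals(self, arr):
        return [MultiLeadSignal(a, 500.0, LEADS_12[:a.shape[0]]) for a in arr]

    def test_identical_signals_zero_rmse(self, rng):
        sigs = self._signals(rng.standard_normal((3, 4, 100)))
        assert (rmse_per_lead(sigs, sigs) == 0).all()

    def test_constant_offset_gives_offset_rmse(self, rng):
        a = rng.standard_normal((2, 3, 50))
        sigs = self._signals(a)
        shifted = self._signals(a + 50.0)
        assert np.allclose(rmse_per_lead(sigs, shifted), 50.0)

    def test_matches_loop_based_recomputation(self, rng):
        a = rng.standard_normal((4, 2, 30)) * 100
        b = rng.standard_normal((4, 2, 30)) * 100
        got = rmse_per_lead(self._signals(a), self._signals(b))
        for li, lead in enumerate(got.index):
            want = brute_rmse(a[:, li, :], b[:, li, :])
            assert got[lead] == pytest.approx(want, rel=1e-12)

    def test_mismatched_sets_rejected(self, rng):
        sigs = self._signals(rng.standard_normal((2, 3, 50)))
        with pytest.raises(EvaluationError):
            rmse_per_lead(sigs, sigs[:1])


class TestErrorPercentiles:
    def test_constant_errors_give_constant_percentiles(self):
        real, recon = _marker_tables({"R_V3": np.zeros(30)},
                                     {"R_V3": np.full(30, 7.0)})
        tbl = error_percentiles(real, recon, leads=("V3",))
        row = tbl[(tbl.feature == "R") & (tbl.lead == "V3")].iloc[0]
        for lv in (5, 10, 90, 95):
            assert row[f"p{lv}"] == 7.0

    def test_matches_order_statistic_interpolation(self, rng):
        errs = np.arange(1.0, 101.0)
        rng.shuffle(errs)
        real, recon = _marker_tables({"R_V1": np.zeros(100)}, {"R_V1": errs})
        tbl = error_percentiles(real, recon, leads=("V1",))
        row = tbl[(tbl.feature == "R") & (tbl.lead == "V1")].iloc[0]
        for lv in (5, 10, 90, 95):
            assert row[f"p{lv}"] == pytest.approx(
                brute_percentile(errs, lv), rel=1e-12)

    def test_negation_swaps_and_negates_tails(self, rng):
        errs = rng.standard_normal(80) * 40
        real, neg = _marker_tables({"T_V2": np.zeros(80)}, {"T_V2": -errs})
        _, pos = _marker_tables({"T_V2": np.zeros(80)}, {"T_V2": errs})
        tp = error_percentiles(real, pos, leads=("V2",))
        tn = error_percentiles(real, neg, leads=("V2",))
        rp = tp[tp.feature == "T"].iloc[0]
        rn = tn[tn.feature == "T"].iloc[0]
        assert rn.p5 == pytest.approx(-rp.p95, rel=1e-12)
        assert rn.p10 == pytest.approx(-rp.p90, rel=1e-12)

    def test_small_samples_flagged(self):
        real, recon = _marker_tables({"R_V3": np.zeros(10)},
                                     {"R_V3": np.ones(10)})
        tbl = error_percentiles(real, recon, leads=("V3",))
        assert tbl.low_n.all()


class TestMeanVarianceComparison:
    def test_identical_groups_flagged_degenerate_without_p(self, rng):
        vals = rng.standard_normal(40) * 100
        real, recon = _marker_tables({"R_V3": vals}, {"R_V3": vals.copy()})
        tbl = compare_means_variances(real, recon, leads=("V3",))
        row = tbl[tbl.feature == "R"].iloc[0]
        assert row.degenerate
        assert np.isnan(row.p_means)

    def test_f_test_type_i_error_calibrated(self, rng):
        """Equal-variance normals, n=500: rejection rate ~ alpha."""
        reps, n = 400, 500
        rejections = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            _, p = f_test_variance(x, y)
            rejections += p < 0.05
        assert 0.02 < rejections / reps < 0.08

    def test_f_test_power_on_quartered_variance(self, rng):
        hits = 0
        for _ in range(50):
            x = rng.standard_normal(500)
            y = rng.standard_normal(500) / 2.0
            _, p = f_test_variance(y, x)
            hits += p < 0.05
        assert hits == 50  # power > 99 % at this effect size

    def test_p_values_match_brute_force(self, rng):
        a = rng.standard_normal(60) * 30 + 5
        b = a + rng.standard_normal(60) * 10
        real, recon = _marker_tables({"S_V2": a}, {"S_V2": b})
        tbl = compare_means_variances(real, recon, leads=("V2",))
        row = tbl[tbl.feature == "S"].iloc[0]
        assert row.p_means == pytest.approx(brute_paired_t_p(a, b), rel=1e-9)
        assert row.p_variance == pytest.approx(brute_f_p(b, a), rel=1e-9)


class TestBlandAltman:
    def test_perfect_agreement_degenerate(self, rng):
        vals = rng.standard_normal(30)
        res = bland_altman(vals, vals)
        assert res.degenerate
        assert res.mean_diff == 0 and res.loa_low == 0 and res.loa_high == 0

    def test_mean_predictor_slope_minus_one_r2_one_exactly(self, rng):
        real = rng.standard_normal(50) * 300 + 800
        recon = np.full(50, real.mean())
        res = bland_altman(real, recon)
        assert res.slope == pytest.approx(-1.0, abs=1e-12)
        assert res.r2_diff_vs_real == pytest.approx(1.0, abs=1e-12)
        assert not res.degenerate

    def test_unbiased_noise_gives_near_zero_slope(self, rng):
        real = rng.standard_normal(5000) * 100
        recon = real + rng.standard_normal(5000) * 20
        res = bland_altman(real, recon)
        assert abs(res.slope) < 0.05
        assert res.r2_diff_vs_real < 0.01
        assert res.loa_low < res.mean_diff < res.loa_high

    def test_constant_real_marker_degenerate_r2_zero(self, rng):
        res = bland_altman(np.full(20, 3.0), rng.standard_normal(20))
        assert res.degenerate and res.r2_diff_vs_real == 0.0

    def test_limits_of_agreement_at_1_96_sd(self, rng):
        real = rng.standard_normal(200) * 50
        recon = real + rng.standard_normal(200) * 15 + 4
        res = bland_altman(real, recon)
        d = recon - real
        assert res.mean_diff == pytest.approx(d.mean())
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))


class TestInterleadCorrelation:
    def test_exact_linear_relation_gives_r2_one(self, rng):
        base = rng.standard_normal(40) * 100
        real, _ = _marker_tables({"R_I": base, "R_V3": 2 * base},
                                 {"R_I": base, "R_V3": 2 * base})
        tbl = interlead_correlation(real, None, "R", leads=("V3",))
        assert tbl.iloc[0].r2_real == pytest.approx(1.0, abs=1e-12)

    def test_independent_markers_near_zero_r2(self, rng):
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        real, _ = _marker_tables({"R_I": x, "R_V3": y}, {"R_I": x, "R_V3": y})
        tbl = interlead_correlation(real, None, "R", leads=("V3",))
        assert tbl.iloc[0].r2_real < 0.01

    def test_r2_invariant_to_affine_rescaling(self, rng):
        x = rng.standard_normal(60)
        y = 0.3 * x + rng.standard_normal(60)
        real_a, _ = _marker_tables({"R_I": x, "R_V1": y}, {"R_I": x, "R_V1": y})
        real_b, _ = _marker_tables({"R_I": 5 * x - 2, "R_V1": -3 * y + 7},
                                   {"R_I": x, "R_V1": y})
        ta = interlead_correlation(real_a, None, "R", leads=("V1",))
        tb = interlead_correlation(real_b, None, "R", leads=("V1",))
        assert ta.iloc[0].r2_real == pytest.approx(tb.iloc[0].r2_real, rel=1e-9)

    def test_reference_marker_always_from_real_table(self, rng):
        x = rng.standard_normal(30)
        y = 2 * x
        real, recon = _marker_tables({"R_I": x, "R_V3": y},
                                     {"R_I": rng.standard_normal(30),
                                      "R_V3": y})
        tbl = interlead_correlation(real, recon, "R", leads=("V3",))
        # recon V3 = 2 * real lead I exactly, so r2_recon = 1 even though the
        # recon table's own lead-I column is garbage
        assert tbl.iloc[0].r2_recon == pytest.approx(1.0, abs=1e-12)

    def test_missing_markers_dropped_pairwise_with_count(self, rng):
        x = rng.standard_normal(20)
        y = 2 * x
        y[3] = np.nan
        real, recon = _marker_tables({"R_I": x, "R_V3": y},
                                     {"R_I": x, "R_V3": y})
        tbl = interlead_correlation(real, recon, "R", leads=("V3",))
        assert tbl.iloc[0].n_real == 19
        assert tbl.iloc[0].r2_real == pytest.approx(1.0, abs=1e-12)


class TestVerdict:
    def _full_tables(self, rng, recon_mode):
        cols_real, cols_recon = {}, {}
        for mk in ("R", "S", "T", "STM"):
            base = rng.standard_normal(60)
            for lead in ("V1", "V2", "V3", "V6"):
                real = 100 * base + rng.standard_normal(60) * 200 + 500
                cols_real[f"{mk}_{lead}"] = real
                if recon_mode == "identity":
                    cols_recon[f"{mk}_{lead}"] = real.copy()
                elif recon_mode == "mean":
                    cols_recon[f"{mk}_{lead}"] = np.full(60, real.mean())
                else:  # small independent noise
                    cols_recon[f"{mk}_{lead}"] = real + rng.standard_normal(60)
            cols_real[f"{mk}_I"] = 30 * base + rng.standard_normal(60) * 100
            cols_recon[f"{mk}_I"] = cols_real[f"{mk}_I"].copy()
        return _marker_tables(cols_real, cols_recon)

    def _verdict(self, real, recon):
        comp = compare_means_variances(real, recon)
        ba = bland_altman_table(real, recon)
        inter = [interlead_correlation(real, recon, mk)
                 for mk in ("R", "S", "T", "STM")]
        return regression_to_mean_verdict(comp, ba, inter)

    def test_identical_reconstruction_raises_no_flags(self, rng):
        v = self._verdict(*self._full_tables(rng, "identity"))
        assert not v.regression_to_mean.any()

    def test_mean_predictor_raises_every_flag(self, rng):
        v = self._verdict(*self._full_tables(rng, "mean"))
        assert v.regression_to_mean.all()

    def test_added_noise_does_not_raise_variance_flag(self, rng):
        v = self._verdict(*self._full_tables(rng, "noise"))
        assert not v.variance_shrunk.any()
        assert not v.regression_to_mean.any()


class TestRealVsReconR2:
    def test_table_two_analogue_tracks_agreement(self, rng):
        a = rng.standard_normal(50) * 100
        real, recon = _marker_tables({"R_V3": a}, {"R_V3": a + rng.standard_normal(50)})
        tbl = real_vs_recon_r2(real, recon, leads=("V3",))
        row = tbl[(tbl.feature == "R") & (tbl.lead == "V3")].iloc[0]
        assert row.r2 > 0.99
        assert row.r2 == pytest.approx(
            brute_pearson_r2(list(a), list(real.frame["R_V3"] * 0
                                           + recon.frame["R_V3"])), rel=1e-9)
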