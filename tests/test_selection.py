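import numpy as np
import pandas as pd
import pytest
from scipy import stats

from caprilact.curves import FitResult, fit_lactation, get_model
from caprilact.errors import DegenerateDataError, InsufficientDataError, ValidationError
from caprilact.selection import (
    aggregate_criteria,
    criteria,
    dim_averaged_residuals,
    durbin_watson,
    select_best,
    shapiro_francia,
)


def _fit(residuals, y, k=2, converged=True):
    residuals = np.asarray(residuals, dtype=float)
    y = np.asarray(y, dtype=float)
    return FitResult(
        model_id="m",
        b=np.zeros(k),
        converged=converged,
        iterations=3,
        rss=float(np.sum(residuals**2)),
        residuals=residuals,
        n=len(y),
        t=np.arange(1.0, len(y) + 1),
        y=y,
    )


class TestCriteria:
    def test_perfect_fit(self):
        f = _fit(np.zeros(8), np.linspace(1, 2, 8))
        with pytest.warns(UserWarning, match="perfect fit"):
            c = criteria(f)
        assert c.rss == 0 and c.adj_r2 == 1.0
        assert c.aic == -np.inf and c.bic == -np.inf

    def test_unit_arithmetic(self):
        f = _fit([1.0, -1.0, 1.0, -1.0], [1, 2, 3, 4], k=1)
        c = criteria(f)
        assert c.rss == pytest.approx(4.0)
        assert c.mspe == pytest.approx(1.0)

    def test_formula_oracle_ten_points(self, rng):
        y = rng.normal(3.0, 1.0, 10)
        e = rng.normal(0, 0.4, 10)
        n, k = 10, 3
        f = _fit(e, y, k=k)
        c = criteria(f)
        rss = np.sum(e**2)
        r2 = 1 - rss / np.sum((y - y.mean()) ** 2)
        assert c.adj_r2 == pytest.approx(1 - (1 - r2) * (n - 1) / (n - k - 1))
        aic = n * np.log(rss / n) + 2 * k
        assert c.aic == pytest.approx(aic)
        assert c.aicc == pytest.approx(aic + 2 * k * (k + 1) / (n - k - 1))
        assert c.bic == pytest.approx(n * np.log(rss / n) + k * np.log(n))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            criteria(_fit(np.zeros(4), np.ones(4), k=3))

    def test_aicc_converges_to_aic(self):
        # gap is exactly 2k(k+1)/(n-k-1), vanishing as n grows at fixed k
        n, k = 10**6, 5
        rng = np.random.default_rng(0)
        e = rng.normal(0, 1, 100)
        f = FitResult("m", np.zeros(k), True, 1, 100.0, e, n, None, np.ones(n))
        c = criteria(f)
        # cancellation noise: aic itself is ~1e7, so the gap carries ~1e-9
        assert c.aicc - c.aic == pytest.approx(
            2 * k * (k + 1) / (n - k - 1), abs=1e-8
        )
        assert abs(c.aicc - c.aic) < 1e-4


class TestDurbinWatson:
    def test_alternating(self):
        assert durbin_watson([1, -1, 1, -1]) == pytest.approx(3.0)

    def test_constant_residuals(self):
        assert durbin_watson([2.0, 2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.stattools import durbin_watson as sm_dw

        e = rng.normal(0, 1, 50)
        assert durbin_watson(e) == pytest.approx(sm_dw(e), rel=1e-12)

    def test_reversal_invariance(self, rng):
        e = rng.normal(0, 1, 31)
        assert durbin_watson(e) == pytest.approx(durbin_watson(e[::-1]))

    def test_all_zero_signaled(self):
        with pytest.raises(DegenerateDataError):
            durbin_watson(np.zeros(5))

    def test_dim_averaging(self):
        f1 = _fit([1.0, 2.0], [0, 0])
        f2 = _fit([3.0, 4.0], [0, 0])
        avg = dim_averaged_residuals([f1, f2])
        assert np.allclose(avg, [2.0, 3.0])


# samples frozen together with their R nortest::sf.test results
_SF_NORMAL = np.array([
    2.7202, 3.149344, 2.802704, 1.318774, 1.02504, 2.047037, 2.602946,
    2.356431, 3.2672, 2.52559, 2.447832, 1.488074, 1.224598, 3.039084,
    2.034239, 2.568064, 1.036504, 1.69454, 1.096236, 1.457025, 2.632144,
    0.963593, 1.626135, 2.114652, 1.532071, 1.823397, 1.844697, 2.292697,
    1.698122, 2.190582, 2.039773, 2.297198, 2.15746, 3.160379, 1.535427,
    2.839431, 1.718171, 1.329452, 2.847836, 1.692346, 1.728655, 1.027921,
    0.531262, 2.444011, 1.184314, 2.544791, 3.293717, 1.919641, 1.211369,
    2.275939,
])
_SF_SKEWED = np.array([
    2.197993, 1.185632, 3.136787, 0.458763, 1.946577, 0.624029, 0.608508,
    0.744097, 0.497952, 1.678332, 0.481746, 4.860236, 1.849899, 2.718687,
    0.623901, 0.907017, 1.383687, 1.330409, 0.673232, 2.407648, 1.601482,
    1.192049, 0.240028, 1.685884, 1.740616, 0.471157, 0.845168, 5.895991,
    1.142772, 1.747739, 0.731752, 1.03418, 1.353504, 1.379253, 1.661163,
    1.581151, 0.499311, 1.118177, 1.811462, 1.294478, 0.499936, 0.021291,
    1.460123, 1.658236, 3.71759, 0.939141, 1.26853, 1.957962, 0.173302,
    0.597697, 1.889013, 4.901792, 1.201927, 6.202645, 2.522469, 1.886227,
    0.172837, 1.67446, 0.601316, 1.555025,
])


class TestShapiroFrancia:
    def test_blom_scores_give_w_one(self):
        n = 40
        m = stats.norm.ppf((np.arange(1, n + 1) - 3 / 8) / (n + 1 / 4))
        w, _ = shapiro_francia(m)
        assert w == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        n = 40
        m = stats.norm.ppf((np.arange(1, n + 1) - 3 / 8) / (n + 1 / 4))
        w, _ = shapiro_francia(3.0 + 0.5 * m)
        assert w == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "sample, w_ref, p_ref",
        [
            (_SF_NORMAL, 0.9845977739, 0.6612663599),
            (_SF_SKEWED, 0.7902610797, 6.227e-07),
        ],
        ids=["normal_n50", "gamma_n60"],
    )
    def test_matches_reference_implementation(self, sample, w_ref, p_ref):
        w, p = shapiro_francia(sample)
        assert w == pytest.approx(w_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-3)

    def test_w_is_squared_correlation(self, rng):
        x = rng.normal(0, 1, 50)
        w, _ = shapiro_francia(x)
        xs = np.sort(x)
        m = stats.norm.ppf((np.arange(1, 51) - 3 / 8) / (50 + 1 / 4))
        # brute-force correlation computation
        num = np.sum((xs - xs.mean()) * (m - m.mean()))
        den = np.sqrt(np.sum((xs - xs.mean()) ** 2) * np.sum((m - m.mean()) ** 2))
        assert w == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_constant_sample_signaled(self):
        with pytest.raises(DegenerateDataError):
            shapiro_francia(np.full(10, 3.0))


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=["model_id", "k", "pct_fitted", "mspe", "adj_r2", "aic", "aicc", "bic"],
    )


class TestSelectBest:
    def test_single_candidate(self):
        t = _table([["a", 3, 100.0, 1.0, 0.9, 10.0, 11.0, 12.0]])
        assert select_best(t).iloc[0]["model_id"] == "a"

    def test_dominance(self):
        t = _table(
            [
                ["worse", 3, 100.0, 2.0, 0.8, 20.0, 21.0, 22.0],
                ["better", 3, 100.0, 1.0, 0.9, 10.0, 11.0, 12.0],
            ]
        )
        assert select_best(t).iloc[0]["model_id"] == "better"

    def test_rank_sum_enumeration_oracle(self):
        rows = [
            ["a", 5, 100.0, 1.0, 0.95, 12.0, 13.0, 15.0],
            ["b", 3, 100.0, 1.2, 0.97, 10.0, 10.5, 11.0],
            ["c", 3, 100.0, 0.9, 0.90, 14.0, 14.5, 16.0],
        ]
        t = _table(rows)
        # brute-force rank sums: mspe asc, adj_r2 desc, aic asc, aicc asc, bic asc
        cols = [(3, 1), (4, -1), (5, 1), (6, 1), (7, 1)]
        sums = {}
        for r in rows:
            total = 0
            for ci, sign in cols:
                vals = sorted((sign * rr[ci] for rr in rows))
                total += vals.index(sign * r[ci]) + 1
            sums[r[0]] = total
        expected = sorted(sums, key=lambda m: (sums[m],))
        got = list(select_best(t)["model_id"])
        assert got == expected
        assert dict(zip(select_best(t)["model_id"], select_best(t)["rank_sum"])) == {
            k: float(v) for k, v in sums.items()
        }

    def test_partial_fit_excluded_and_error_when_none(self):
        t = _table(
            [
                ["partial", 3, 95.0, 0.1, 0.99, 1.0, 1.1, 1.2],
                ["full", 3, 100.0, 1.0, 0.9, 10.0, 11.0, 12.0],
            ]
        )
        assert select_best(t).iloc[0]["model_id"] == "full"
        t_bad = _table([["partial", 3, 95.0, 0.1, 0.99, 1.0, 1.1, 1.2]])
        with pytest.raises(ValidationError, match="partial"):
            select_best(t_bad)

    def test_order_invariance(self):
        rows = [
            ["a", 5, 100.0, 1.0, 0.95, 12.0, 13.0, 15.0],
            ["b", 3, 100.0, 1.2, 0.97, 10.0, 10.5, 11.0],
            ["c", 3, 100.0, 0.9, 0.90, 14.0, 14.5, 16.0],
        ]
        fwd = list(select_best(_table(rows))["model_id"])
        rev = list(select_best(_table(rows[::-1]))["model_id"])
        assert fwd == rev

    def test_aggregate_criteria_from_fits(self, small_herd):
        from caprilact.records import build_lactations

        series = build_lactations(small_herd.records)[:20]
        model = get_model("quadratic")
        fits = [fit_lactation(s.dims, s.values("milk_kg"), model) for s in series]
        table = aggregate_criteria({"quadratic": fits})
        assert table.loc[0, "n_fits"] == 20
        assert table.loc[0, "pct_fitted"] == 100.0
        assert np.isfinite(table.loc[0, "aic"])
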