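"""Lin's CCC, Altman grading, Bland-Altman analysis, rater tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from marrowmeter import (
    AgreementGrade,
    RaterProfile,
    RaterSeries,
    bland_altman,
    bland_altman_plot,
    classify_agreement,
    lin_ccc,
    pairwise_ccc_table,
    simulate_rater,
)


def ccc_expectation_form(x, y):
    """Independent oracle: CCC = 1 - E[(X-Y)^2] / (varx + vary + (mux-muy)^2)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    denom = x.var() + y.var() + (x.mean() - y.mean()) ** 2
    return 1.0 - np.mean((x - y) ** 2) / denom


class TestLinCCC:
    def test_perfect_concordance(self):
        r = lin_ccc(RaterSeries(np.array([10.0, 50, 90]), np.array([10.0, 50, 90])))
        assert r.ccc == pytest.approx(1.0)
        assert r.grade is AgreementGrade.OPTIMAL
        assert r.ci_low <= r.ccc <= r.ci_high

    def test_perfect_discordance(self):
        r = lin_ccc(RaterSeries(np.array([1.0, 2, 3]), np.array([3.0, 2, 1])))
        assert r.ccc == pytest.approx(-1.0)
        assert r.pearson_rho == pytest.approx(-1.0)

    def test_matches_expectation_form_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.uniform(0, 100, 40)
            y = np.clip(x + rng.normal(0, 10, 40), 0, 100)
            r = lin_ccc(RaterSeries(x, y))
            assert r.ccc == pytest.approx(ccc_expectation_form(x, y), abs=1e-10)

    def test_ccc_bounded_by_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 50)
        y = np.clip(0.8 * x + 12 + rng.normal(0, 6, 50), 0, 100)
        r = lin_ccc(RaterSeries(x, y))
        assert abs(r.ccc) <= abs(r.pearson_rho) <= 1

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, 30)
        y = np.clip(x + rng.normal(0, 8, 30), 0, 100)
        assert lin_ccc(RaterSeries(x, y)).ccc == pytest.approx(
            lin_ccc(RaterSeries(y, x)).ccc, abs=1e-12
        )

    @given(st.integers(0, 1000))
    def test_invariant_under_common_permutation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, 20)
        y = np.clip(x + rng.normal(0, 5, 20), 0, 100)
        perm = rng.permutation(20)
        assert lin_ccc(RaterSeries(x, y)).ccc == pytest.approx(
            lin_ccc(RaterSeries(x[perm], y[perm])).ccc, abs=1e-12
        )

    def test_constant_shift_penalised_monotonically(self):
        x = np.array([20.0, 35, 50, 65, 80])
        cccs = [lin_ccc(RaterSeries(x, x + c)).ccc for c in (0, 2, 5, 10, 20)]
        assert cccs[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(cccs, cccs[1:]))

    def test_both_constant_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            lin_ccc(RaterSeries(np.full(5, 50.0), np.full(5, 60.0)))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="3"):
            lin_ccc(RaterSeries(np.array([1.0, 2]), np.array([1.0, 2])))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RaterSeries(np.array([1.0, 2, 3]), np.array([1.0, 2]))

    def test_ci_contains_estimate_and_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        widths = {40: [], 160: []}
        for _ in range(20):
            t = rng.uniform(10, 95, 160)
            e = np.clip(t + rng.normal(0, 8, 160), 0, 100)
            for n in (40, 160):
                r = lin_ccc(RaterSeries(e[:n], t[:n]))
                assert r.ci_low <= r.ccc <= r.ci_high
                widths[n].append(r.ci_high - r.ci_low)
        assert np.mean(widths[160]) < np.mean(widths[40])


class TestClassifyAgreement:
    @pytest.mark.parametrize(
        "ccc, grade",
        [
            (0.9400, AgreementGrade.OPTIMAL),
            (0.7918, AgreementGrade.SUBSTANTIAL),
            (0.7785, AgreementGrade.SUBSTANTIAL),
            (0.8, AgreementGrade.SUBSTANTIAL),  # "greater than 0.8" is strict
            (0.6, AgreementGrade.SUBSTANTIAL),
            (0.5999, AgreementGrade.BELOW_SUBSTANTIAL),
            (0.801, AgreementGrade.OPTIMAL),
            (-0.2, AgreementGrade.BELOW_SUBSTANTIAL),
        ],
    )
    def test_grading_boundaries(self, ccc, grade):
        assert classify_agreement(ccc) is grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="ccc"):
            classify_agreement(1.2)


class TestBlandAltman:
    def test_identical_series_collapse_to_zero(self):
        x = np.array([10.0, 40, 70])
        r = bland_altman(RaterSeries(x, x))
        assert r.bias == 0 and r.ula == 0 and r.lal == 0

    def test_hand_computed_limits(self):
        # d = (1, -1): mean 0, sample sd sqrt(2), ULA = 1.96*sqrt(2)
        r = bland_altman(RaterSeries(np.array([51.0, 49.0]), np.array([50.0, 50.0])))
        assert r.bias == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(np.sqrt(2))
        assert r.ula == pytest.approx(1.96 * np.sqrt(2))
        assert r.lal == pytest.approx(-1.96 * np.sqrt(2))

    def test_limits_symmetric_about_bias(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(10, 90, 30)
        y = np.clip(x + rng.normal(2, 5, 30), 0, 100)
        r = bland_altman(RaterSeries(x, y))
        assert r.ula - r.bias == pytest.approx(r.bias - r.lal)
        assert r.lal <= r.bias <= r.ula

    def test_normal_coverage_is_95_percent(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 5, 10_000)
        x = np.clip(50 + d / 2, 0, 100)
        y = np.clip(50 - d / 2, 0, 100)
        r = bland_altman(RaterSeries(x, y))
        coverage = ((r.diffs >= r.lal) & (r.diffs <= r.ula)).mean()
        assert 0.94 <= coverage <= 0.96

    def test_plot_written(self, tmp_path):
        rng = np.random.default_rng(5)
        x = rng.uniform(10, 90, 20)
        y = np.clip(x + rng.normal(0, 4, 20), 0, 100)
        r = bland_altman(RaterSeries(x, y))
        p = bland_altman_plot(r, tmp_path / "ba.png")
        assert p.exists() and p.stat().st_size > 0


class TestPairwiseTable:
    def test_identical_raters_and_symmetry(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(10, 90, 12)
        b = np.clip(a + rng.normal(0, 6, 12), 0, 100)
        table = pairwise_ccc_table({"r1": a, "r2": a.copy(), "r3": b})
        assert table.matrix.loc["r1", "r2"] == pytest.approx(1.0)
        assert np.allclose(table.matrix.values, table.matrix.values.T, atol=1e-12)
        assert np.allclose(np.diag(table.matrix.values), 1.0)
        assert set(table.vs_mean.index) == {"r1", "r2", "r3"}

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_ccc_table(pd.DataFrame({"a": [1.0, 2, np.nan], "b": [1.0, 2, 3]}))

    def test_experts_beat_residents_against_truth(self):
        # low-noise "experts" must out-agree high-noise "residents" with the
        # underlying truth in >=95% of seeded replicates
        wins = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            truth = rng.uniform(10, 95, 40)

            def panel_mean_ccc(noise_sd, bias_range, k):
                vals = []
                for _ in range(k):
                    prof = RaterProfile(
                        bias=float(rng.uniform(-bias_range, bias_range)),
                        noise_sd=noise_sd,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    )
                    ratings = simulate_rater(truth, prof)
                    vals.append(lin_ccc(RaterSeries(ratings, truth)).ccc)
                return float(np.mean(vals))

            experts = panel_mean_ccc(4.0, 2.0, 5)
            residents = panel_mean_ccc(12.0, 8.0, 3)
            wins += experts > residents
        assert wins >= 95
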