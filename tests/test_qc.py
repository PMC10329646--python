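"""The aptamer QC cascade: scale-factor and CV filters with strict
boundaries, IQR outlier masking against a brute-force fence oracle, the
two-stage call-rate filter, and log10 z-score normalization."""

import numpy as np
import pandas as pd
import pytest

from proteopheno.qc import (
    RawAptamerData,
    call_rate_cascade,
    filter_cv,
    filter_scale_factor,
    iqr_screen,
    normalize,
    run_qc,
)


def make_raw(values: pd.DataFrame, scale=None, cvs=None, plates=None) -> RawAptamerData:
    if plates is None:
        plates = pd.Series("P1", index=values.index)
    return RawAptamerData(values=values, plate_of=plates, scale_factors=scale, cvs=cvs)


def uniform_values(n=40, aptamers=("A", "B", "C"), seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(50, 150, size=(n, len(aptamers))),
        index=[f"S{i}" for i in range(n)],
        columns=list(aptamers),
    )


class TestScaleFactor:
    def test_divergent_aptamer_removed(self):
        scale = pd.DataFrame({"A": [1.0, 1.6], "B": [1.0, 1.0], "C": [1.0, 1.0]}, index=["P1", "P2"])
        data = make_raw(uniform_values(), scale=scale)
        out, report = filter_scale_factor(data)
        assert list(out.values.columns) == ["B", "C"]
        assert "A" in report.removed_aptamers["scale_factor"]

    def test_boundary_exactly_half_retained(self):
        scale = pd.DataFrame({"A": [1.5], "B": [1.0], "C": [1.0]}, index=["P1"])
        out, _ = filter_scale_factor(make_raw(uniform_values(), scale=scale))
        assert "A" in out.values.columns  # strict >, |1.5 - 1.0| == 0.5 kept

    def test_identical_scales_nothing_removed(self):
        scale = pd.DataFrame(1.0, index=["P1", "P2"], columns=["A", "B", "C"])
        out, report = filter_scale_factor(make_raw(uniform_values(), scale=scale))
        assert out.values.shape[1] == 3
        assert not report.removed_aptamers.get("scale_factor")

    def test_missing_metadata_skips_stage(self):
        out, report = filter_scale_factor(make_raw(uniform_values()))
        assert out.values.shape[1] == 3


class TestCv:
    @pytest.mark.parametrize(
        "cvs,removed",
        [
            ([0.10, 0.20, 0.16], True),   # median 0.16 > 0.15
            ([0.10, 0.15, 0.20], False),  # median exactly 0.15, strict >
            ([0.05], False),
        ],
    )
    def test_median_cv_rule(self, cvs, removed):
        plates = [f"P{i}" for i in range(len(cvs))]
        cv = pd.DataFrame({"A": cvs, "B": [0.05] * len(cvs), "C": [0.05] * len(cvs)}, index=plates)
        out, _ = filter_cv(make_raw(uniform_values(), cvs=cv))
        assert ("A" not in out.values.columns) is removed


class TestIqr:
    def test_outlier_masked_against_fence_oracle(self):
        vals = pd.DataFrame({"A": list(range(1, 10)) + [100]},
                            index=[f"S{i}" for i in range(10)]).astype(float)
        # brute-force oracle: linear-interpolation quartiles of the column
        col = np.sort(vals["A"].to_numpy())
        q1 = np.quantile(col, 0.25)
        q3 = np.quantile(col, 0.75)
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        expect_masked = {i for i, v in enumerate(vals["A"]) if v < lo or v > hi}
        assert expect_masked == {9}
        out, report = iqr_screen(make_raw(vals))
        assert out.values["A"].isna().tolist() == [False] * 9 + [True]
        assert report.n_iqr_masked == 1

    def test_constant_column_untouched(self):
        vals = pd.DataFrame({"A": [5.0] * 10}, index=[f"S{i}" for i in range(10)])
        out, report = iqr_screen(make_raw(vals))
        assert out.values["A"].notna().all()
        assert report.n_iqr_masked == 0

    def test_value_exactly_on_fence_kept(self):
        base = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        q1, q3 = np.quantile(base, [0.25, 0.75])
        hi = q3 + 1.5 * (q3 - q1)
        vals = pd.DataFrame({"A": np.append(base, hi)}, index=[f"S{i}" for i in range(9)])
        out, _ = iqr_screen(make_raw(vals))
        assert out.values["A"].notna().all()

    def test_too_few_values_skipped_with_warning(self):
        vals = pd.DataFrame({"A": [1.0, 2.0, 300.0, np.nan, np.nan, np.nan]},
                            index=[f"S{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="IQR screen skipped"):
            out, _ = iqr_screen(make_raw(vals))
        assert out.values["A"].notna().sum() == 3


class TestCallRate:
    def _with_missing(self, rates: dict[str, float], n=100) -> RawAptamerData:
        rng = np.random.default_rng(1)
        vals = uniform_values(n=n, aptamers=("A", "B", "C", "D"), seed=2)
        for apt, rate in rates.items():
            k = int(round(rate * n))
            vals.iloc[:k, vals.columns.get_loc(apt)] = np.nan
        return make_raw(vals)

    def test_stage1_removes_low_call_rate_aptamer(self):
        out, report = call_rate_cascade(self._with_missing({"A": 0.40}))
        assert "A" in report.removed_aptamers["call_rate_1"]
        assert "A" not in out.values.columns

    def test_stage2_after_recalculation(self):
        out, report = call_rate_cascade(self._with_missing({"A": 0.20}))
        assert "A" in report.removed_aptamers["call_rate_2"]

    def test_fully_observed_untouched(self):
        out, report = call_rate_cascade(make_raw(uniform_values()))
        assert out.values.shape == (40, 3)
        assert not report.removed_aptamers

    def test_all_filtered_is_an_error(self):
        vals = uniform_values(n=10)
        vals.iloc[:, :] = np.nan
        vals.iloc[0, 0] = 1.0
        with pytest.raises(ValueError, match="filtered"):
            call_rate_cascade(make_raw(vals))


class TestNormalize:
    def test_log10_zscore_closed_form(self):
        vals = pd.DataFrame({"A": [10.0, 100.0, 1000.0]}, index=["S0", "S1", "S2"])
        prot, _ = normalize(make_raw(vals))
        # log10 -> [1, 2, 3]; sample sd (ddof=1) is exactly 1
        np.testing.assert_allclose(prot.values["A"].to_numpy(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_output_moments(self):
        prot, _ = normalize(make_raw(uniform_values(n=200)))
        assert np.allclose(prot.values.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(prot.values.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        vals = uniform_values()
        vals["A"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            prot, report = normalize(make_raw(vals))
        assert "A" not in prot.values.columns
        assert "A" in report.removed_aptamers["normalize"]

    def test_nonpositive_value_names_cell(self):
        vals = uniform_values()
        vals.loc["S3", "B"] = -1.0
        with pytest.raises(ValueError, match="S3.*B|B.*S3"):
            normalize(make_raw(vals))

    def test_idempotence(self):
        prot, _ = normalize(make_raw(uniform_values(n=100)))
        again, _ = normalize(make_raw(np.power(10.0, prot.values)))
        np.testing.assert_allclose(
            again.values.to_numpy(), prot.values.to_numpy(), atol=1e-10
        )


class TestCascade:
    def test_cv_monotonicity(self):
        rng = np.random.default_rng(3)
        cv = pd.DataFrame(rng.uniform(0.05, 0.3, size=(3, 10)),
                          index=["P1", "P2", "P3"], columns=[f"A{i}" for i in range(10)])
        vals = uniform_values(aptamers=[f"A{i}" for i in range(10)])
        kept = [
            filter_cv(make_raw(vals, cvs=cv), max_cv=c)[0].values.shape[1]
            for c in (0.30, 0.20, 0.10, 0.05)
        ]
        assert kept == sorted(kept, reverse=True)

    def test_report_conserves_aptamer_count(self):
        rng = np.random.default_rng(4)
        n, m = 60, 12
        vals = pd.DataFrame(rng.lognormal(2, 0.2, size=(n, m)),
                            index=[f"S{i}" for i in range(n)],
                            columns=[f"A{i}" for i in range(m)])
        vals.iloc[: int(0.5 * n), 0] = np.nan
        scale = pd.DataFrame(1.0, index=["P1"], columns=vals.columns)
        scale.loc["P1", "A1"] = 1.8
        cvs = pd.DataFrame(0.05, index=["P1"], columns=vals.columns)
        cvs.loc["P1", "A2"] = 0.25
        data = make_raw(vals, scale=scale, cvs=cvs)
        proteins, report = run_qc(data)
        removed = sum(len(v) for v in report.removed_aptamers.values())
        assert m == proteins.values.shape[1] + removed

    def test_planted_violations_attributed_correctly(self):
        # one scale-factor, one CV, one stage-1 call-rate violation
        rng = np.random.default_rng(5)
        n = 80
        cols = [f"A{i}" for i in range(8)]
        vals = pd.DataFrame(rng.lognormal(2, 0.2, size=(n, 8)),
                            index=[f"S{i}" for i in range(n)], columns=cols)
        vals.iloc[: int(0.4 * n), 3] = np.nan  # A3: 60% call rate
        scale = pd.DataFrame(1.0, index=["P1"], columns=cols)
        scale.loc["P1", "A0"] = 1.7
        cvs = pd.DataFrame(0.05, index=["P1"], columns=cols)
        cvs.loc["P1", "A1"] = 0.3
        proteins, report = run_qc(make_raw(vals, scale=scale, cvs=cvs))
        removed = report.all_removed_aptamers()
        assert set(removed) == {"A0", "A1", "A3"}
        assert removed["A0"].startswith("scale_factor")
        assert removed["A1"].startswith("cv")
        assert removed["A3"].startswith("call_rate_1")
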