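"""Group statistics, percent changes and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cardiomorph.report import (compare_groups, percent_change, run_pipeline,
                                summarize_groups)
from cardiomorph.synth import sample_population


def _table(groups: dict[str, np.ndarray], feature="area_um2") -> pd.DataFrame:
    rows = []
    for g, vals in groups.items():
        for v in vals:
            rows.append({"group": g, feature: float(v), "qualified": 1})
    return pd.DataFrame(rows)


class TestPercentChange:
    def test_hypertrophy_surface_delta(self):
        assert percent_change(3169.79, 3838.96) == pytest.approx(21.11, abs=0.01)

    def test_aspect_ratio_reduction(self):
        assert percent_change(5.16, 4.6) == pytest.approx(-10.85, abs=0.01)

    @given(x=st.floats(0.01, 1e6))
    def test_self_change_is_zero(self, x):
        assert percent_change(x, x) == 0.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            percent_change(0.0, 5.0)


class TestSummaries:
    def test_single_row_group_has_zero_sd(self):
        df = _table({"Control": [5.0]})
        out = summarize_groups(df, features=["area_um2"])
        assert out.loc[0, "mean"] == 5.0
        assert out.loc[0, "sd"] == 0.0
        assert out.loc[0, "sem"] == 0.0

    def test_qualified_filter_excludes_flagged_rows(self):
        df = _table({"Control": [1.0, 2.0, 3.0]})
        df.loc[2, "qualified"] = 0
        q = summarize_groups(df, features=["area_um2"])
        a = summarize_groups(df, features=["area_um2"], qualified_only=False)
        assert q.loc[0, "n_cells"] == 2
        assert a.loc[0, "n_cells"] == 3
        assert q.loc[0, "mean"] == pytest.approx(1.5)

    def test_sem_is_sd_over_sqrt_n(self):
        vals = np.arange(10.0)
        out = summarize_groups(_table({"G": vals, "H": vals + 1}),
                               features=["area_um2"])
        for _, row in out.iterrows():
            assert row["sem"] == pytest.approx(row["sd"] / np.sqrt(row["n_cells"]))

    def test_sampled_control_population_recovers_group_mean(self):
        specs = sample_population("control", 2000, {"intact_rod": 1.0}, seed=5)
        df = pd.DataFrame({"group": "Control",
                           "length_um": [s.length_um for s in specs],
                           "qualified": 1})
        out = summarize_groups(df, features=["length_um"])
        se = 33.06 / np.sqrt(2000)
        assert abs(out.loc[0, "mean"] - 139.42) < 3 * se

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            summarize_groups(_table({"G": [1.0, 2.0]}), features=["bogus"])


class TestComparisons:
    def test_identical_groups_are_not_significant(self):
        vals = np.arange(30.0)
        out = compare_groups(_table({"Control": vals, "B": vals}), "area_um2")
        assert out["omnibus_p"].iloc[0] > 0.5
        b = out[out["group"] == "B"].iloc[0]
        assert b["p_value"] > 0.5
        assert not b["significant"]
        ctrl = out[out["group"] == "Control"].iloc[0]
        assert ctrl["percent_change_vs_control"] == 0.0

    @pytest.mark.parametrize("test", ["kruskal_dunn", "anova_tukey",
                                      "mann_whitney"])
    def test_three_sd_shift_is_detected(self, test):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 200) + 10.0
        b = rng.normal(3.0, 1.0, 200) + 10.0
        out = compare_groups(_table({"Control": a, "B": b}), "area_um2",
                             test=test)
        row = out[out["group"] == "B"].iloc[0]
        assert row["p_value"] < 0.05
        assert row["significant"]

    def test_kruskal_omnibus_matches_hand_ranked_statistic(self):
        # 6 values, 2 groups; H from first-principles ranking
        groups = {"Control": np.array([1.0, 3.0, 5.0]),
                  "B": np.array([2.0, 4.0, 6.0])}
        all_vals = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(all_vals)
        n = all_vals.size
        rbar = {g: ranks[i * 3:(i + 1) * 3].mean()
                for i, g in enumerate(groups)}
        h = 12.0 / (n * (n + 1)) * sum(
            3 * (rbar[g] - (n + 1) / 2) ** 2 for g in groups)
        expected_p = sps.chi2.sf(h, df=1)
        out = compare_groups(_table(groups), "area_um2", test="kruskal_dunn")
        assert out["omnibus_p"].iloc[0] == pytest.approx(expected_p, rel=1e-9)

    def test_fisher_exact_on_binary_feature(self):
        df = _table({"Control": [1.0] * 18 + [0.0] * 2,
                     "B": [1.0] * 5 + [0.0] * 15}, feature="flag")
        out = compare_groups(df, "flag", test="fisher_exact")
        assert out[out["group"] == "B"]["p_value"].iloc[0] < 0.05

    def test_rank_test_requires_two_per_group(self):
        with pytest.raises(ValueError, match="n < 2"):
            compare_groups(_table({"Control": [1.0, 2.0], "B": [1.0]}),
                           "area_um2")

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            compare_groups(_table({"A": [1.0, 2.0], "B": [1.0, 2.0]}),
                           "area_um2", control="Zzz")


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    cfg = {"n_cells_per_group": 40, "qc_train_n": 200, "seed": 1,
           "cells_per_field": 15}
    out = run_pipeline(cfg, tmp_path_factory.mktemp("pipe") / "run1")
    return cfg, out


class TestPipeline:
    def test_outputs_present_and_control_change_zero(self, small_run):
        _, out = small_run
        for name in ("cells.csv", "group_summary.csv", "group_summary_raw.csv",
                     "comparisons.csv", "run_log.json", "qc_model.json"):
            assert (out / name).exists()
        comps = pd.read_csv(out / "comparisons.csv")
        ctrl = comps[comps["group"] == "Control"]
        assert (ctrl["percent_change_vs_control"] == 0.0).all()
        cells = pd.read_csv(out / "cells.csv")
        assert set(cells["qualified"].unique()) <= {0, 1}

    def test_rerun_is_byte_identical(self, small_run, tmp_path):
        cfg, out = small_run
        out2 = run_pipeline(cfg, tmp_path / "run2")
        for name in ("cells.csv", "group_summary.csv", "comparisons.csv"):
            assert (out / name).read_bytes() == (out2 / name).read_bytes()

    def test_unknown_mode_fails_with_stage_context(self, tmp_path):
        with pytest.raises(ValueError, match="mode"):
            run_pipeline({"mode": "nope"}, tmp_path / "x")
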