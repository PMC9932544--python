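"""Statistical battery: tests, ANOVA decomposition, regressions, diagnostics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from alphaffr import stats
from alphaffr.stats import (
    brain_behavior_corr,
    conover_posthoc,
    f0_ratio_one_sample,
    fit_group_regression,
    group_compare,
    mixed_anova_f0,
    rm_anova_2x2,
)


class TestOneSample:
    def test_hand_computed_t(self):
        r = f0_ratio_one_sample([1.1, 1.2, 1.3])
        assert r.statistic == pytest.approx(3.464, abs=0.001)
        assert r.df == 2

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            f0_ratio_one_sample([1.0, 1.0, 1.0])


class TestGroupCompare:
    def test_wilcoxon_identical_convention(self):
        r = group_compare(np.arange(5.0), np.arange(5.0), test="wilcoxon-paired")
        assert r.statistic == 0.0 and r.p == 1.0

    def test_equal_variance_f_example(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.5, size=19)
        y = rng.normal(0, 0.8, size=13)
        x = (x - x.mean()) / x.std(ddof=1) * 2.5
        y = (y - y.mean()) / y.std(ddof=1) * 0.8
        r = group_compare(x, y, test="equal-variance-F")
        assert r.statistic == pytest.approx(2.5**2 / 0.8**2, rel=1e-6)
        assert r.df == (18, 12)
        assert r.p < 0.01

    def test_bonferroni_bookkeeping(self):
        rng = np.random.default_rng(1)
        r = group_compare(rng.normal(size=10), rng.normal(size=12),
                          test="mann-whitney", n_comparisons=4)
        assert r.p_adj == pytest.approx(min(1.0, 4 * r.p))
        assert r.p_adj >= r.p

    def test_mann_whitney_type_i_calibration(self):
        rng = np.random.default_rng(2)
        hits = sum(
            group_compare(rng.normal(size=13), rng.normal(size=19)).p < 0.05
            for _ in range(1000)
        )
        assert 0.03 <= hits / 1000 <= 0.07

    def test_unknown_test(self):
        with pytest.raises(ValueError):
            group_compare([1.0], [2.0], test="anova")


class TestConover:
    def test_hand_computed_two_groups(self):
        # groups {1,2} vs {3,4}: ranks 1..4, Rbar (1.5, 3.5), S2 = 5/3,
        # H = 2.4, scale = 0.5 -> t = -2.828, df = 2, p = 0.1056
        out = conover_posthoc([[1.0, 2.0], [3.0, 4.0]])
        row = out.iloc[0]
        assert row["statistic"] == pytest.approx(-2.8284, abs=1e-3)
        assert row["df"] == 2
        assert row["p"] == pytest.approx(0.1056, abs=1e-3)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        out = conover_posthoc([x, x.copy()])
        assert out["p"].iloc[0] > 0.9

    def test_shifted_group_detected_and_adjusted(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=20), rng.normal(size=20), rng.normal(3, 1, 20)]
        out = conover_posthoc(groups, labels=["a", "b", "c"])
        assert len(out) == 3
        ac = out[(out["a"] == "a") & (out["b"] == "c")].iloc[0]
        assert ac["p_adj"] < 0.01
        assert (out["p_adj"] >= out["p"]).all()


def _factorial_frame(rng, n_nh=6, n_hl=6, effect=0.0):
    rows = []
    for g, n in (("NH", n_nh), ("HL", n_hl)):
        for s in range(n):
            subj = rng.normal(0, 1)
            for snr in ("clear", "noise"):
                for al in ("low", "high"):
                    val = subj + rng.normal(0, 0.5)
                    if g == "NH" and snr == "clear" and al == "high":
                        val += effect
                    rows.append(dict(participant=f"{g}{s}", group=g, snr=snr,
                                     alpha=al, log_f0=val))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_constant_data_all_zero_f(self):
        df = _factorial_frame(np.random.default_rng(0))
        df["log_f0"] = 1.0
        res = mixed_anova_f0(df)
        assert all(v.statistic == 0.0 for v in res.values())

    def test_programmed_interaction_detected(self):
        df = _factorial_frame(np.random.default_rng(1), n_nh=13, n_hl=19, effect=1.0)
        res = mixed_anova_f0(df)
        assert res["snr:alpha:group"].p < 0.05
        assert 0 <= res["snr:alpha:group"].effect_size <= 1

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_r_aov_balanced(self, tmp_path):
        df = _factorial_frame(np.random.default_rng(7))
        res = mixed_anova_f0(df)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = f"""
        d <- read.csv("{csv}")
        for (c in c("participant","group","snr","alpha")) d[[c]] <- factor(d[[c]])
        m <- summary(aov(log_f0 ~ group*snr*alpha + Error(participant/(snr*alpha)), data=d))
        f <- c(m[[1]][[1]]["group","F value"],
               m[[2]][[1]]["snr","F value"], m[[2]][[1]]["group:snr","F value"],
               m[[3]][[1]]["alpha","F value"], m[[3]][[1]]["group:alpha","F value"],
               m[[4]][[1]]["snr:alpha","F value"], m[[4]][[1]]["group:snr:alpha","F value"])
        cat(sprintf("%.10f", f), sep="\\n")
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        r_f = [float(v) for v in out.stdout.split()]
        keys = ["group", "snr", "snr:group", "alpha", "alpha:group",
                "snr:alpha", "snr:alpha:group"]
        for key, expect in zip(keys, r_f):
            assert res[key].statistic == pytest.approx(expect, rel=1e-6), key

    def test_missing_cell_raises(self):
        df = _factorial_frame(np.random.default_rng(2)).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            mixed_anova_f0(df)

    def test_followup_within_anova(self):
        df = _factorial_frame(np.random.default_rng(3), effect=1.5)
        res = rm_anova_2x2(df[df["group"] == "NH"])
        assert set(res) == {"snr", "alpha", "snr:alpha"}
        assert res["snr:alpha"].p < 0.05


class TestBrainBehaviorCorr:
    def test_monotone_and_reversed(self):
        x = np.linspace(0, 1, 12)
        frame = pd.DataFrame({"f0": x, "pc": np.exp(x), "rt": -x})
        out = brain_behavior_corr(frame, ["f0"], ["pc", "rt"])
        assert out.loc[out["behavior"] == "pc", "rho"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out["behavior"] == "rt", "rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        frame = pd.DataFrame({"f0": np.ones(10), "pc": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            brain_behavior_corr(frame, ["f0"], ["pc"])


class TestGroupRegression:
    def test_exact_recovery_noiseless(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 40)
        g = (np.arange(40) >= 20).astype(float)
        y = 1.0 - 2.0 * x + 0.5 * g + 1.0 * x * g
        m = fit_group_regression(y, x, g)
        assert m.params["const"] == pytest.approx(1.0, abs=1e-10)
        assert m.slope_nh == pytest.approx(-2.0, abs=1e-10)
        assert m.slope_diff == pytest.approx(1.0, abs=1e-10)
        assert m.slope_hl == pytest.approx(-1.0, abs=1e-10)

    def test_single_group_refused(self):
        with pytest.raises(ValueError, match="single-group"):
            fit_group_regression(np.arange(10.0), np.arange(10.0), np.zeros(10))

    def test_age_covariate_inert_when_orthogonal(self):
        rng = np.random.default_rng(1)
        n = 60
        x = rng.normal(size=n)
        g = (np.arange(n) >= n // 2).astype(float)
        age = rng.normal(size=n)  # independent of everything
        y = 2.0 - 1.5 * x + 0.8 * x * g + rng.normal(0, 0.5, n)
        base = fit_group_regression(y, x, g)
        adj = fit_group_regression(y, x, g, age=age)
        assert abs(adj.slope_nh - base.slope_nh) < base.bse["x"]
        assert abs(adj.slope_diff - base.slope_diff) < base.bse["x:group"]

    def test_diagnostics_present(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        g = (np.arange(50) >= 25).astype(float)
        y = x + rng.normal(0, 1, 50)
        m = fit_group_regression(y, x, g)
        for key in ("shapiro_p", "breusch_pagan_p", "goldfeld_quandt_p"):
            assert 0 <= m.diagnostics[key] <= 1
        assert m.diagnostics_pass

    def test_programmed_slope_signs_recovered(self):
        # NH slope negative, HL attenuated (positive difference)
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n_nh, n_hl = 13, 19
            x = np.concatenate([rng.uniform(8, 21, n_nh), rng.uniform(16, 45, n_hl)])
            g = np.concatenate([np.zeros(n_nh), np.ones(n_hl)])
            y = 0.15 - 0.0018 * x + 0.0012 * x * g + rng.normal(0, 0.01, n_nh + n_hl)
            m = fit_group_regression(y, x, g)
            hits += (m.slope_nh < 0) and (m.slope_diff > 0)
        assert hits >= 45


def test_bonferroni_helper():
    assert stats.bonferroni(0.3, 4) == 1.0
    assert stats.bonferroni(0.01, 4) == pytest.approx(0.04)
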