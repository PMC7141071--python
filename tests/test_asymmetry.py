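"""DA/FA mixed-model decomposition and group-level asymmetry tests."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from wingspot.asymmetry import (da_group_tests, da_slope_comparison,
                                levene_fa_test, sides_mixed_anova)
from wingspot.synthgen import MEASUREMENT_COLUMNS

from conftest import make_table


def simulate_mixed(rng, n=50, r=2, delta=0.0, s_ind=5.0, s_fa=2.0, s_me=1.0):
    ind = rng.normal(0, s_ind, n)
    cell = ind[:, None] + np.array([-delta / 2, delta / 2]) \
        + rng.normal(0, s_fa, (n, 2))
    reps = cell[:, :, None] + rng.normal(0, s_me, (n, 2, r))
    iid = np.repeat([f"i{i:04d}" for i in range(n)], 2 * r)
    side = np.tile(np.repeat(["L", "R"], r), n)
    rep = np.tile(np.arange(1, r + 1), 2 * n)
    return pd.DataFrame({"individual_id": iid, "side": side,
                         "replicate": rep, "y": reps.reshape(-1)})


class TestSidesMixedAnova:
    def test_noise_free_da_is_exact_and_degenerate_flagged(self):
        t = make_table({
            "i1": {"L": [(10.0, 1.0)] * 2, "R": [(14.0, 1.0)] * 2},
            "i2": {"L": [(20.0, 1.0)] * 2, "R": [(24.0, 1.0)] * 2},
        })
        res = sides_mixed_anova(t, "wing_area")
        assert res.da_estimate == pytest.approx(4.0)
        assert res.ms["interaction"] == 0.0
        assert res.ms["error"] == 0.0
        assert any("degenerate" in f for f in res.flags)

    def test_small_balanced_instance_matches_cell_means_oracle(self, rng):
        df = simulate_mixed(rng, n=4, r=2, delta=1.0)
        res = sides_mixed_anova(df, "y")
        arr = df.sort_values(["individual_id", "side", "replicate"])["y"] \
                .to_numpy().reshape(4, 2, 2)
        cell = arr.mean(axis=2)
        g = arr.mean()
        im = cell.mean(axis=1)
        sm = cell.mean(axis=0)
        ss_ind = 4 * ((im - g) ** 2).sum()
        ss_side = 8 * ((sm - g) ** 2).sum()
        ss_int = 2 * ((cell - im[:, None] - sm[None, :] + g) ** 2).sum()
        ss_err = ((arr - cell[:, :, None]) ** 2).sum()
        assert res.ss["individual"] == pytest.approx(ss_ind, rel=1e-10)
        assert res.ss["side"] == pytest.approx(ss_side, rel=1e-10)
        assert res.ss["interaction"] == pytest.approx(ss_int, rel=1e-10)
        assert res.ss["error"] == pytest.approx(ss_err, rel=1e-10)
        # decomposition is exhaustive
        tot = ((df.y - df.y.mean()) ** 2).sum()
        assert sum(res.ss.values()) == pytest.approx(tot, rel=1e-9)

    def test_unbalanced_falls_back_and_matches_statsmodels(self, rng):
        df = simulate_mixed(rng, n=6, r=3)
        df = df.drop(df.index[[2, 10]])      # ragged replicates, still >= 2
        res = sides_mixed_anova(df, "y")
        assert "unbalanced" in res.flags
        sm = anova_lm(ols("y ~ C(individual_id) + C(side) "
                          "+ C(individual_id):C(side)", df).fit(), typ=1)
        assert res.ss["individual"] == pytest.approx(
            sm.loc["C(individual_id)", "sum_sq"])
        assert res.ss["side"] == pytest.approx(sm.loc["C(side)", "sum_sq"])
        assert res.ss["interaction"] == pytest.approx(
            sm.loc["C(individual_id):C(side)", "sum_sq"])
        assert res.ss["error"] == pytest.approx(sm.loc["Residual", "sum_sq"])

    def test_expected_mean_squares_recovered(self, rng):
        mse, msi = [], []
        for _ in range(400):
            res = sides_mixed_anova(simulate_mixed(rng, n=100), "y")
            mse.append(res.ms["error"])
            msi.append(res.ms["interaction"])
        assert np.mean(mse) == pytest.approx(1.0, rel=0.05)       # sigma_ME^2
        assert np.mean(msi) == pytest.approx(1.0 + 2 * 4.0, rel=0.05)

    def test_da_estimate_equals_grand_mean_of_side_differences(self, rng):
        df = simulate_mixed(rng, n=20, delta=0.7)
        res = sides_mixed_anova(df, "y")
        pw = df.groupby(["individual_id", "side"])["y"].mean()
        diff = (pw.xs("R", level="side") - pw.xs("L", level="side")).mean()
        assert res.da_estimate == pytest.approx(diff, rel=1e-12)

    def test_single_replicate_rejected(self, rng):
        df = simulate_mixed(rng, n=5, r=1)
        with pytest.raises(ValueError, match="separable"):
            sides_mixed_anova(df, "y")


class TestGroupTests:
    @staticmethod
    def individuals(rng, da_by_cell=None, n=20):
        rows = []
        for p in ("A", "B", "C"):
            for t in (16.0, 22.0, 28.0):
                mu = (da_by_cell or {}).get((p, t), 0.0)
                rows.append(pd.DataFrame({
                    "population": p, "temperature_C": t,
                    "asym_spot": mu + rng.normal(0, 1, n),
                    "asym_ratio": mu + rng.normal(0, 1, n)}))
        return pd.concat(rows, ignore_index=True)

    def test_zero_asymmetry_gives_no_da_signal(self):
        ind = pd.DataFrame({"population": ["A"] * 20 + ["B"] * 20,
                            "temperature_C": [16.0, 28.0] * 20,
                            "asym_spot": 0.0})
        summaries, anova = da_group_tests(ind, "asym_spot")
        assert all(s.da_mean == 0.0 for s in summaries)
        assert anova.table.loc["temperature_C", "ss"] == pytest.approx(0.0, abs=1e-18)

    def test_sign_flip_reverses_da_keeps_p(self, rng):
        ind = self.individuals(rng, {("A", 28.0): 1.0})
        s1, a1 = da_group_tests(ind, "asym_spot")
        flipped = ind.assign(asym_spot=-ind.asym_spot)
        s2, a2 = da_group_tests(flipped, "asym_spot")
        for u, v in zip(s1, s2):
            assert u.da_mean == pytest.approx(-v.da_mean)
            assert u.p == pytest.approx(v.p)
        assert a1.p("temperature_C:population") == pytest.approx(
            a2.p("temperature_C:population"))

    def test_mixed_anova_route_used_when_table_given(self, rng):
        df = simulate_mixed(rng, n=12, delta=2.0)
        df["population"] = "A"
        df["temperature_C"] = 22.0
        df = df.rename(columns={"y": "spot_area"})
        df["wing_area"] = 100.0
        pw = df.groupby(["individual_id", "side"])["spot_area"].mean().unstack()
        ind = pd.DataFrame({
            "individual_id": pw.index, "population": "A", "temperature_C": 22.0,
            "asym_spot": (pw["R"] - pw["L"]).to_numpy()})
        ind2 = pd.concat([ind, ind.assign(population="B"),
                          ind.assign(temperature_C=16.0),
                          ind.assign(population="B", temperature_C=16.0)],
                         ignore_index=True)
        df2 = pd.concat([df, df.assign(population="B"),
                         df.assign(temperature_C=16.0),
                         df.assign(population="B", temperature_C=16.0)],
                        ignore_index=True)
        summaries, _ = da_group_tests(
            ind2, "asym_spot", table=df2, measurement_trait="spot_area")
        assert all(s.method == "mixed-anova" for s in summaries)
        ref = sides_mixed_anova(df, "spot_area")
        assert summaries[0].p == pytest.approx(ref.p_DA)


class TestLevene:
    def test_location_shift_invariance(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 2, 30)
        f1, _, p1, _ = levene_fa_test([a, b])
        f2, _, p2, _ = levene_fa_test([a + 5.0, b - 3.0])
        assert f1 == pytest.approx(f2)
        assert p1 == pytest.approx(p2)

    def test_power_for_ratio_fa_contrast(self, rng):
        # sd 0.003 vs 0.010 at n = 35: the 16C-vs-28C ratio-FA contrast
        hits = 0
        for _ in range(1000):
            a = rng.normal(0, 0.003, 35)
            b = rng.normal(0.005, 0.010, 35)
            _, _, p, _ = levene_fa_test([a, b])
            hits += p < 0.05
        assert hits / 1000 > 0.9

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(400):
            ps.append(levene_fa_test([rng.normal(0, 1, 25),
                                      rng.normal(0, 1, 25)])[2])
        assert 0.02 < np.mean(np.array(ps) < 0.05) < 0.09

    def test_reports_group_sds(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 3, 20)
        _, _, _, sds = levene_fa_test([a, b])
        assert sds[0] == pytest.approx(np.std(a, ddof=1))
        assert sds[1] == pytest.approx(np.std(b, ddof=1))


class TestDaSlopeComparison:
    def test_identical_populations_give_null_ts(self, rng):
        base = pd.DataFrame({
            "temperature_C": np.repeat([16.0, 22.0, 28.0], 15),
            "asym_ratio": rng.normal(0, 0.01, 45)})
        ind = pd.concat([base.assign(population=p) for p in "AB"],
                        ignore_index=True)
        fits, pairwise = da_slope_comparison(ind)
        (t, df, p), = pairwise.values()
        assert t == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_distinct_slopes_detected(self, rng):
        rows = []
        for p, slope in (("A", 0.0), ("B", 0.002), ("C", 0.002)):
            t = np.repeat([16.0, 22.0, 28.0], 40)
            rows.append(pd.DataFrame({
                "population": p, "temperature_C": t,
                "asym_ratio": slope * t + rng.normal(0, 0.003, 120)}))
        ind = pd.concat(rows, ignore_index=True)
        fits, pairwise = da_slope_comparison(ind)
        assert pairwise[("A", "B")][2] < 0.05
        assert pairwise[("A", "C")][2] < 0.05
        assert pairwise[("B", "C")][2] > 0.05

    def test_relabeling_permutes_results(self, rng):
        base = pd.DataFrame({
            "temperature_C": np.tile([16.0, 22.0, 28.0], 12),
            "asym_ratio": rng.normal(0, 0.01, 36)})
        other = pd.DataFrame({
            "temperature_C": np.tile([16.0, 22.0, 28.0], 12),
            "asym_ratio": rng.normal(0.005, 0.02, 36)})
        ind1 = pd.concat([base.assign(population="A"),
                          other.assign(population="B")], ignore_index=True)
        ind2 = pd.concat([base.assign(population="B"),
                          other.assign(population="A")], ignore_index=True)
        _, p1 = da_slope_comparison(ind1)
        _, p2 = da_slope_comparison(ind2)
        t1, _, pv1 = p1[("A", "B")]
        t2, _, pv2 = p2[("A", "B")]
        assert t1 == pytest.approx(-t2)
        assert pv1 == pytest.approx(pv2)
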