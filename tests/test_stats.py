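import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import toy_splitplot_table
from oracles import oneway_f, splitplot_f, splitplot_ss

from freeop.stats import (
    drop_incomplete_subjects,
    flsd_bars,
    flsd_half_width,
    mauchly_test,
    mixed_anova,
    simple_effects,
    sphericity_epsilons,
    welch_t,
)


class TestWelch:
    def test_identical_samples_t_zero(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)

    def test_equal_variance_case_matches_pooled_t(self):
        # with equal n and equal variances Welch reduces to Student's t
        a = np.array([1.0, 2.0, 3.0])
        b = a + 1.0
        r = welch_t(a, b)
        t_pooled, _ = sps.ttest_ind(a, b, equal_var=True)
        assert r.t == pytest.approx(float(t_pooled))
        assert r.df == pytest.approx(4.0)

    def test_antisymmetric_under_swap(self):
        a, b = [1.0, 4.0, 2.0, 5.0], [0.0, 1.0, 2.5]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.df == pytest.approx(r2.df)
        assert r1.p == pytest.approx(r2.p)

    def test_constant_equal_samples_convention(self):
        r = welch_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (r.t, r.p) == (0.0, 1.0)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestEpsilons:
    def test_compound_symmetry_is_spherical(self):
        # CS covariance: equal variances, equal covariances → ε_GG = 1
        k = 4
        cov = np.full((k, k), 0.3) + 0.7 * np.eye(k)
        gg, hf = sphericity_epsilons(cov, n_subjects=20)
        assert gg == pytest.approx(1.0)
        assert hf >= gg

    def test_two_levels_trivially_spherical(self):
        cov = np.array([[1.0, 0.2], [0.2, 2.0]])
        assert sphericity_epsilons(cov, 10) == (1.0, 1.0)
        m = mauchly_test(cov, 10)
        assert m.p == 1.0

    def test_rank_one_dominant_near_lower_bound(self):
        # one dominant contrast direction drives ε_GG towards 1/(k−1)
        k = 4
        v = np.array([3.0, -1.0, -1.0, -1.0])
        cov = np.outer(v, v) + 1e-6 * np.eye(k)
        gg, _ = sphericity_epsilons(cov, 30)
        assert gg == pytest.approx(1.0 / (k - 1), abs=1e-3)

    def test_bounds_respected(self, rng):
        for _ in range(20):
            A = rng.normal(size=(8, 4))
            cov = A.T @ A
            gg, hf = sphericity_epsilons(cov, 12)
            assert 1.0 / 3 <= gg <= 1.0
            assert hf >= 1.0 / 3

    def test_matches_reference_implementation(self):
        # pingouin computes the same GG/HF from the same covariance
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        data = rng.normal(size=(12, 4)) * [1.0, 2.0, 0.5, 1.5]
        wide = pd.DataFrame(data, columns=list("abcd"))
        cov = np.cov(data, rowvar=False)
        gg, hf = sphericity_epsilons(cov, 12, 1)
        assert gg == pytest.approx(float(pg.epsilon(wide, correction="gg")))
        assert hf == pytest.approx(float(pg.epsilon(wide, correction="hf")))
        m = mauchly_test(cov, 12, 1)
        sph = pg.sphericity(wide)
        assert m.W == pytest.approx(float(sph.W))
        assert m.p == pytest.approx(float(sph.pval))

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError):
            sphericity_epsilons(np.array([[1.0, 0.5], [0.1, 1.0]]), 10)


@pytest.mark.parametrize(
    "group_sizes,k,seed",
    [
        ((4, 4), 3, 0),
        ((3, 4, 5), 3, 1),
        ((4, 4, 4), 4, 2),
        ((6, 3), 5, 3),
    ],
)
class TestMixedAnovaOracle:
    def test_matches_brute_force_sums_of_squares(self, group_sizes, k, seed):
        df = toy_splitplot_table(group_sizes, k, seed)
        oracle = splitplot_ss(df, "y", "level", "group", "subject")
        res = mixed_anova(df, dv="y", within="level", between="group",
                         subject="subject")
        by = {r.effect: r for r in res}
        rel = lambda a, b: abs(a - b) / max(abs(b), 1e-12)  # noqa: E731
        assert rel(by["group"].ss_effect, oracle["ss_group"]) < 1e-10
        assert rel(by["group"].ss_error, oracle["ss_subjects"]) < 1e-10
        assert rel(by["level"].ss_effect, oracle["ss_within"]) < 1e-10
        assert rel(by["group × level"].ss_effect, oracle["ss_interaction"]) < 1e-10
        assert rel(by["level"].ss_error, oracle["ss_error"]) < 1e-10

    def test_f_and_p_match_oracle(self, group_sizes, k, seed):
        df = toy_splitplot_table(group_sizes, k, seed)
        oracle = splitplot_f(df, "y", "level", "group", "subject")
        res = {r.effect: r for r in mixed_anova(
            df, dv="y", within="level", between="group", subject="subject")}
        assert res["group"].F == pytest.approx(oracle["group"][0], rel=1e-10)
        assert res["level"].F == pytest.approx(oracle["within"][0], rel=1e-10)
        assert res["group × level"].F == pytest.approx(
            oracle["interaction"][0], rel=1e-10)
        assert res["level"].p_uncorrected == pytest.approx(
            oracle["within"][1], rel=1e-9)


class TestMixedAnovaBehaviour:
    def test_constant_within_levels_give_zero_f(self):
        rows = []
        for j, g in enumerate("AB"):
            for i in range(3):
                for lev in range(3):
                    rows.append(dict(subject=f"{g}{i}", group=g, level=lev,
                                     y=float(i + 10 * j)))
        with pytest.warns(RuntimeWarning):
            res = mixed_anova(pd.DataFrame(rows), dv="y", within="level",
                             between="group", subject="subject")
        by = {r.effect: r for r in res}
        assert by["level"].F == 0.0
        assert by["group × level"].F == 0.0

    def test_two_within_levels_no_correction(self):
        df = toy_splitplot_table((5, 5), 2, seed=4)
        res = {r.effect: r for r in mixed_anova(
            df, dv="y", within="level", between="group", subject="subject")}
        assert res["level"].epsilon_gg == 1.0
        assert res["level"].epsilon_hf == 1.0
        assert res["level"].p_corrected == res["level"].p_uncorrected
        assert res["level"].correction_used == "none"

    def test_missing_cell_raises_naming_it(self):
        df = toy_splitplot_table((3, 3), 3, seed=5)
        df = df[~((df.subject == "s01") & (df.level == 2))]
        with pytest.raises(ValueError, match="s01"):
            mixed_anova(df, dv="y", within="level", between="group",
                        subject="subject")

    def test_matches_pingouin_on_balanced_data(self):
        pg = pytest.importorskip("pingouin")
        df = toy_splitplot_table((8, 8), 4, seed=6, integers=False)
        mine = {r.effect: r for r in mixed_anova(
            df, dv="y", within="level", between="group", subject="subject")}
        theirs = pg.mixed_anova(df, dv="y", within="level", between="group",
                                subject="subject")
        ref = {row.Source: row for row in theirs.itertuples()}
        assert mine["group"].F == pytest.approx(ref["group"].F, rel=1e-9)
        assert mine["level"].F == pytest.approx(ref["level"].F, rel=1e-9)
        assert mine["group × level"].F == pytest.approx(
            ref["Interaction"].F, rel=1e-9)
        assert mine["level"].p_uncorrected == pytest.approx(
            ref["level"]._asdict()["p_unc"], rel=1e-9)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_ss_conservation(self, seed):
        df = toy_splitplot_table((3, 4), 3, seed, integers=False)
        res = mixed_anova(df, dv="y", within="level", between="group",
                         subject="subject")
        by = {r.effect: r for r in res}
        total = (
            by["group"].ss_effect + by["group"].ss_error
            + by["level"].ss_effect + by["group × level"].ss_effect
            + by["level"].ss_error
        )
        y = df["y"].to_numpy()
        assert total == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-9)

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_ges_invariant_to_affine_rescaling(self, scale, shift):
        df = toy_splitplot_table((4, 4), 3, seed=8, integers=False)
        df2 = df.assign(y=df.y * scale + shift)
        r1 = mixed_anova(df, dv="y", within="level", between="group",
                        subject="subject")
        r2 = mixed_anova(df2, dv="y", within="level", between="group",
                        subject="subject")
        for a, b in zip(r1, r2):
            assert 0.0 <= a.ges <= 1.0
            assert a.ges == pytest.approx(b.ges, rel=1e-8)


class TestSimpleEffects:
    def test_equal_group_means_give_zero_f(self):
        rows = [
            dict(subject=f"s{i}{g}", group=g, level=0, y=float(i))
            for g in "AB" for i in range(4)
        ]
        r = simple_effects(pd.DataFrame(rows), dv="y", within="level",
                          between="group", subject="subject", at_level=0)
        assert r.F == pytest.approx(0.0)

    def test_matches_one_way_oracle(self, rng):
        groups = [rng.normal(loc=m, size=n)
                  for m, n in ((0.0, 5), (1.0, 7), (0.5, 4))]
        rows = []
        for j, g in enumerate(groups):
            for i, v in enumerate(g):
                rows.append(dict(subject=f"g{j}s{i}", group=f"g{j}",
                                 level="L", y=float(v)))
        r = simple_effects(pd.DataFrame(rows), dv="y", within="level",
                          between="group", subject="subject", at_level="L")
        F, p, eta2 = oneway_f(groups)
        assert r.F == pytest.approx(F, rel=1e-10)
        assert r.p_corrected == pytest.approx(p, rel=1e-9)
        assert r.ges == pytest.approx(eta2, rel=1e-10)

    def test_location_invariance(self, rng):
        df = toy_splitplot_table((4, 4), 3, seed=9, integers=False)
        r1 = simple_effects(df, dv="y", within="level", between="group",
                           subject="subject", at_level=1)
        df2 = df.assign(y=df.y + 42.0)
        r2 = simple_effects(df2, dv="y", within="level", between="group",
                           subject="subject", at_level=1)
        assert r1.F == pytest.approx(r2.F, rel=1e-9)

    def test_unknown_level_rejected(self):
        df = toy_splitplot_table((3, 3), 3, seed=10)
        with pytest.raises(ValueError):
            simple_effects(df, dv="y", within="level", between="group",
                          subject="subject", at_level=99)


class TestFlsd:
    def test_zero_spread_zero_width(self):
        assert flsd_half_width([1.0, 1.0, 1.0], [0.0, 0.0, 0.0]) == 0.0

    def test_width_grows_as_alpha_shrinks(self, rng):
        d = rng.normal(size=10)
        widths = [flsd_half_width(d, alpha=a) for a in (0.2, 0.1, 0.05, 0.01)]
        assert widths == sorted(widths)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            flsd_half_width([1.0])

    def test_bar_overlap_equals_paired_t_decision(self):
        # exhaustive grid of simulated paired datasets: bars fail to
        # overlap exactly when the paired t-test rejects at the same α
        rng = np.random.default_rng(99)
        agree = 0
        trials = 200
        for _ in range(trials):
            n = int(rng.integers(4, 20))
            shift = rng.uniform(-1.5, 1.5)
            a = rng.normal(size=n)
            b = a + shift + rng.normal(scale=1.0, size=n)
            hw = flsd_half_width(a, b, alpha=0.05)
            non_overlap = abs(a.mean() - b.mean()) > 2 * hw
            t_reject = sps.ttest_rel(a, b).pvalue < 0.05
            agree += non_overlap == t_reject
        assert agree == trials

    def test_bars_per_condition(self, rng):
        rows = []
        for i in range(8):
            base = rng.normal()
            for lev in (0.0, 0.3, 0.6):
                rows.append(dict(subject=f"s{i}", level=lev,
                                 y=base + lev + rng.normal(scale=0.2)))
        bars = flsd_bars(pd.DataFrame(rows), dv="y", within="level",
                        subject="subject")
        assert [b.condition for b in bars] == [0.0, 0.3, 0.6]
        assert all(b.half_width >= 0 for b in bars)


class TestMissingData:
    def test_incomplete_subjects_dropped_and_counted(self):
        df = toy_splitplot_table((3, 3), 3, seed=11)
        df.loc[df.subject == "s00", "y"] = np.nan
        kept, n_dropped = drop_incomplete_subjects(df, "y", "subject")
        assert n_dropped == 1
        assert "s00" not in set(kept.subject)
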