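"""ANOVA decompositions, rank tests, Bonferroni, phase unwrapping."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronophase import (
    bonferroni,
    mann_whitney,
    one_way_anova,
    two_way_anova,
    unwrap_phases,
)


def long_frame(cells, reps_key="values"):
    rows = []
    for (a, b), values in cells.items():
        for v in values:
            rows.append({"genotype": a, "zt_h": b, "value": float(v)})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_textbook_2x2_decomposition(self):
        # hand-computed: SS_A=128, SS_B=32, SS_AB=0, SS_res=8 (df 4)
        data = long_frame(
            {
                ("a1", 0): [2, 4],
                ("a1", 12): [6, 8],
                ("a2", 0): [10, 12],
                ("a2", 12): [14, 16],
            }
        )
        res = two_way_anova(data)
        assert res.table.loc["genotype", "sum_sq"] == pytest.approx(128.0)
        assert res.table.loc["zt_h", "sum_sq"] == pytest.approx(32.0)
        assert res.table.loc["genotype:zt_h", "sum_sq"] == pytest.approx(0.0)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(8.0)
        assert res.table.loc["genotype", "F"] == pytest.approx(64.0)
        assert res.table.loc["zt_h", "F"] == pytest.approx(16.0)

    def test_no_genotype_effect_gives_zero_ss(self):
        data = long_frame(
            {
                ("a1", 0): [1, 1],
                ("a1", 12): [5, 5],
                ("a2", 0): [1, 1],
                ("a2", 12): [5, 5],
            }
        )
        res = two_way_anova(data)
        assert res.table.loc["genotype", "sum_sq"] == pytest.approx(0.0)
        assert res.table.loc["genotype:zt_h", "sum_sq"] == pytest.approx(0.0)

    def test_ss_decomposition_sums_to_total(self, rng):
        data = long_frame(
            {
                (g, t): rng.normal(size=4)
                for g in ("wt", "ko")
                for t in (0, 4, 8, 12)
            }
        )
        res = two_way_anova(data)
        total = ((data["value"] - data["value"].mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_balanced_path_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        data = long_frame(
            {(g, t): rng.normal(g == "ko", 1, 3) for g in ("wt", "ko") for t in (0, 8, 16)}
        )
        res = two_way_anova(data)
        fit = smf.ols("value ~ C(genotype)*C(zt_h)", data=data).fit()
        aov = sm.stats.anova_lm(fit, typ=2)
        assert res.table.loc["genotype", "F"] == pytest.approx(aov.loc["C(genotype)", "F"])
        assert res.table.loc["genotype:zt_h", "p"] == pytest.approx(
            aov.loc["C(genotype):C(zt_h)", "PR(>F)"]
        )

    def test_unbalanced_design_uses_type_ii(self, rng):
        cells = {(g, t): rng.normal(size=(3 if g == "ko" else 4)) for g in ("wt", "ko") for t in (0, 8, 16)}
        res = two_way_anova(long_frame(cells))
        assert {"genotype", "zt_h", "genotype:zt_h", "Residual"} <= set(res.table.index)
        assert np.isfinite(res.p("genotype:zt_h"))

    def test_empty_cell_raises(self):
        data = long_frame({("a", 0): [1, 2], ("a", 12): [3, 4], ("b", 0): [5, 6]})
        with pytest.raises(ValueError):
            two_way_anova(data)

    def test_phase_gap_interaction_power(self):
        """wt vs Cry1 skin Bmal1 interaction detected in >=90% of 100 seeds."""
        from chronophase import expression_profile, simulate_expression

        times = [0.0, 4.0, 8.0, 12.0, 16.0, 20.0]
        hits = 0
        for seed in range(100):
            frames = []
            for g in ("wt", "cry1"):
                tc = simulate_expression(
                    expression_profile(g, "skin", "Bmal1", noise_cv=0.2),
                    times,
                    3,
                    seed=seed * 7 + (g == "cry1"),
                    genotype=g,
                )
                df = tc.data.copy()
                df["genotype"] = g
                frames.append(df)
            p = two_way_anova(pd.concat(frames)).p("genotype:zt_h")
            hits += p < 0.05
        assert hits >= 90


class TestOneWayAnova:
    def test_identical_groups(self):
        groups = {g: np.array([5.0, 5.0, 5.0]) for g in "abc"}
        res = one_way_anova(groups, circular=False)
        assert res.table.loc["group", "sum_sq"] == pytest.approx(0.0)
        assert (res.pairwise["p_adjusted"] == 1.0).all()

    def test_three_group_toy_matches_bruteforce(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [6, 7, 8]}
        res = one_way_anova(groups, circular=False)
        # brute force: SS_between=42 (df 2), SS_within=6 (df 6) -> F=21
        assert res.table.loc["group", "sum_sq"] == pytest.approx(42.0)
        assert res.table.loc["Residual", "sum_sq"] == pytest.approx(6.0)
        assert res.table.loc["group", "F"] == pytest.approx(21.0)

    def test_circular_unwrap_handles_midnight_wrap(self):
        # phases straddling ZT0: linear ANOVA on raw values would explode
        groups = {"a": [23.5, 0.5, 23.8], "b": [23.6, 0.2, 0.1]}
        res = one_way_anova(groups, circular=True)
        assert res.table.loc["group", "F"] < 1.5  # groups are equivalent

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0], "b": [1.0, 2.0]})


def mann_whitney_exact_oracle(a, b):
    """Two-tailed p by full enumeration of all label arrangements."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    pooled = a + b
    u_obs = sum(1 for x in a for y in b if x > y)
    u_obs = min(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        sel = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n1 + n2) if i not in idx]
        u = sum(1 for x in sel for y in rest if x > y)
        u = min(u, n1 * n2 - u)
        count += u <= u_obs
        total += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_midpoint_u(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.u == pytest.approx(4.5)  # n1*n2/2

    def test_separated_samples_exact_p(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u == 0
        assert r.p == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (5, 5)])
    def test_matches_enumeration_oracle(self, n1, n2, rng):
        for _ in range(10):
            a = rng.permutation(100)[:n1].astype(float)
            b = rng.permutation(100)[50 : 50 + n2].astype(float) + 0.5
            r = mann_whitney(a, b)
            assert r.p == pytest.approx(mann_whitney_exact_oracle(a, b))

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(0, 1, 10)
        r = mann_whitney(a, a + 100)
        assert r.p < 0.01

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01, 0.2]) == pytest.approx([0.02, 0.4])
        assert bonferroni([0.9], m=3) == pytest.approx([1.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=20),
        m=st.integers(1, 10),
    )
    def test_monotone_and_bounded(self, p, m):
        p = np.asarray(p)
        adj = bonferroni(p, m=m)
        assert (adj >= p).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bonferroni([1.2])


class TestUnwrapPhases:
    def test_wrapped_phases_move_to_common_branch(self):
        out = unwrap_phases([23.5, 0.5, 23.9])
        assert np.ptp(out) < 2.0
        assert np.allclose(np.sort(out % 24), [0.5, 23.5, 23.9])

    def test_concentrated_phases_untouched(self):
        p = np.array([13.9, 14.2, 14.6])
        assert unwrap_phases(p) == pytest.approx(p)
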