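"""Group-statistics tests against brute-force and enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import hemoloco as hl


class TestSummarize:
    def test_two_value_group(self):
        table = pd.DataFrame({"vessel": ["a", "a"], "max_peak": [2.0, 4.0]})
        out = hl.summarize(table, "max_peak", "vessel")
        assert out["mean"][0] == pytest.approx(3.0)
        assert out["sd"][0] == pytest.approx(np.sqrt(2.0))
        assert out["n"][0] == 2

    def test_singleton_group_sd_flagged(self):
        table = pd.DataFrame({"vessel": ["a"], "max_peak": [5.0]})
        out = hl.summarize(table, "max_peak", "vessel")
        assert out["mean"][0] == 5.0
        assert np.isnan(out["sd"][0]) and out["sd_undefined"][0]

    def test_matches_brute_force_two_pass(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {"vessel": rng.choice(list("abcd"), 1000), "max_peak": rng.normal(2, 3, 1000)}
        )
        out = hl.summarize(table, "max_peak", "vessel").set_index("vessel")
        for g in "abcd":
            vals = [v for v, lab in zip(table.max_peak, table.vessel) if lab == g]
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert out.loc[g, "mean"] == pytest.approx(mean, rel=1e-12)
            assert out.loc[g, "sd"] == pytest.approx(sd, rel=1e-12)


class TestCorrelate:
    def test_exact_linear_relation(self):
        table = pd.DataFrame(
            {"vessel": "artery", "locomotion_auc": np.arange(10.0),
             "max_peak": 2.0 * np.arange(10.0) + 1.0}
        )
        out = hl.correlate(table)
        assert out.r[0] == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        """Under independence, the two-sided p-value is uniform (KS check)."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(200):
            table = pd.DataFrame(
                {"vessel": "artery", "locomotion_auc": rng.normal(size=50),
                 "max_peak": rng.normal(size=50)}
            )
            pvals.append(hl.correlate(table).p[0])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        t1 = pd.DataFrame({"vessel": "v", "locomotion_auc": x, "max_peak": y})
        t2 = pd.DataFrame({"vessel": "v", "locomotion_auc": 3 * x - 2, "max_peak": 0.5 * y + 7})
        assert hl.correlate(t1).r[0] == pytest.approx(hl.correlate(t2).r[0], rel=1e-12)

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"vessel": "v", "locomotion_auc": [1.0] * 5,
                              "max_peak": np.arange(5.0)})
        with pytest.raises(ValueError, match="variance"):
            hl.correlate(table)


class TestCompareSlopes:
    def _table(self, ya, yb, x=None):
        x = np.arange(10.0) if x is None else x
        return pd.DataFrame(
            {"x": np.r_[x, x], "y": np.r_[ya, yb],
             "vessel": ["dv"] * len(x) + ["mn"] * len(x)}
        )

    def test_identical_groups_have_no_differences(self):
        rng = np.random.default_rng(2)
        y = 1.5 * np.arange(10.0) + rng.normal(0, 0.5, 10)
        out = hl.compare_slopes(self._table(y, y), "x", "y", "vessel")
        assert out.slope_difference == pytest.approx(0.0, abs=1e-10)
        assert out.p_slope > 0.95

    def test_vertical_offset_shows_in_intercept_only(self):
        rng = np.random.default_rng(3)
        y = 2.0 * np.arange(10.0) + rng.normal(0, 0.3, 10)
        out = hl.compare_slopes(self._table(y, y + 5.0), "x", "y", "vessel")
        assert out.slope_difference == pytest.approx(0.0, abs=1e-10)
        assert abs(out.intercept_difference) == pytest.approx(5.0, abs=1e-8)
        assert out.p_intercept < 1e-6

    def test_matches_explicit_design_matrix_solve(self):
        """Interaction regression reproduced by hand on a 20-point fixture."""
        rng = np.random.default_rng(4)
        x = np.arange(10.0)
        ya = 1.0 * x + rng.normal(0, 1, 10)
        yb = 2.5 * x + 3 + rng.normal(0, 1, 10)
        table = self._table(ya, yb)
        out = hl.compare_slopes(table, "x", "y", "vessel")
        # oracle: X = [1, x, g, x·g] with g = 1 for group 'mn'
        g = np.r_[np.zeros(10), np.ones(10)]
        xx = np.r_[x, x]
        design = np.column_stack([np.ones(20), xx, g, xx * g])
        yy = np.r_[ya, yb]
        beta, *_ = np.linalg.lstsq(design, yy, rcond=None)
        resid = yy - design @ beta
        sigma2 = resid @ resid / (20 - 4)
        cov = sigma2 * np.linalg.inv(design.T @ design)
        t_stat = beta[3] / np.sqrt(cov[3, 3])
        p = 2 * sps.t.sf(abs(t_stat), 20 - 4)
        assert abs(out.slope_difference) == pytest.approx(abs(beta[3]), rel=1e-8)
        assert out.p_slope == pytest.approx(p, rel=1e-8)

    def test_degenerate_input_rejected(self):
        table = self._table(np.arange(10.0), np.arange(10.0), x=np.full(10, 2.0))
        with pytest.raises(ValueError):
            hl.compare_slopes(table, "x", "y", "vessel")


def _null_table(rng, n_animals=6, rows_per_animal=40, animal_sd=1.0):
    """Animal-structured noise with no true vessel effect."""
    rows = []
    for a in range(n_animals):
        shift = rng.normal(0, animal_sd)
        for _ in range(rows_per_animal):
            rows.append(dict(animal_id=f"M{a}",
                             vessel=rng.choice(["artery", "whisker_vein", "draining_vein"]),
                             max_peak=shift + rng.normal()))
    return pd.DataFrame(rows)


class TestMixedCompare:
    SPEC = hl.ComparisonSpec(response="max_peak", fixed=("vessel",))

    def test_zero_random_variance_matches_oneway_anova(self):
        """Forced-zero random variance reduces exactly to fixed-effects ANOVA."""
        rng = np.random.default_rng(5)
        table = _null_table(rng, animal_sd=0.0)
        out = hl.mixed_compare(table, self.SPEC, random_variance_zero=True)
        groups = [g.max_peak.to_numpy() for _, g in table.groupby("vessel")]
        f_ref, p_ref = sps.f_oneway(*groups)
        row = out.factor_tests.iloc[0]
        assert row.statistic == pytest.approx(f_ref, abs=1e-6)
        assert row.p == pytest.approx(p_ref, abs=1e-6)
        assert out.method == "ols"

    def test_label_shuffle_false_positive_rate(self):
        """Shuffled vessel labels stay non-significant in >= 94 of 100 runs."""
        rng = np.random.default_rng(6)
        base = _null_table(rng, n_animals=4, rows_per_animal=30)
        hits = 0
        for _ in range(100):
            shuffled = base.copy()
            shuffled["vessel"] = rng.permutation(shuffled["vessel"].to_numpy())
            out = hl.mixed_compare(shuffled, self.SPEC)
            if out.factor_tests.iloc[0].p <= 0.05:
                hits += 1
        assert hits <= 6

    def test_injected_vessel_effect_detected(self):
        rng = np.random.default_rng(8)
        table = _null_table(rng)
        sd = table.max_peak.std()
        table.loc[table.vessel == "draining_vein", "max_peak"] -= 3.0 * sd
        out = hl.mixed_compare(table, self.SPEC)
        assert out.method == "mixedlm" and out.converged
        assert out.factor_tests.iloc[0].p < 1e-6
        dv_rows = out.pairwise[(out.pairwise.level_a == "draining_vein")
                               | (out.pairwise.level_b == "draining_vein")]
        assert (dv_rows.p_tukey < 0.05).all()

    def test_tukey_never_below_raw(self, default_study):
        table = default_study.metrics
        table = table[table.vessel.isin(["artery", "whisker_vein", "draining_vein"])]
        out = hl.mixed_compare(table, self.SPEC)
        assert (out.pairwise.p_tukey >= out.pairwise.p_raw - 1e-12).all()

    def test_single_animal_random_grouping_rejected(self):
        table = _null_table(np.random.default_rng(9), n_animals=1)
        with pytest.raises(ValueError, match="random grouping"):
            hl.mixed_compare(table, self.SPEC)


class TestTwoGroup:
    def test_identical_paired_samples_flagged_p_one(self):
        a = np.arange(10.0)
        out = hl.two_group_test(a, a, paired=True)
        assert out.all_tied and out.pvalue == 1.0

    def test_similar_unpaired_samples_nonsignificant(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=40)
        out = hl.two_group_test(a, rng.normal(size=40))
        assert out.pvalue > 0.05

    def test_disjoint_supports_extreme_statistic(self):
        a = np.arange(20.0)
        b = np.arange(100.0, 120.0)
        out = hl.two_group_test(a, b)
        assert out.statistic in (0.0, 400.0)
        assert out.pvalue < 1e-7

    def test_exact_enumeration_oracle_n5(self):
        """Mann-Whitney p equals full enumeration over all C(10,5) labelings."""
        a = np.array([1.2, 3.4, 0.5, 2.2, 4.1])
        b = np.array([2.9, 5.5, 6.1, 1.7, 4.8])
        out = hl.two_group_test(a, b)

        def u_stat(x, y):
            return sum(1.0 for xi in x for yi in y if xi > yi)

        combined = np.concatenate([a, b])
        center = len(a) * len(b) / 2.0
        obs = abs(u_stat(a, b) - center)
        count = 0
        total = 0
        for idx in itertools.combinations(range(10), 5):
            xa = combined[list(idx)]
            xb = np.delete(combined, list(idx))
            if abs(u_stat(xa, xb) - center) >= obs - 1e-12:
                count += 1
            total += 1
        assert out.pvalue == pytest.approx(count / total, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=15), rng.normal(0.5, 1, 15)
        p1 = hl.two_group_test(a, b).pvalue
        p2 = hl.two_group_test(np.exp(a), np.exp(b)).pvalue
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            hl.two_group_test([1.0, 2.0], [1.0], paired=True)


def test_normality_report_contents():
    rng = np.random.default_rng(12)
    rep = hl.normality_report(rng.normal(size=80), rng.normal(size=60) * 2)
    assert rep["sample_a"]["shapiro_p"] > 0.01
    assert 0 <= rep["variance_F"]["p"] <= 1
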