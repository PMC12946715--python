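"""Association statistics: effects, permutation p, FDR, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifespanfc.stats import (
    CollinearityError,
    PermutationScheme,
    bootstrap_ci,
    exclude_outliers,
    fdr_bh,
    linear_effect,
    mass_univariate,
    over_and_above,
    permutation_pvalue,
    quadratic_effect,
    regression_table,
    standardized_regression,
)


def naive_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = (sum((a - mx) ** 2 for a in x) / n) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / n) ** 0.5
    return cov / (sx * sy)


def naive_quadratic(x, y):
    """Explicit normal-equation solves for both hierarchy levels."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def r2(design):
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        resid = y - design @ beta
        tss = np.sum((y - y.mean()) ** 2)
        return 1 - np.sum(resid**2) / tss, beta

    d1 = np.column_stack([np.ones_like(x), x])
    d2 = np.column_stack([np.ones_like(x), x, x**2])
    r2_1, _ = r2(d1)
    r2_2, beta2 = r2(d2)
    return np.sign(beta2[2]) * (r2_2 - r2_1)


class TestEffects:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert linear_effect(x, 2 * x + 1) == pytest.approx(1.0)
        assert linear_effect(x, -x) == pytest.approx(-1.0)

    def test_matches_naive_formula(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        assert linear_effect(x, y) == pytest.approx(naive_pearson(x, y), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            linear_effect(np.ones(10), np.arange(10.0))

    def test_pure_negative_curvature_saturates(self):
        x = np.linspace(-3, 3, 31)  # symmetric about its mean
        y = -((x - x.mean()) ** 2)
        assert quadratic_effect(x, y) == pytest.approx(-1.0)

    def test_pure_linear_zero_increment(self):
        x = np.linspace(0, 10, 25)
        assert quadratic_effect(x, 3 * x) == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.uniform(18, 87, 40)
        y = rng.standard_normal(40)
        assert quadratic_effect(x, y) == pytest.approx(naive_quadratic(x, y), abs=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 5.0), b=st.floats(-10.0, 10.0),
        c=st.floats(-2.0, 2.0), seed=st.integers(0, 50),
    )
    def test_affine_rescaling_invariance(self, a, b, c, seed):
        # x -> a x + b spans the same design space, so the statistic is
        # unchanged; the incremental ESS (numerator) is also unchanged when a
        # linear-in-x component is added to y, although the R² ratio is not.
        r = np.random.default_rng(seed)
        x = r.uniform(0, 10, 30)
        y = r.standard_normal(30)
        base = quadratic_effect(x, y)
        assert quadratic_effect(a * x + b, y) == pytest.approx(base, abs=1e-8)
        shifted = y + c * x
        ess = abs(base) * np.sum((y - y.mean()) ** 2)
        ess_shifted = abs(quadratic_effect(x, shifted)) * np.sum(
            (shifted - shifted.mean()) ** 2
        )
        assert ess_shifted == pytest.approx(ess, abs=1e-6 * max(1.0, ess))


class TestPermutation:
    def test_add_one_rule_floor(self, rng):
        x = np.arange(50.0)
        y = 2 * x  # observed |r| = 1 beats every shuffle
        _, p = permutation_pvalue(
            linear_effect, x, y, PermutationScheme(999, seed=0)
        )
        assert p == pytest.approx(0.001)

    def test_null_statistic_p_near_one(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        xc = x - x.mean()
        y = y - xc * (xc @ y) / (xc @ xc)  # center-orthogonalize: r == 0
        obs, p = permutation_pvalue(
            linear_effect, x, y, PermutationScheme(200, seed=1)
        )
        assert abs(obs) < 1e-10
        assert p > 0.99

    def test_reproducible_per_seed(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        sch = PermutationScheme(100, seed=42)
        assert permutation_pvalue(linear_effect, x, y, sch) == \
            permutation_pvalue(linear_effect, x, y, sch)


def naive_bh(p):
    """Independent step-up: adjusted_(i) = min_{k>=i} p_(k) m / k, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = running
    return adj


class TestFDR:
    def test_constant_ratio_pool(self):
        np.testing.assert_allclose(
            fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_bh([0.3]), [0.3])

    def test_matches_step_up_oracle(self, rng):
        p = rng.uniform(0, 1, 100)
        np.testing.assert_allclose(fdr_bh(p), naive_bh(p), atol=1e-12)

    def test_pooled_by_key(self, rng):
        p = rng.uniform(0, 1, 40)
        keys = np.repeat(["a", "b"], 20)
        out = fdr_bh(p, keys)
        np.testing.assert_allclose(out[:20], naive_bh(p[:20]), atol=1e-12)
        np.testing.assert_allclose(out[20:], naive_bh(p[20:]), atol=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])


class TestMassUnivariate:
    def test_spectrum_level_unit_count(self, rng):
        y = rng.standard_normal((40, 32))
        x = rng.uniform(18, 87, 40)
        t = mass_univariate(y, x, PermutationScheme(50, seed=0))
        assert (t["kind"] == "linear").sum() == 32
        assert (t["kind"] == "quadratic").sum() == 32

    def test_effects_match_scalar_operations(self, rng):
        y = rng.standard_normal((60, 5))
        x = rng.uniform(18, 87, 60)
        t = mass_univariate(y, x, PermutationScheme(10, seed=0))
        for u in range(5):
            lin = t[(t.kind == "linear") & (t.unit == u)]["effect"].item()
            quad = t[(t.kind == "quadratic") & (t.unit == u)]["effect"].item()
            assert lin == pytest.approx(linear_effect(x, y[:, u]), abs=1e-10)
            assert quad == pytest.approx(quadratic_effect(x, y[:, u]), abs=1e-10)

    def test_missing_subject_dropped_with_warning(self, rng):
        y = rng.standard_normal((30, 3))
        y[4, 1] = np.nan
        x = rng.uniform(18, 87, 30)
        with pytest.warns(UserWarning, match="dropping"):
            t = mass_univariate(y, x, PermutationScheme(10, seed=0))
        assert (t["n"] == 29).all()


class TestBootstrap:
    def test_noiseless_identity_collapses(self, rng):
        x = rng.uniform(0, 1, 25)
        lo, hi = bootstrap_ci(linear_effect, x, x.copy(), n_boot=100, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_reproducible(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        assert bootstrap_ci(linear_effect, x, y, 200, seed=5) == \
            bootstrap_ci(linear_effect, x, y, 200, seed=5)

    def test_null_coverage_reduced(self):
        hits = 0
        reps = 40
        for rep in range(reps):
            r = np.random.default_rng(1000 + rep)
            x = r.standard_normal(40)
            y = r.standard_normal(40)
            lo, hi = bootstrap_ci(linear_effect, x, y, n_boot=200, seed=rep)
            hits += lo <= 0 <= hi
        assert hits / reps >= 0.85


class TestStandardizedRegression:
    def test_pure_age_effect(self, rng):
        age = rng.uniform(18, 87, 200)
        overcomp = rng.standard_normal(200)
        y = (age - age.mean()) / age.std()
        res = standardized_regression(y, age, overcomp)
        assert res["beta_age"] == pytest.approx(1.0, abs=0.02)
        assert res["beta_overcomp"] == pytest.approx(0.0, abs=0.05)

    def test_two_predictor_closed_form(self, rng):
        age = rng.uniform(18, 87, 150)
        overcomp = 0.4 * (age - age.mean()) / age.std() + rng.standard_normal(150)
        y = rng.standard_normal(150) + 0.3 * age / age.std()
        res = standardized_regression(y, age, overcomp)
        z = lambda v: (v - v.mean()) / v.std()
        r_y1 = np.corrcoef(z(y), z(age))[0, 1]
        r_y2 = np.corrcoef(z(y), z(overcomp))[0, 1]
        r_12 = np.corrcoef(z(age), z(overcomp))[0, 1]
        expected = (r_y1 - r_y2 * r_12) / (1 - r_12**2)
        assert res["beta_age"] == pytest.approx(expected, abs=1e-10)

    def test_collinear_predictors_refused(self, rng):
        age = rng.uniform(18, 87, 50)
        with pytest.raises(CollinearityError, match="collinear"):
            standardized_regression(rng.standard_normal(50), age, age.copy())

    def test_regression_table_pools_both_predictors(self, rng):
        age = rng.uniform(18, 87, 80)
        overcomp = rng.standard_normal(80)
        y = rng.standard_normal((80, 4))
        table = regression_table(y, age, overcomp, region_labels=list("abcd"))
        assert len(table) == 8  # 4 regions x 2 predictors, one FDR pool
        np.testing.assert_allclose(
            table["p_fdr"].to_numpy(), naive_bh(table["p"].to_numpy()), atol=1e-12
        )


class TestOverAndAbove:
    def _table(self, units, effects, p_fdr):
        return pd.DataFrame(
            {"unit": units, "kind": "linear", "effect": effects,
             "p_perm": p_fdr, "p_fdr": p_fdr, "n": 100}
        )

    def test_flagging_rules(self):
        beh = self._table(["r1", "r2"], [-0.3, -0.1], [0.01, 0.01])
        age = self._table(["r1", "r2"], [-0.1, -0.3], [0.01, 0.01])
        out = over_and_above(beh, age).set_index("unit")
        assert bool(out.loc["r1", "flagged"]) is True
        assert bool(out.loc["r2", "flagged"]) is False

    def test_insignificant_behavior_never_flagged(self):
        beh = self._table(["r1"], [-0.5], [0.2])
        age = self._table(["r1"], [-0.1], [0.5])
        assert not over_and_above(beh, age)["flagged"].any()

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError, match="region sets"):
            over_and_above(self._table(["r1"], [0.1], [0.01]),
                           self._table(["r2"], [0.1], [0.01]))


class TestOutliers:
    def test_single_extreme_point_masked(self, rng):
        v = rng.standard_normal(100)
        v[17] = 30.0
        mask = exclude_outliers(v)
        assert not mask[17]
        assert mask.sum() == 99

    def test_no_outliers_identity(self, rng):
        v = rng.uniform(0, 1, 50)
        assert exclude_outliers(v).all()

    def test_reanalysis_stable_after_injection(self, rng):
        age = rng.uniform(18, 87, 120)
        y = 0.01 * age + 0.2 * rng.standard_normal(120)
        clean_r = linear_effect(age, y)
        y_dirty = y.copy()
        y_dirty[3] += 25.0
        mask = exclude_outliers(y_dirty)
        r_masked = linear_effect(age[mask], y_dirty[mask])
        assert abs(r_masked - clean_r) < 0.05
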