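"""Mass-univariate association statistics with permutation nulls.

Linear and quadratic associations between age (or a behavioral variable) and
an outcome are modeled by hierarchical linear regression: a first-level fit
with the predictor alone, then a second level adding the squared predictor.
Effect sizes are the Pearson correlation (linear) and the incremental
coefficient of determination signed by the quadratic coefficient,
``sign(β_x²) · (R²_level2 − R²_level1)`` — a negative value is the
"inverted-U" lifespan signature.  Significance comes from a two-tailed
permutation test that shuffles the dependent variable while keeping the
predictors fixed (default 1000 permutations, add-one p estimator), and
multiple comparisons are corrected with Benjamini–Hochberg FDR within the
appropriate pool (across connections or regions within a frequency band;
across frequency bins for whole-network spectra).

A standardized multiple regression (z-scored outcome ~ z-scored age +
z-scored overcompensation) separates age-related from behavioral effects at
the region level, with a collinearity guard (|corr| < 0.7 between
predictors) and parametric two-tailed coefficient tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationScheme",
    "CollinearityError",
    "linear_effect",
    "quadratic_effect",
    "permutation_pvalue",
    "fdr_bh",
    "mass_univariate",
    "bootstrap_ci",
    "standardized_regression",
    "regression_table",
    "over_and_above",
    "exclude_outliers",
]


class CollinearityError(ValueError):
    """Raised when regression predictors are too strongly correlated."""


@dataclass(frozen=True)
class PermutationScheme:
    """Permutation-test settings: number of shuffles, seed, tail convention."""

    n_permutations: int = 1000
    seed: int = 0
    two_tailed: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be ≥ 1")


def linear_effect(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation between predictor and outcome."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined correlation")
    return float(np.corrcoef(x, y)[0, 1])


def quadratic_effect(x: np.ndarray, y: np.ndarray) -> float:
    """Signed incremental R² of the quadratic term.

    Level 1 regresses y on (1, x); level 2 on (1, x, x²).  The statistic is
    ``sign(β_x²) · (R²_2 − R²_1)``: the variance explained beyond the linear
    trend, signed by the curvature.  Invariant to affine rescaling of x and
    to adding any linear-in-x component to y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct x values")
    xc = (x - x.mean()) / x.std()  # condition the design
    d2 = np.column_stack([np.ones_like(xc), xc, xc**2])
    if np.linalg.matrix_rank(d2) < 3:
        raise ValueError("rank-deficient quadratic design")
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("constant outcome")
    q1, _ = np.linalg.qr(d2[:, :2])
    q2, r2 = np.linalg.qr(d2)
    ess1 = float(np.sum((q1.T @ y) ** 2)) - x.size * y.mean() ** 2
    proj2 = q2.T @ y
    ess2 = float(np.sum(proj2**2)) - x.size * y.mean() ** 2
    beta = np.linalg.solve(r2, proj2)
    return float(np.sign(beta[2]) * (ess2 - ess1) / tss)


def permutation_pvalue(
    stat_fn, x: np.ndarray, y: np.ndarray, scheme: PermutationScheme
) -> tuple[float, float]:
    """Two-tailed permutation p for ``stat_fn(x, y)`` under shuffles of y.

    Returns (observed statistic, p).  p uses the add-one estimator
    ``(#{|stat_perm| ≥ |stat_obs|} + 1) / (n_permutations + 1)`` so p is never
    exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = stat_fn(x, y)
    rng = np.random.default_rng(scheme.seed)
    count = 0
    for _ in range(scheme.n_permutations):
        perm = stat_fn(x, rng.permutation(y))
        extreme = abs(perm) >= abs(obs) if scheme.two_tailed else perm >= obs
        count += bool(extreme)
    return float(obs), (count + 1) / (scheme.n_permutations + 1)


def fdr_bh(p_values, pooling_key=None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values.

    With ``pooling_key`` (one key per p value) the adjustment is applied
    separately within each pool; otherwise all p values form one pool.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value pool")
    if pooling_key is None:
        return multipletests(p, method="fdr_bh")[1]
    keys = np.asarray(pooling_key)
    out = np.empty_like(p)
    for key in np.unique(keys):
        sel = keys == key
        out[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return out


def _perm_index_matrix(n: int, scheme: PermutationScheme) -> np.ndarray:
    """Shared shuffled index sets, (n_permutations, n); one set per seed."""
    rng = np.random.default_rng(scheme.seed)
    return np.array([rng.permutation(n) for _ in range(scheme.n_permutations)])


def mass_univariate(
    outcomes: np.ndarray,
    x: np.ndarray,
    scheme: PermutationScheme,
    unit_ids=None,
    kinds: tuple = ("linear", "quadratic"),
) -> pd.DataFrame:
    """Separate hierarchical regression per unit, with a pooled FDR correction.

    Parameters
    ----------
    outcomes
        (n_subjects, n_units) stack — one column per connection, region, or
        frequency bin.  All units passed in one call form one FDR pool (per
        effect kind), so callers should pass exactly the units that the
        analysis level pools: connections or regions of one frequency band,
        or the frequency bins of a whole-network spectrum.
    x
        Predictor (e.g. age), (n_subjects,).
    scheme
        Permutation settings; the same shuffled index sets are reused across
        units within one call.

    Subjects with a missing outcome in any unit are dropped with a warning;
    the retained n is recorded per row.

    Returns
    -------
    Tidy DataFrame: unit, kind, effect, p_perm, p_fdr, n.
    """
    Y = np.atleast_2d(np.asarray(outcomes, dtype=float))
    if Y.ndim != 2:
        raise ValueError("outcomes must be (n_subjects, n_units)")
    x = np.asarray(x, dtype=float)
    if Y.shape[0] != x.size:
        raise ValueError("outcomes and x must align on subjects")
    keep = np.isfinite(Y).all(axis=1) & np.isfinite(x)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} subject(s) with missing outcomes"
        )
    Y, x = Y[keep], x[keep]
    n, n_units = Y.shape
    if unit_ids is None:
        unit_ids = list(range(n_units))

    xz = (x - x.mean()) / x.std()
    d2 = np.column_stack([np.ones(n), xz, xz**2])
    q1, _ = np.linalg.qr(d2[:, :2])
    q2, r2 = np.linalg.qr(d2)

    ymean = Y.mean(axis=0)
    yz_sd = Y.std(axis=0)
    if np.any(yz_sd == 0):
        raise ValueError("constant outcome column")
    tss = (yz_sd**2) * n

    def _stats(Ymat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(linear r, signed incremental R²) for every column of Ymat."""
        g1 = q1.T @ Ymat  # (2, units)
        g2 = q2.T @ Ymat  # (3, units)
        ess1 = (g1**2).sum(axis=0) - n * ymean**2
        ess2 = (g2**2).sum(axis=0) - n * ymean**2
        beta = np.linalg.solve(r2, g2)
        r_lin = (xz @ Ymat) / (n * yz_sd)
        quad = np.sign(beta[2]) * (ess2 - ess1) / tss
        return r_lin, quad

    obs_lin, obs_quad = _stats(Y)
    idx = _perm_index_matrix(n, scheme)
    count_lin = np.zeros(n_units)
    count_quad = np.zeros(n_units)
    for p in range(scheme.n_permutations):
        perm_lin, perm_quad = _stats(Y[idx[p]])
        if scheme.two_tailed:
            count_lin += np.abs(perm_lin) >= np.abs(obs_lin)
            count_quad += np.abs(perm_quad) >= np.abs(obs_quad)
        else:
            count_lin += perm_lin >= obs_lin
            count_quad += perm_quad >= obs_quad
    p_lin = (count_lin + 1) / (scheme.n_permutations + 1)
    p_quad = (count_quad + 1) / (scheme.n_permutations + 1)

    frames = []
    if "linear" in kinds:
        frames.append(
            pd.DataFrame(
                {"unit": unit_ids, "kind": "linear", "effect": obs_lin,
                 "p_perm": p_lin, "p_fdr": fdr_bh(p_lin), "n": n}
            )
        )
    if "quadratic" in kinds:
        frames.append(
            pd.DataFrame(
                {"unit": unit_ids, "kind": "quadratic", "effect": obs_quad,
                 "p_perm": p_quad, "p_fdr": fdr_bh(p_quad), "n": n}
            )
        )
    return pd.concat(frames, ignore_index=True)


def bootstrap_ci(
    stat_fn,
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for ``stat_fn(x, y)``.

    Subjects are resampled with replacement; resamples on which the statistic
    is undefined are redrawn (bounded retries).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    max_attempts = 50 * n_boot
    attempts = 0
    b = 0
    while b < n_boot:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("bootstrap: persistent degenerate resamples")
        idx = rng.integers(0, x.size, size=x.size)
        try:
            s = stat_fn(x[idx], y[idx])
        except ValueError:
            continue
        if not np.isfinite(s):
            continue
        stats[b] = s
        b += 1
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def standardized_regression(
    y: np.ndarray, age: np.ndarray, overcomp: np.ndarray,
    collinearity_bound: float = 0.7,
) -> dict:
    """OLS of z-scored outcome on z-scored age and overcompensation.

    Refuses to fit when |corr(age, overcomp)| ≥ the collinearity bound.
    Coefficient p values are parametric two-tailed t-tests.
    """
    import statsmodels.api as sm

    r12 = float(np.corrcoef(age, overcomp)[0, 1])
    if abs(r12) >= collinearity_bound:
        raise CollinearityError(
            f"predictors too collinear: |corr(age, overcomp)| = {abs(r12):.3f} "
            f"≥ {collinearity_bound}"
        )
    z = lambda v: (v - np.mean(v)) / np.std(v)
    design = sm.add_constant(np.column_stack([z(age), z(overcomp)]))
    fit = sm.OLS(z(y), design).fit()
    return {
        "beta_age": float(fit.params[1]),
        "beta_overcomp": float(fit.params[2]),
        "p_age": float(fit.pvalues[1]),
        "p_overcomp": float(fit.pvalues[2]),
        "r12": r12,
        "n": int(len(y)),
    }


def regression_table(
    region_outcomes: np.ndarray, age: np.ndarray, overcomp: np.ndarray,
    region_labels=None, collinearity_bound: float = 0.7,
) -> pd.DataFrame:
    """Standardized multiple regression per region, FDR over all regions.

    The FDR pool contains the p values of both predictors across all regions.
    Subjects missing the behavioral value are dropped first.
    """
    Y = np.atleast_2d(np.asarray(region_outcomes, dtype=float))
    keep = np.isfinite(np.asarray(overcomp, dtype=float))
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} subject(s) without behavior")
    Y, age, overcomp = Y[keep], np.asarray(age)[keep], np.asarray(overcomp)[keep]
    if region_labels is None:
        region_labels = list(range(Y.shape[1]))
    rows = []
    for ri, label in enumerate(region_labels):
        res = standardized_regression(Y[:, ri], age, overcomp, collinearity_bound)
        rows.append((label, "age", res["beta_age"], res["p_age"], res["n"]))
        rows.append(
            (label, "overcomp", res["beta_overcomp"], res["p_overcomp"], res["n"])
        )
    table = pd.DataFrame(rows, columns=["region", "predictor", "beta", "p", "n"])
    table["p_fdr"] = fdr_bh(table["p"].to_numpy())
    return table


def over_and_above(
    assoc_behavior: pd.DataFrame, assoc_age: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Regions where the behavioral association dominates the age association.

    A region is flagged iff its behavior association is FDR-significant and
    |effect_behavior| > |effect_age|.  Both tables must cover the same
    regions (column ``unit``) with one row per region.
    """
    b = assoc_behavior.set_index("unit")
    a = assoc_age.set_index("unit")
    if set(b.index) != set(a.index):
        raise ValueError("region sets differ between the two association tables")
    a = a.reindex(b.index)
    flagged = (b["p_fdr"] < alpha) & (b["effect"].abs() > a["effect"].abs())
    return pd.DataFrame(
        {"unit": b.index, "flagged": flagged.to_numpy(),
         "effect_behavior": b["effect"].to_numpy(),
         "effect_age": a["effect"].to_numpy()}
    ).reset_index(drop=True)


def exclude_outliers(values: np.ndarray, sd_factor: float = 3.0) -> np.ndarray:
    """Inclusion mask: False for values more than ``sd_factor`` SDs from the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 values")
    mask = np.abs(v - v.mean()) <= sd_factor * v.std()
    if not mask.any():
        raise ValueError("outlier rule excluded every value")
    return mask
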