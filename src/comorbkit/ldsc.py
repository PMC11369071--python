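"""LD-score regression: SNP heritability and cross-trait genetic correlation.

Under polygenicity the expected association chi-square of a variant rises
linearly in its LD score l (the sum of squared correlations with nearby
variants): E[chi^2_j] = intercept + N h^2 l_j / M.  Regressing chi^2 on l
therefore estimates the observed-scale SNP heritability from summary
statistics alone, with the intercept absorbing confounding; the analogous
regression of z1*z2 on l gives the genetic covariance of two traits, and
the genetic correlation is r_g = gencov / sqrt(h1^2 h2^2).  Standard
errors come from a delete-a-block jackknife over contiguous variant
blocks; case-control heritabilities are converted to the liability scale
from the population and sample prevalences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .liability import h2_observed_to_liability

__all__ = ["LdscOptions", "LdscFit", "ldsc_h2", "ldsc_rg"]


@dataclass
class LdscOptions:
    """Knobs shared by the univariate and bivariate regressions.

    ``M`` defaults to the number of regression variants.  ``blocks`` is the
    jackknife block count (200 standard; drop toward 20 for small
    simulated panels).  ``K``/``P`` (population/sample prevalence) enable
    the liability-scale conversion.  The intercept is free unless
    ``fix_intercept``.
    """

    M: int | None = None
    blocks: int = 200
    K: float | None = None
    P: float | None = None
    fix_intercept: bool = False
    unit_weights: bool = False  # plain OLS; mainly for cross-checks


@dataclass
class LdscFit:
    h2_obs: float
    h2_se: float
    intercept: float
    intercept_se: float
    M: int
    n_variants: int
    n_blocks: int
    h2_liab: float | None = None
    h2_liab_se: float | None = None
    gencov: float | None = None
    gencov_se: float | None = None
    rg: float | None = None
    rg_se: float | None = None
    rg_p: float | None = None
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if k != "extras"} | self.extras


def _wls(y: np.ndarray, ell: np.ndarray, w: np.ndarray, fix_intercept: float | None):
    """Weighted least squares of y on ell; returns (slope, intercept)."""
    sw = np.sqrt(w)
    if fix_intercept is None:
        X = np.column_stack([ell, np.ones_like(ell)])
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        return float(coef[0]), float(coef[1])
    slope = float(
        np.sum(w * ell * (y - fix_intercept)) / np.sum(w * ell * ell)
    )
    return slope, float(fix_intercept)


def _weights(ell: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Two-step LDSC weights: 1 / (l * max(1, E[chi^2])^2)."""
    return 1.0 / (np.clip(ell, 1.0, None) * np.clip(expected, 1.0, None) ** 2)


def _jackknife(values: np.ndarray) -> float:
    b = len(values)
    return float(np.sqrt((b - 1) / b * np.sum((values - values.mean()) ** 2)))


def _block_bounds(n: int, blocks: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, n, blocks + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(blocks)]


def _merge(ss: pd.DataFrame, ld: pd.DataFrame) -> pd.DataFrame:
    merged = ss.merge(ld, on="snp", how="inner")
    return merged


def _check_size(n: int, blocks: int) -> None:
    if n < 2 * blocks:
        raise ValueError(
            f"only {n} variants after merging; need at least {2 * blocks} for {blocks} blocks"
        )


def ldsc_h2(ss: pd.DataFrame, ld: pd.DataFrame, opts: LdscOptions | None = None) -> LdscFit:
    """SNP heritability by two-step weighted LD-score regression.

    ``ss`` needs columns ``snp``, ``z``, ``n``; ``ld`` needs ``snp``,
    ``l2``.  The slope of chi^2 = z^2 on l, times M/N, is the
    observed-scale h^2; the regression is run once with crude weights,
    then once with weights from the first-pass h^2.  Jackknife SEs come
    from delete-a-block re-estimation over contiguous blocks.  A negative
    fitted h^2 is reported as-is (flagged in ``extras``).
    """
    opts = opts or LdscOptions()
    d = _merge(ss, ld)
    _check_size(len(d), opts.blocks)
    ell = d["l2"].to_numpy(dtype=float)
    chi2 = d["z"].to_numpy(dtype=float) ** 2
    N = d["n"].to_numpy(dtype=float)
    Nbar = float(N.mean())
    M = opts.M or len(d)
    fix = 1.0 if opts.fix_intercept else None

    if opts.unit_weights:
        w = np.ones_like(ell)
    else:
        w0 = _weights(ell, np.ones_like(ell))
        slope0, _ = _wls(chi2, ell * N / Nbar, w0, fix)
        h2_0 = np.clip(slope0 * M / Nbar, 0.0, 2.0)
        w = _weights(ell, 1.0 + Nbar * h2_0 * ell / M)

    def estimate(mask: np.ndarray) -> tuple[float, float]:
        s, i = _wls(chi2[mask], (ell * N / Nbar)[mask], w[mask], fix)
        return s * M / Nbar, i

    full_mask = np.ones(len(d), dtype=bool)
    h2_full, int_full = estimate(full_mask)

    h2_del, int_del = [], []
    for lo, hi in _block_bounds(len(d), opts.blocks):
        m = full_mask.copy()
        m[lo:hi] = False
        h2_b, int_b = estimate(m)
        h2_del.append(h2_b)
        int_del.append(int_b)
    h2_se = _jackknife(np.array(h2_del))
    int_se = _jackknife(np.array(int_del))

    fit = LdscFit(
        h2_obs=h2_full, h2_se=h2_se,
        intercept=int_full, intercept_se=int_se,
        M=int(M), n_variants=len(d), n_blocks=opts.blocks,
    )
    if h2_full < 0:
        fit.extras["negative_h2_warning"] = True
    if opts.K is not None and opts.P is not None:
        factor = h2_observed_to_liability(1.0, opts.K, opts.P)
        fit.h2_liab = h2_full * factor
        fit.h2_liab_se = h2_se * factor
    return fit


def ldsc_rg(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    ld: pd.DataFrame,
    opts: LdscOptions | None = None,
    n_tests: int | None = None,
) -> LdscFit:
    """Genetic correlation by cross-trait LD-score regression.

    Traits are merged on variant id with allele harmonization: where
    trait 2 reports the swapped allele pair its z is sign-flipped;
    variants with irreconcilable alleles are dropped.  The z1*z2 slope
    gives the genetic covariance; r_g divides by the per-trait
    heritabilities, and the jackknife re-estimates the full ratio per
    deleted block.  ``n_tests`` adds a Bonferroni-adjusted significance
    flag at level 0.05 / n_tests.
    """
    opts = opts or LdscOptions()
    m = ss1.merge(ss2, on="snp", suffixes=("_1", "_2"))
    if {"a1_1", "a2_1", "a1_2", "a2_2"} <= set(m.columns):
        same = (m["a1_1"] == m["a1_2"]) & (m["a2_1"] == m["a2_2"])
        swapped = (m["a1_1"] == m["a2_2"]) & (m["a2_1"] == m["a1_2"])
        keep = same | swapped
        m = m[keep].copy()
        flip = swapped[keep].to_numpy()
        m["z_2"] = np.where(flip, -m["z_2"].to_numpy(), m["z_2"].to_numpy())
    d = _merge(m, ld)
    _check_size(len(d), opts.blocks)

    ell = d["l2"].to_numpy(dtype=float)
    z1 = d["z_1"].to_numpy(dtype=float)
    z2 = d["z_2"].to_numpy(dtype=float)
    N1 = d["n_1"].to_numpy(dtype=float)
    N2 = d["n_2"].to_numpy(dtype=float)
    N1bar, N2bar = float(N1.mean()), float(N2.mean())
    M = opts.M or len(d)
    fix_h2 = 1.0 if opts.fix_intercept else None
    fix_x = 0.0 if opts.fix_intercept else None

    # first-pass heritabilities for the weights
    w0 = _weights(ell, np.ones_like(ell))
    s1, _ = _wls(z1**2, ell * N1 / N1bar, w0, fix_h2)
    s2, _ = _wls(z2**2, ell * N2 / N2bar, w0, fix_h2)
    h1_0 = np.clip(s1 * M / N1bar, 1e-6, 2.0)
    h2_0 = np.clip(s2 * M / N2bar, 1e-6, 2.0)
    w1 = _weights(ell, 1.0 + N1bar * h1_0 * ell / M)
    w2 = _weights(ell, 1.0 + N2bar * h2_0 * ell / M)
    wx = np.sqrt(w1 * w2)

    sqrtN = np.sqrt(N1 * N2)
    sqrtNbar = float(sqrtN.mean())

    def estimate(mask: np.ndarray) -> tuple[float, float, float, float]:
        sh1, _ = _wls(z1[mask] ** 2, (ell * N1 / N1bar)[mask], w1[mask], fix_h2)
        sh2, _ = _wls(z2[mask] ** 2, (ell * N2 / N2bar)[mask], w2[mask], fix_h2)
        sx, ix = _wls((z1 * z2)[mask], (ell * sqrtN / sqrtNbar)[mask], wx[mask], fix_x)
        h1 = sh1 * M / N1bar
        h2 = sh2 * M / N2bar
        gencov = sx * M / sqrtNbar
        denom = np.sqrt(max(h1 * h2, 1e-300))
        return gencov / denom, gencov, h1, h2

    full = np.ones(len(d), dtype=bool)
    rg_full, gencov_full, h1_full, h2_full = estimate(full)

    rg_del, gencov_del = [], []
    for lo, hi in _block_bounds(len(d), opts.blocks):
        msk = full.copy()
        msk[lo:hi] = False
        r_b, g_b, *_ = estimate(msk)
        rg_del.append(r_b)
        gencov_del.append(g_b)
    rg_se = _jackknife(np.array(rg_del))
    gencov_se = _jackknife(np.array(gencov_del))

    z_stat = rg_full / rg_se if rg_se > 0 else np.inf
    p = float(2.0 * norm.sf(abs(z_stat)))

    fit = LdscFit(
        h2_obs=h1_full, h2_se=np.nan,
        intercept=np.nan, intercept_se=np.nan,
        M=int(M), n_variants=len(d), n_blocks=opts.blocks,
        gencov=gencov_full, gencov_se=gencov_se,
        rg=rg_full, rg_se=rg_se, rg_p=p,
        extras={"h2_obs_trait2": h2_full},
    )
    if n_tests is not None:
        alpha = 0.05 / n_tests
        fit.extras["bonferroni_alpha"] = alpha
        fit.extras["significant_after_bonferroni"] = bool(p < alpha)
    return fit
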