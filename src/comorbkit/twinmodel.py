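"""Liability-threshold twin variance-component models (ACE/ADE/AE/CE/E).

The classical twin design contrasts monozygotic (MZ) and dizygotic (DZ)
pairs: MZ twins share 100% of additive genetic (A) and dominance (D)
variance, DZ twins 50% and 25%; shared environment (C) is common to both
members of either kind of pair, unique environment (E) to neither.  For a
binary trait the model operates on the liability scale — a pair's latent
liabilities are bivariate normal with the zygosity-implied correlation and
a prevalence-determined threshold — so the likelihood is a multinomial over
orthant cells.  Bivariate models use the correlated-factors
parameterization: per-trait variance proportions plus cross-trait factor
correlations r_a, r_c (or r_d), r_e, and a 4-dimensional orthant
likelihood over the 16 joint cells.

Estimation is maximum likelihood on unconstrained transforms (softmax over
variance proportions, atanh for correlations) with seeded random restarts;
Wald confidence intervals come from the numerical Hessian by the delta
method on the natural scale and are deliberately left untruncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from .liability import bvn_upper, cell_probabilities, upper_orthant_batch

__all__ = [
    "VarianceComponents",
    "CrossTraitCorrelations",
    "ModelFit",
    "expected_structure",
    "expected_univariate_counts",
    "expected_bivariate_counts",
    "univariate_counts_from_pairs",
    "bivariate_counts_from_pairs",
    "fit_univariate",
    "fit_bivariate",
    "model_select",
    "likelihood_ratio_test",
]

_FAMILIES = ("ACE", "ADE", "AE", "CE", "E")
_Z95 = 1.959963984540054


@dataclass
class VarianceComponents:
    """Proportions of liability variance (sum to one)."""

    a2: float
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 0.0
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)

    @property
    def h2(self) -> float:
        """Narrow-sense heritability."""
        return self.a2

    @property
    def H(self) -> float:
        """Broad-sense heritability, A + D."""
        return self.a2 + self.d2

    def as_dict(self) -> dict:
        return {
            "a2": self.a2, "c2": self.c2, "d2": self.d2, "e2": self.e2,
            "h2": self.h2, "H": self.H, "se": self.se, "ci": self.ci,
        }


@dataclass
class CrossTraitCorrelations:
    """Correlations between the trait-specific A, C/D, E factors."""

    r_a: float = 0.0
    r_c: float = 0.0
    r_d: float = 0.0
    r_e: float = 0.0
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "r_a": self.r_a, "r_c": self.r_c, "r_d": self.r_d, "r_e": self.r_e,
            "se": self.se, "ci": self.ci,
        }


@dataclass
class ModelFit:
    family: str
    log_likelihood: float
    n_params: int
    thresholds: dict = field(default_factory=dict)
    covariate_coefs: dict = field(default_factory=dict)
    converged: bool = True
    n_restarts_used: int = 0
    message: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.log_likelihood + 2.0 * self.n_params


def _check_family(family: str) -> str:
    family = family.upper()
    if family not in _FAMILIES:
        raise ValueError(f"unknown model family {family!r}; choose from {_FAMILIES}")
    return family


def _twin_r(comp: VarianceComponents, zygosity: str) -> float:
    if zygosity == "MZ":
        return comp.a2 + comp.c2 + comp.d2
    if zygosity == "DZ":
        return 0.5 * comp.a2 + comp.c2 + 0.25 * comp.d2
    raise ValueError(f"unknown zygosity {zygosity!r}")


def expected_structure(
    components: VarianceComponents | tuple,
    cross: CrossTraitCorrelations | None = None,
    zygosity: str = "MZ",
) -> np.ndarray:
    """Model-implied liability correlation matrix for one zygosity group.

    Univariate (``cross`` is None): the 2x2 cross-twin matrix with
    off-diagonal a2+c2+d2 (MZ) or a2/2+c2+d2/4 (DZ).  Bivariate:
    ``components`` is the per-trait pair and the 4x4 matrix is ordered
    (twin1-trait1, twin1-trait2, twin2-trait1, twin2-trait2), with
    within-person cross-trait correlation r_a*a1*a2 + r_c*c1*c2 + r_d*d1*d2
    + r_e*e1*e2 and the cross-twin cross-trait entries sharing A (and D)
    according to zygosity but never E.
    """
    if cross is None:
        if isinstance(components, tuple):
            raise ValueError("univariate structure takes a single VarianceComponents")
        rz = _twin_r(components, zygosity)
        return np.array([[1.0, rz], [rz, 1.0]])

    comp1, comp2 = components
    share_a = 1.0 if zygosity == "MZ" else 0.5
    share_d = 1.0 if zygosity == "MZ" else 0.25
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"unknown zygosity {zygosity!r}")
    a1, a2_ = np.sqrt(comp1.a2), np.sqrt(comp2.a2)
    c1, c2_ = np.sqrt(comp1.c2), np.sqrt(comp2.c2)
    d1, d2_ = np.sqrt(comp1.d2), np.sqrt(comp2.d2)
    e1, e2_ = np.sqrt(comp1.e2), np.sqrt(comp2.e2)
    r_within = (
        cross.r_a * a1 * a2_ + cross.r_c * c1 * c2_
        + cross.r_d * d1 * d2_ + cross.r_e * e1 * e2_
    )
    r_cross = (
        share_a * cross.r_a * a1 * a2_ + cross.r_c * c1 * c2_
        + share_d * cross.r_d * d1 * d2_
    )
    rz1 = _twin_r(comp1, zygosity)
    rz2 = _twin_r(comp2, zygosity)
    m = np.array(
        [
            [1.0, r_within, rz1, r_cross],
            [r_within, 1.0, r_cross, rz2],
            [rz1, r_cross, 1.0, r_within],
            [r_cross, rz2, r_within, 1.0],
        ]
    )
    if np.linalg.eigvalsh(m).min() < -1e-8:
        raise ValueError("implied liability correlation matrix is not PSD")
    return m


# ---------------------------------------------------------------------------
# expected-count and observed-count tables
# ---------------------------------------------------------------------------

def _univariate_cell_probs(r: float, t: float) -> np.ndarray:
    """Exchangeable 3-cell probabilities: both affected, exactly one, neither."""
    p11 = float(bvn_upper(t, t, r))
    m = float(norm.sf(t))
    p1 = max(2.0 * (m - p11), 0.0)
    return np.array([p11, p1, max(1.0 - 2.0 * m + p11, 0.0)])


def expected_univariate_counts(
    components: VarianceComponents, K: float, n_pairs: Mapping[str, float]
) -> dict:
    """Exact expected 3-cell counts per zygosity under the model; the
    oracle input for parameter-recovery tests."""
    t = float(norm.isf(K))
    return {
        z: n_pairs[z] * _univariate_cell_probs(_twin_r(components, z), t)
        for z in ("MZ", "DZ")
    }


def expected_bivariate_counts(
    comp1: VarianceComponents,
    comp2: VarianceComponents,
    cross: CrossTraitCorrelations,
    K1: float,
    K2: float,
    n_pairs: Mapping[str, float],
) -> dict:
    """Exact expected 16-cell counts per zygosity (flattened C-order over
    the pattern (twin1-trait1, twin1-trait2, twin2-trait1, twin2-trait2))."""
    t1, t2 = float(norm.isf(K1)), float(norm.isf(K2))
    out = {}
    for z in ("MZ", "DZ"):
        corr = expected_structure((comp1, comp2), cross, z)
        cells = cell_probabilities([t1, t2, t1, t2], corr)
        out[z] = n_pairs[z] * cells.reshape(-1)
    return out


def univariate_counts_from_pairs(pairs: pd.DataFrame, trait: str) -> dict:
    """Collapse a twin-pair table to per-zygosity exchangeable 3-cell counts."""
    out = {}
    for z, g in pairs.groupby("zygosity"):
        s = g[f"{trait}_1"].astype(int) + g[f"{trait}_2"].astype(int)
        out[z] = np.array([(s == 2).sum(), (s == 1).sum(), (s == 0).sum()], dtype=float)
    return out


def bivariate_counts_from_pairs(pairs: pd.DataFrame, trait1: str, trait2: str) -> dict:
    """Collapse a twin-pair table to per-zygosity 16-cell counts."""
    out = {}
    for z, g in pairs.groupby("zygosity"):
        idx = (
            8 * g[f"{trait1}_1"].astype(int)
            + 4 * g[f"{trait2}_1"].astype(int)
            + 2 * g[f"{trait1}_2"].astype(int)
            + g[f"{trait2}_2"].astype(int)
        )
        out[z] = np.bincount(idx, minlength=16).astype(float)
    return out


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

def _family_props(family: str, u: np.ndarray) -> tuple[float, float, float, float]:
    """Map unconstrained params to (a2, c2, d2, e2) via softmax."""
    if family == "ACE":
        w = np.exp(np.clip([u[0], u[1], 0.0], -700, 700))
        a2, c2, e2 = w / w.sum()
        return a2, c2, 0.0, e2
    if family == "ADE":
        w = np.exp(np.clip([u[0], u[1], 0.0], -700, 700))
        a2, d2, e2 = w / w.sum()
        return a2, 0.0, d2, e2
    if family == "AE":
        a2 = 1.0 / (1.0 + np.exp(-np.clip(u[0], -700, 700)))
        return a2, 0.0, 0.0, 1.0 - a2
    if family == "CE":
        c2 = 1.0 / (1.0 + np.exp(-np.clip(u[0], -700, 700)))
        return 0.0, c2, 0.0, 1.0 - c2
    return 0.0, 0.0, 0.0, 1.0  # E


def _n_var_params(family: str) -> int:
    return {"ACE": 2, "ADE": 2, "AE": 1, "CE": 1, "E": 0}[family]


def _cross_names(family: str) -> list[str]:
    if family == "ACE":
        return ["r_a", "r_c", "r_e"]
    if family == "ADE":
        return ["r_a", "r_d", "r_e"]
    if family == "AE":
        return ["r_a", "r_e"]
    if family == "CE":
        return ["r_c", "r_e"]
    return ["r_e"]


# ---------------------------------------------------------------------------
# univariate fit
# ---------------------------------------------------------------------------

def _resolve_covariate_matrix(
    df: pd.DataFrame, covariates: list[str], twin: int
) -> np.ndarray:
    cols = []
    for c in covariates:
        col = f"{c}_{twin}" if f"{c}_{twin}" in df.columns else c
        cols.append(df[col].to_numpy(dtype=float))
    return np.column_stack(cols)


def _univariate_negloglik_counts(theta, family, counts):
    t = theta[0]
    a2, c2, d2, e2 = _family_props(family, theta[1:])
    comp = VarianceComponents(a2, c2, d2, e2)
    nll = 0.0
    for z, c in counts.items():
        p = np.clip(_univariate_cell_probs(_twin_r(comp, z), t), 1e-300, 1.0)
        nll -= float(c @ np.log(p))
    return nll


def _univariate_negloglik_pairs(theta, family, grouped, n_cov):
    t0 = theta[0]
    beta = theta[1 : 1 + n_cov]
    a2, c2, d2, e2 = _family_props(family, theta[1 + n_cov :])
    comp = VarianceComponents(a2, c2, d2, e2)
    nll = 0.0
    for z, (y1, y2, x1, x2) in grouped.items():
        rz = _twin_r(comp, z)
        corr = np.array([[1.0, rz], [rz, 1.0]])
        th1 = t0 - x1 @ beta
        th2 = t0 - x2 @ beta
        p11 = upper_orthant_batch(np.column_stack([th1, th2]), corr)
        m1 = norm.sf(th1)
        m2 = norm.sf(th2)
        p = np.where(
            y1 & y2, p11,
            np.where(
                y1 & ~y2, m1 - p11,
                np.where(~y1 & y2, m2 - p11, 1.0 - m1 - m2 + p11),
            ),
        )
        nll -= float(np.sum(np.log(np.clip(p, 1e-300, 1.0))))
    return nll


def _numerical_hessian(f, x, step=1e-5):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ej = np.zeros(n)
            ei[i] = step; ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step * step)
    return H


def _delta_method(natural_of_theta, theta_hat, cov_theta, step=1e-6):
    """SEs and Wald CIs of natural-scale parameters via a numerical Jacobian."""
    base = np.asarray(natural_of_theta(theta_hat), dtype=float)
    J = np.empty((len(base), len(theta_hat)))
    for j in range(len(theta_hat)):
        e = np.zeros(len(theta_hat)); e[j] = step
        J[:, j] = (
            np.asarray(natural_of_theta(theta_hat + e))
            - np.asarray(natural_of_theta(theta_hat - e))
        ) / (2 * step)
    var = np.einsum("ij,jk,ik->i", J, cov_theta, J)
    se = np.sqrt(np.clip(var, 0.0, None))
    return base, se


def _minimize_restarts(nll, x0, n_restarts, seed, scale=1.0):
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(scale=scale, size=len(x0)) for _ in range(n_restarts)]
    best = None
    used = 0
    for s in starts:
        res = optimize.minimize(nll, s, method="L-BFGS-B")
        used += 1
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("twin model optimization failed to produce a finite likelihood")
    return best, used


def fit_univariate(
    data,
    family: str,
    trait: str | None = None,
    covariates: list[str] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[VarianceComponents, ModelFit]:
    """Fit a univariate liability-threshold variance-component model by ML.

    ``data`` is either a twin-pair DataFrame (columns ``zygosity``,
    ``<trait>_1``, ``<trait>_2`` and optional covariates) or a mapping
    ``{"MZ": counts, "DZ": counts}`` of exchangeable 3-cell counts
    (both affected, exactly one, neither); expected (non-integer) counts
    are accepted, which is how the parameter-recovery oracles enter.
    Without covariates the likelihood is the per-zygosity 3-cell
    multinomial; with covariates each pair contributes a bivariate orthant
    probability with thresholds linear in its covariates (probit scale).
    """
    family = _check_family(family)
    covariates = covariates or []

    if isinstance(data, pd.DataFrame):
        if trait is None:
            raise ValueError("trait column name required with a pair table")
        zyg = set(data["zygosity"].unique())
        if not {"MZ", "DZ"} <= zyg:
            raise ValueError("both MZ and DZ pairs are required")
        if not covariates:
            counts = univariate_counts_from_pairs(data, trait)
            return _fit_univariate_counts(family, counts, n_restarts, seed)
        grouped = {}
        for z, g in data.groupby("zygosity"):
            grouped[z] = (
                g[f"{trait}_1"].to_numpy(dtype=bool),
                g[f"{trait}_2"].to_numpy(dtype=bool),
                _resolve_covariate_matrix(g, covariates, 1),
                _resolve_covariate_matrix(g, covariates, 2),
            )
        return _fit_univariate_pairs(family, grouped, len(covariates), covariates, n_restarts, seed)

    counts = {z: np.asarray(v, dtype=float) for z, v in dict(data).items()}
    if not {"MZ", "DZ"} <= set(counts):
        raise ValueError("both MZ and DZ counts are required")
    return _fit_univariate_counts(family, counts, n_restarts, seed)


def _uni_start(family, counts):
    """Deterministic start: thresholds from prevalence, components from the
    MZ/DZ correlation contrast (Falconer-style)."""
    n_tot = sum(c.sum() for c in counts.values())
    n_aff = sum(2 * c[0] + c[1] for c in counts.values())
    K = min(max(n_aff / (2 * n_tot), 1e-4), 1 - 1e-4)
    t0 = float(norm.isf(K))
    u0 = np.zeros(_n_var_params(family))
    return np.concatenate([[t0], u0])


def _fit_univariate_counts(family, counts, n_restarts, seed):
    nll = lambda th: _univariate_negloglik_counts(th, family, counts)
    x0 = _uni_start(family, counts)
    res, used = _minimize_restarts(nll, x0, n_restarts, seed)
    return _package_univariate(family, res, used, nll, {}, [])


def _fit_univariate_pairs(family, grouped, n_cov, cov_names, n_restarts, seed):
    nll = lambda th: _univariate_negloglik_pairs(th, family, grouped, n_cov)
    n_tot = sum(len(g[0]) for g in grouped.values())
    n_aff = sum(g[0].sum() + g[1].sum() for g in grouped.values())
    K = min(max(n_aff / (2 * n_tot), 1e-4), 1 - 1e-4)
    x0 = np.concatenate([[norm.isf(K)], np.zeros(n_cov), np.zeros(_n_var_params(family))])
    res, used = _minimize_restarts(nll, x0, n_restarts, seed)
    return _package_univariate(family, res, used, nll, grouped, cov_names)


def _package_univariate(family, res, used, nll, grouped, cov_names):
    n_cov = len(cov_names)
    theta = res.x

    def natural(th):
        a2, c2, d2, e2 = _family_props(family, th[1 + n_cov :])
        return [a2, c2, d2, e2, th[0]]

    H = _numerical_hessian(nll, theta)
    se = np.full(5, np.nan)
    vals = np.asarray(natural(theta))
    try:
        cov_theta = np.linalg.inv(H)
        vals, se = _delta_method(natural, theta, cov_theta)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian; standard errors unavailable")

    names = ["a2", "c2", "d2", "e2"]
    comp = VarianceComponents(
        a2=float(vals[0]), c2=float(vals[1]), d2=float(vals[2]), e2=float(vals[3]),
        se={k: float(s) for k, s in zip(names, se[:4])},
        ci={
            k: (float(v - _Z95 * s), float(v + _Z95 * s))
            for k, v, s in zip(names, vals[:4], se[:4])
        },
    )
    fit = ModelFit(
        family=family,
        log_likelihood=-float(res.fun),
        n_params=1 + n_cov + _n_var_params(family),
        thresholds={"t": float(theta[0]), "se": float(se[4])},
        covariate_coefs={c: float(b) for c, b in zip(cov_names, theta[1 : 1 + n_cov])},
        converged=bool(res.success),
        n_restarts_used=used,
        message=str(res.message),
    )
    return comp, fit


# ---------------------------------------------------------------------------
# bivariate fit
# ---------------------------------------------------------------------------

def _bivar_unpack(theta, family):
    k = _n_var_params(family)
    t1, t2 = theta[0], theta[1]
    comp1 = VarianceComponents(*_family_props(family, theta[2 : 2 + k]))
    comp2 = VarianceComponents(*_family_props(family, theta[2 + k : 2 + 2 * k]))
    rs = np.tanh(theta[2 + 2 * k :])
    cross = CrossTraitCorrelations(**dict(zip(_cross_names(family), rs)))
    return t1, t2, comp1, comp2, cross


def _bivariate_negloglik_counts(theta, family, counts):
    t1, t2, comp1, comp2, cross = _bivar_unpack(theta, family)
    nll = 0.0
    for z, c in counts.items():
        try:
            corr = expected_structure((comp1, comp2), cross, z)
        except ValueError:
            return 1e12
        p = cell_probabilities([t1, t2, t1, t2], corr).reshape(-1)
        nll -= float(c @ np.log(np.clip(p, 1e-300, 1.0)))
    return nll


_PATTERN_BITS = np.array([[b >> 3 & 1, b >> 2 & 1, b >> 1 & 1, b & 1] for b in range(16)])


def _bivariate_negloglik_pairs(theta, family, grouped, n_cov):
    n_corr = len(_cross_names(theta_family := family))
    k = _n_var_params(family)
    base = theta[: 2 + 2 * k + n_corr]
    # covariate coefs shared across traits? independent per trait:
    b1 = theta[2 + 2 * k + n_corr : 2 + 2 * k + n_corr + n_cov]
    b2 = theta[2 + 2 * k + n_corr + n_cov :]
    t1, t2, comp1, comp2, cross = _bivar_unpack(base, family)
    nll = 0.0
    for z, (pattern_idx, x1, x2) in grouped.items():
        try:
            corr = expected_structure((comp1, comp2), cross, z)
        except ValueError:
            return 1e12
        th = np.column_stack(
            [t1 - x1 @ b1, t2 - x1 @ b2, t1 - x2 @ b1, t2 - x2 @ b2]
        )
        # Moebius over above-threshold subsets, batched per subset
        m = th.shape[0]
        uppers = {}
        for mask in range(1, 16):
            cols = [i for i in range(4) if mask >> (3 - i) & 1]
            sub = th[:, cols]
            uppers[mask] = upper_orthant_batch(sub, corr[np.ix_(cols, cols)])
        uppers[0] = np.ones(m)
        probs = np.zeros(m)
        cell_prob = {}
        for pat in range(16):
            rest = [i for i in range(4) if not pat >> (3 - i) & 1]
            p = np.zeros(m)
            for extra_mask in range(1 << len(rest)):
                extra = [rest[i] for i in range(len(rest)) if extra_mask >> i & 1]
                mask = pat
                for i in extra:
                    mask |= 1 << (3 - i)
                p += (-1) ** len(extra) * uppers[mask]
            cell_prob[pat] = np.clip(p, 1e-300, 1.0)
        probs = np.choose(pattern_idx, [cell_prob[pat] for pat in range(16)])
        nll -= float(np.sum(np.log(probs)))
    return nll


def fit_bivariate(
    data,
    family: str,
    traits: tuple[str, str] | None = None,
    covariates: list[str] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[tuple[VarianceComponents, VarianceComponents], CrossTraitCorrelations, ModelFit]:
    """Fit a bivariate correlated-factors liability model by ML.

    ``data`` is a twin-pair DataFrame (columns ``zygosity``,
    ``<trait>_<twin>`` for both traits) or per-zygosity 16-cell counts in
    C-order over (twin1-trait1, twin1-trait2, twin2-trait1, twin2-trait2).
    Wald CIs for the factor correlations are untruncated and may cross
    zero.
    """
    family = _check_family(family)
    covariates = covariates or []

    if isinstance(data, pd.DataFrame):
        if traits is None:
            raise ValueError("trait column names required with a pair table")
        if not covariates:
            counts = bivariate_counts_from_pairs(data, *traits)
            return _fit_bivariate_counts(family, counts, n_restarts, seed)
        grouped = {}
        for z, g in data.groupby("zygosity"):
            idx = (
                8 * g[f"{traits[0]}_1"].astype(int)
                + 4 * g[f"{traits[1]}_1"].astype(int)
                + 2 * g[f"{traits[0]}_2"].astype(int)
                + g[f"{traits[1]}_2"].astype(int)
            ).to_numpy()
            grouped[z] = (
                idx,
                _resolve_covariate_matrix(g, covariates, 1),
                _resolve_covariate_matrix(g, covariates, 2),
            )
        return _fit_bivariate_pairs(family, grouped, covariates, n_restarts, seed)

    counts = {z: np.asarray(v, dtype=float) for z, v in dict(data).items()}
    if not {"MZ", "DZ"} <= set(counts):
        raise ValueError("both MZ and DZ counts are required")
    return _fit_bivariate_counts(family, counts, n_restarts, seed)


def _bivar_start(family, counts):
    k1 = k2 = 0.0
    tot = 0.0
    for c in counts.values():
        c = c.reshape(2, 2, 2, 2)
        n = c.sum()
        tot += 2 * n
        k1 += c[1].sum() + c[:, :, 1].sum()
        k2 += c[:, 1].sum() + c[:, :, :, 1].sum()
    K1 = min(max(k1 / tot, 1e-4), 1 - 1e-4)
    K2 = min(max(k2 / tot, 1e-4), 1 - 1e-4)
    k = _n_var_params(family)
    n_corr = len(_cross_names(family))
    return np.concatenate([[norm.isf(K1), norm.isf(K2)], np.zeros(2 * k + n_corr)])


def _fit_bivariate_counts(family, counts, n_restarts, seed):
    nll = lambda th: _bivariate_negloglik_counts(th, family, counts)
    x0 = _bivar_start(family, counts)
    res, used = _minimize_restarts(nll, x0, n_restarts, seed, scale=0.5)
    return _package_bivariate(family, res, used, nll, 0, [])


def _fit_bivariate_pairs(family, grouped, cov_names, n_restarts, seed):
    n_cov = len(cov_names)
    nll = lambda th: _bivariate_negloglik_pairs(th, family, grouped, n_cov)
    counts = {
        z: np.bincount(idx, minlength=16).astype(float)
        for z, (idx, _, _) in grouped.items()
    }
    x0 = np.concatenate([_bivar_start(family, counts), np.zeros(2 * n_cov)])
    res, used = _minimize_restarts(nll, x0, n_restarts, seed, scale=0.5)
    return _package_bivariate(family, res, used, nll, n_cov, cov_names)


def _package_bivariate(family, res, used, nll, n_cov, cov_names):
    theta = res.x
    k = _n_var_params(family)
    n_corr = len(_cross_names(family))
    base_len = 2 + 2 * k + n_corr

    def natural(th):
        t1, t2, comp1, comp2, cross = _bivar_unpack(th[:base_len], family)
        return [
            comp1.a2, comp1.c2, comp1.d2, comp1.e2,
            comp2.a2, comp2.c2, comp2.d2, comp2.e2,
            cross.r_a, cross.r_c, cross.r_d, cross.r_e,
            t1, t2,
        ]

    H = _numerical_hessian(nll, theta)
    vals = np.asarray(natural(theta))
    se = np.full(14, np.nan)
    try:
        cov_theta = np.linalg.inv(H)
        vals, se = _delta_method(natural, theta, cov_theta)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian; standard errors unavailable")

    names = ["a2", "c2", "d2", "e2"]
    comps = []
    for off in (0, 4):
        comps.append(
            VarianceComponents(
                a2=float(vals[off]), c2=float(vals[off + 1]),
                d2=float(vals[off + 2]), e2=float(vals[off + 3]),
                se={n: float(s) for n, s in zip(names, se[off : off + 4])},
                ci={
                    n: (float(v - _Z95 * s), float(v + _Z95 * s))
                    for n, v, s in zip(names, vals[off : off + 4], se[off : off + 4])
                },
            )
        )
    rnames = ["r_a", "r_c", "r_d", "r_e"]
    cross = CrossTraitCorrelations(
        r_a=float(vals[8]), r_c=float(vals[9]), r_d=float(vals[10]), r_e=float(vals[11]),
        se={n: float(s) for n, s in zip(rnames, se[8:12])},
        ci={
            n: (float(v - _Z95 * s), float(v + _Z95 * s))
            for n, v, s in zip(rnames, vals[8:12], se[8:12])
        },
    )
    t_se = se[12:14]
    fit = ModelFit(
        family=family,
        log_likelihood=-float(res.fun),
        n_params=base_len + 2 * n_cov,
        thresholds={
            "t1": float(vals[12]), "t2": float(vals[13]),
            "se_t1": float(t_se[0]), "se_t2": float(t_se[1]),
        },
        covariate_coefs={
            f"{c}:trait{i+1}": float(b)
            for i in range(2)
            for c, b in zip(cov_names, theta[base_len + i * n_cov : base_len + (i + 1) * n_cov])
        },
        converged=bool(res.success),
        n_restarts_used=used,
        message=str(res.message),
    )
    return (comps[0], comps[1]), cross, fit


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

_NESTED = {
    ("AE", "ACE"), ("AE", "ADE"), ("CE", "ACE"),
    ("E", "AE"), ("E", "CE"), ("E", "ACE"), ("E", "ADE"),
}


def likelihood_ratio_test(restricted: ModelFit, full: ModelFit) -> dict:
    """Chi-square LRT of a nested pair of fits on the same data."""
    if (restricted.family, full.family) not in _NESTED:
        raise ValueError(
            f"{restricted.family} is not nested in {full.family}; valid pairs: {sorted(_NESTED)}"
        )
    df = full.n_params - restricted.n_params
    stat = max(2.0 * (full.log_likelihood - restricted.log_likelihood), 0.0)
    return {
        "restricted": restricted.family, "full": full.family,
        "statistic": stat, "df": df, "p_value": float(chi2.sf(stat, df)),
    }


def model_select(fits: list[ModelFit]) -> dict:
    """AIC ranking plus LRTs for every nested pair among the supplied fits."""
    by_family = {f.family: f for f in fits}
    table = sorted(
        ({"family": f.family, "log_likelihood": f.log_likelihood,
          "n_params": f.n_params, "aic": f.aic} for f in fits),
        key=lambda row: row["aic"],
    )
    lrts = [
        likelihood_ratio_test(by_family[r], by_family[f])
        for r, f in _NESTED
        if r in by_family and f in by_family
    ]
    return {"best": table[0]["family"], "aic_table": table, "lrt": lrts}
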