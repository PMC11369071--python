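"""Maximum-likelihood tetrachoric correlation from paired binary data.

The tetrachoric correlation is the correlation of the latent bivariate
normal inferred from a 2x2 table of binary outcomes, here the workhorse for
twin cross-twin within-trait and cross-twin cross-trait correlations.  The
multinomial likelihood over the four orthant cells is maximized jointly in
(atanh r, t1, t2); Wald confidence intervals come from the observed
information via the delta method, with the interval for r built on the
atanh scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .liability import bvn_upper

__all__ = ["CellCounts2x2", "TetrachoricEstimate", "estimate_tetrachoric", "twin_correlations"]


@dataclass(frozen=True)
class CellCounts2x2:
    """Joint counts of two binary outcomes: n11 both, n10 first only, etc."""

    n11: float
    n10: float
    n01: float
    n00: float

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.total <= 0:
            raise ValueError("table is empty")

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    @classmethod
    def from_binary(cls, x: np.ndarray, y: np.ndarray) -> "CellCounts2x2":
        x = np.asarray(x).astype(bool)
        y = np.asarray(y).astype(bool)
        return cls(
            n11=float(np.sum(x & y)),
            n10=float(np.sum(x & ~y)),
            n01=float(np.sum(~x & y)),
            n00=float(np.sum(~x & ~y)),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.n11, self.n10, self.n01, self.n00])


@dataclass
class TetrachoricEstimate:
    """ML tetrachoric correlation with thresholds and Wald uncertainty."""

    r: float
    t1: float
    t2: float
    se_r: float = np.nan
    se_t1: float = np.nan
    se_t2: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    n: float = 0.0
    log_likelihood: float = np.nan
    boundary: bool = False
    converged: bool = True
    extras: dict = field(default_factory=dict)


def _cell_probs(r: float, t1: float, t2: float) -> np.ndarray:
    p11 = float(bvn_upper(t1, t2, r))
    m1 = float(norm.sf(t1))
    m2 = float(norm.sf(t2))
    p10 = max(m1 - p11, 0.0)
    p01 = max(m2 - p11, 0.0)
    p00 = max(1.0 - p11 - p10 - p01, 0.0)
    return np.array([p11, p10, p01, p00])


def _negloglik(theta: np.ndarray, counts: np.ndarray) -> float:
    z, t1, t2 = theta
    p = _cell_probs(np.tanh(z), t1, t2)
    p = np.clip(p, 1e-300, 1.0)
    return -float(counts @ np.log(p))


def _numerical_hessian(f, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = step
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step * step)
    return H


def estimate_tetrachoric(counts: CellCounts2x2) -> TetrachoricEstimate:
    """Maximum-likelihood tetrachoric correlation from a 2x2 table.

    Degenerate tables (an empty margin) and tables with fewer than three
    nonzero cells yield a boundary result: r pinned at +/-1 when the table
    is perfectly concordant/discordant, NaN when the margin carries no
    information, with ``boundary=True`` and no standard errors.
    """
    c = counts.as_array()
    n = counts.total
    m1 = (c[0] + c[1]) / n  # P(first = 1)
    m2 = (c[0] + c[2]) / n
    if m1 in (0.0, 1.0) or m2 in (0.0, 1.0):
        return TetrachoricEstimate(
            r=np.nan, t1=float(norm.isf(m1)) if 0 < m1 < 1 else np.inf,
            t2=float(norm.isf(m2)) if 0 < m2 < 1 else np.inf,
            n=n, boundary=True,
        )
    if np.count_nonzero(c) < 3:
        # both off-diagonal or both diagonal cells empty: |r| at its bound
        r_b = 1.0 if (c[1] == 0 and c[2] == 0) else -1.0
        return TetrachoricEstimate(
            r=r_b, t1=float(norm.isf(m1)), t2=float(norm.isf(m2)),
            n=n, boundary=True,
        )

    # start: thresholds from margins, r from the Pearson correlation of the
    # binary indicators (a consistent, if biased-toward-zero, proxy)
    t1_0 = float(norm.isf(m1))
    t2_0 = float(norm.isf(m2))
    phi = (c[0] / n - m1 * m2) / np.sqrt(m1 * (1 - m1) * m2 * (1 - m2))
    z0 = np.arctanh(np.clip(phi, -0.95, 0.95))
    res = optimize.minimize(
        _negloglik, x0=np.array([z0, t1_0, t2_0]), args=(c,), method="L-BFGS-B",
    )
    z, t1, t2 = res.x
    r = float(np.tanh(z))

    H = _numerical_hessian(lambda th: _negloglik(th, c), res.x)
    se_z = se_t1 = se_t2 = se_r = np.nan
    ci_low = ci_high = np.nan
    try:
        cov = np.linalg.inv(H)
        if np.all(np.diag(cov) > 0):
            se_z, se_t1, se_t2 = np.sqrt(np.diag(cov))
            se_r = se_z * (1 - r * r)  # delta method through tanh
            ci_low = float(np.tanh(z - 1.959963984540054 * se_z))
            ci_high = float(np.tanh(z + 1.959963984540054 * se_z))
    except np.linalg.LinAlgError:
        pass

    return TetrachoricEstimate(
        r=r, t1=float(t1), t2=float(t2),
        se_r=float(se_r), se_t1=float(se_t1), se_t2=float(se_t2),
        ci_low=ci_low, ci_high=ci_high, n=n,
        log_likelihood=-res.fun, boundary=False, converged=bool(res.success),
    )


def _inflate_double_entry(est: TetrachoricEstimate, n_unique: float) -> TetrachoricEstimate:
    """Rescale uncertainty so it reflects unique pairs, not doubled entries."""
    z = np.arctanh(np.clip(est.r, -1 + 1e-12, 1 - 1e-12))
    for attr in ("se_r", "se_t1", "se_t2"):
        setattr(est, attr, getattr(est, attr) * np.sqrt(2.0))
    se_z = est.se_r / max(1 - est.r**2, 1e-12)
    est.ci_low = float(np.tanh(z - 1.959963984540054 * se_z))
    est.ci_high = float(np.tanh(z + 1.959963984540054 * se_z))
    est.extras["n_unique_pairs"] = n_unique
    return est


def twin_correlations(
    pairs: pd.DataFrame,
    trait1: str,
    trait2: str | None = None,
    zygosity: str | None = None,
    zygosity_col: str = "zygosity",
) -> TetrachoricEstimate:
    """Cross-twin tetrachoric correlation for one zygosity group.

    For the within-trait correlation (``trait2`` omitted) each pair is
    double-entered — (twin1, twin2) and (twin2, twin1) — so the estimate is
    invariant to twin ordering; for the cross-twin cross-trait correlation
    the two orderings twin1-trait1 x twin2-trait2 and twin1-trait2 x
    twin2-trait1 are pooled.  Standard errors are based on the number of
    unique pairs, not doubled entries.

    The pair table needs columns ``<trait>_1`` / ``<trait>_2`` holding each
    twin's binary phenotype.
    """
    df = pairs
    if zygosity is not None:
        df = df[df[zygosity_col] == zygosity]
    if len(df) == 0:
        raise ValueError(f"no pairs for zygosity {zygosity!r}")

    if trait2 is None:
        x = np.concatenate([df[f"{trait1}_1"], df[f"{trait1}_2"]])
        y = np.concatenate([df[f"{trait1}_2"], df[f"{trait1}_1"]])
    else:
        x = np.concatenate([df[f"{trait1}_1"], df[f"{trait2}_1"]])
        y = np.concatenate([df[f"{trait2}_2"], df[f"{trait1}_2"]])
    est = estimate_tetrachoric(CellCounts2x2.from_binary(x, y))
    if not est.boundary:
        est = _inflate_double_entry(est, n_unique=float(len(df)))
    return est
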