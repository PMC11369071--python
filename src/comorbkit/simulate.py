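"""Seeded generators for the four data structures the pipeline consumes.

The real inputs — Swedish national registers, twin-registry subcohorts and
published GWAS summary statistics — are not redistributable, so every
analysis stage is validated against synthetic data that reproduces the
statistical structure the stage assumes:

* twin pairs with liabilities drawn from the zygosity-implied 4-variate
  normal (MZ share A 100%/D 100%/C 100%; DZ 50%/25%/100%),
* multigeneration families with full- and half-sibling genetic sharing
  (kinship-correct A transmission) or, alternatively, a direct logit link
  between two traits with a stated conditional odds ratio,
* GWAS summary statistics under the polygenicity model
  E[chi^2] = 1 + N h^2 l / M, with an exact "noiseless" mode for
  regression-recovery oracles,
* standardized polygenic scores tied to a binary outcome through a logit
  model with a stated per-SD odds ratio.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from .twinmodel import CrossTraitCorrelations, VarianceComponents, expected_structure

__all__ = [
    "TwinSimParams",
    "FamilySimParams",
    "SumstatSimParams",
    "PrsSimParams",
    "simulate_twin_pairs",
    "simulate_family_cohort",
    "simulate_sumstats",
    "simulate_prs_cohort",
    "split_bivariate_sumstats",
]


def split_bivariate_sumstats(ss: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a bivariate sumstats frame into two single-trait frames."""
    ss1 = ss[["snp", "a1", "a2", "z", "n"]].copy()
    ss2 = ss[["snp", "a1", "a2", "z2", "n2"]].rename(columns={"z2": "z", "n2": "n"})
    return ss1, ss2


def _solve_intercept(target_prev: float, offset: np.ndarray) -> float:
    """Intercept alpha with mean(expit(alpha + offset)) = target_prev."""
    f = lambda a: float(np.mean(expit(a + offset))) - target_prev
    lo, hi = -30.0, 30.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# twin pairs
# ---------------------------------------------------------------------------

@dataclass
class TwinSimParams:
    """Generating truth for a liability-model twin-pair sample.

    Components are per-trait proportions summing to one; a second trait is
    simulated when ``components2`` is given, with cross-trait factor
    correlations from ``cross``.  ``beta_sex`` / ``beta_birth_year`` shift
    the liability (equivalently, the threshold) per covariate unit.
    """

    n_mz: int
    n_dz: int
    components: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(a2=0.5, e2=0.5)
    )
    prevalence: float = 0.1
    components2: VarianceComponents | None = None
    prevalence2: float = 0.1
    cross: CrossTraitCorrelations | None = None
    beta_sex: float = 0.0
    beta_birth_year: float = 0.0
    birth_year_range: tuple[int, int] = (1959, 2012)
    seed: int = 0

    def __post_init__(self) -> None:
        for comp in (self.components, self.components2):
            if comp is None:
                continue
            total = comp.a2 + comp.c2 + comp.d2 + comp.e2
            if not np.isclose(total, 1.0, atol=1e-8):
                raise ValueError(f"variance proportions must sum to 1, got {total}")
            if min(comp.a2, comp.c2, comp.d2, comp.e2) < 0:
                raise ValueError("variance proportions must be nonnegative")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


def simulate_twin_pairs(params: TwinSimParams) -> pd.DataFrame:
    """Draw twin pairs from the liability model implied by the sharing rules.

    Returns one row per pair: ``zygosity``, binary ``trait1_1/..2`` (and
    ``trait2_*`` in the bivariate case), ``sex`` (pair-shared, 0/1) and
    standardized ``birth_year``.
    """
    rng = np.random.default_rng(params.seed)
    bivariate = params.components2 is not None
    cross = params.cross or CrossTraitCorrelations()
    frames = []
    t1 = norm.isf(params.prevalence)
    t2 = norm.isf(params.prevalence2) if bivariate else None
    for zygosity, n in (("MZ", params.n_mz), ("DZ", params.n_dz)):
        if n == 0:
            continue
        if bivariate:
            corr = expected_structure((params.components, params.components2), cross, zygosity)
        else:
            corr = expected_structure(params.components, None, zygosity)
        L = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
        liab = rng.standard_normal((n, corr.shape[0])) @ L.T
        sex = rng.integers(0, 2, size=n)
        by = rng.uniform(*params.birth_year_range, size=n)
        by_std = (by - np.mean(params.birth_year_range)) / (
            (params.birth_year_range[1] - params.birth_year_range[0]) / np.sqrt(12.0)
        )
        shift = params.beta_sex * sex + params.beta_birth_year * by_std
        df = pd.DataFrame({"zygosity": zygosity, "sex": sex, "birth_year": by_std})
        if bivariate:
            df["trait1_1"] = (liab[:, 0] + shift > t1).astype(int)
            df["trait2_1"] = (liab[:, 1] + shift > t2).astype(int)
            df["trait1_2"] = (liab[:, 2] + shift > t1).astype(int)
            df["trait2_2"] = (liab[:, 3] + shift > t2).astype(int)
        else:
            df["trait1_1"] = (liab[:, 0] + shift > t1).astype(int)
            df["trait1_2"] = (liab[:, 1] + shift > t1).astype(int)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "pair_id", np.arange(len(out)))
    return out


# ---------------------------------------------------------------------------
# multigeneration family cohort
# ---------------------------------------------------------------------------

@dataclass
class FamilySimParams:
    """Generating truth for a multigeneration register-like cohort.

    Two trait models are available.  The liability variant transmits
    additive genetic liability parent to child (child A = midparent A plus
    segregation noise of variance a2/2) with a mother-household shared C,
    giving kinship-correct familial gradients.  The logit variant links
    trait2 directly to trait1 within individual with a stated conditional
    odds ratio — the quantity the register-style logistic analyses
    estimate.
    """

    n_families: int
    mean_offspring: float = 2.2
    p_new_father: float = 0.12   # chance a later child is by a different father
    p_shared_father: float = 0.04  # chance a family reuses an earlier family's father
    trait_model: str = "logit"   # "logit" or "liability"
    # logit variant
    prevalence1: float = 0.007
    prevalence2: float = 0.18
    conditional_or: float = 1.0
    beta_sex: float = 0.2
    beta_birth_year: float = 0.1
    # liability variant
    a2: float = 0.75
    c2: float = 0.0
    birth_year_range: tuple[int, int] = (1987, 2014)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_model not in ("logit", "liability"):
            raise ValueError("trait_model must be 'logit' or 'liability'")
        if self.conditional_or <= 0:
            raise ValueError("conditional odds ratio must be positive")


def simulate_family_cohort(params: FamilySimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a pedigree table and a phenotype table.

    Pedigree rows are probands (children) plus their parents; parents have
    missing parent ids.  Phenotypes: ``trait1`` (the rarer exposure, e.g.
    an IBD-like flag) and ``trait2`` for all individuals.
    """
    rng = np.random.default_rng(params.seed)
    nf = params.n_families
    n_kids = 1 + rng.poisson(max(params.mean_offspring - 1.0, 0.0), size=nf)
    total_kids = int(n_kids.sum())

    mother = np.repeat(np.arange(nf), n_kids)  # family index per child
    birth_order = np.concatenate([np.arange(k) for k in n_kids])

    # father assignment: base father per family, possibly shared with an
    # earlier family; later children may switch to a new father
    base_father = np.arange(nf)
    shared = rng.random(nf) < params.p_shared_father
    donor = rng.integers(0, nf, size=nf)
    base_father[shared & (donor < np.arange(nf))] = donor[shared & (donor < np.arange(nf))]

    father_slot = np.zeros(total_kids, dtype=int)  # 0 = family father, 1,2,... new
    switch = (rng.random(total_kids) < params.p_new_father) & (birth_order > 0)
    father_slot = np.where(switch, birth_order, 0)

    mother_id = np.array([f"M{m}" for m in mother])
    father_key = np.where(
        father_slot == 0,
        [f"F{base_father[m]}" for m in mother],
        [f"F{m}x{s}" for m, s in zip(mother, father_slot)],
    )
    child_id = np.array([f"C{i}" for i in range(total_kids)])

    sex = rng.integers(0, 2, size=total_kids)
    by = rng.integers(params.birth_year_range[0], params.birth_year_range[1] + 1, size=total_kids)
    by_std = (by - by.mean()) / max(by.std(), 1e-12)
    parity = np.minimum(birth_order + 1, 3)

    parents = pd.DataFrame(
        {
            "individual_id": np.concatenate([np.unique(mother_id), np.unique(father_key)]),
        }
    )
    parents["father_id"] = pd.NA
    parents["mother_id"] = pd.NA
    parents["sex"] = [0] * len(np.unique(mother_id)) + [1] * len(np.unique(father_key))
    parents["birth_year"] = np.nan
    parents["parity"] = pd.NA

    children = pd.DataFrame(
        {
            "individual_id": child_id,
            "father_id": father_key,
            "mother_id": mother_id,
            "sex": sex,
            "birth_year": by.astype(float),
            "parity": parity,
        }
    )
    pedigree = pd.concat([children, parents], ignore_index=True)

    all_ids = pedigree["individual_id"].to_numpy()
    n_all = len(all_ids)
    is_child = np.concatenate([np.ones(total_kids, bool), np.zeros(n_all - total_kids, bool)])

    if params.trait_model == "logit":
        sex_all = pedigree["sex"].to_numpy(dtype=float)
        by_all = np.where(is_child, np.concatenate([by_std, np.zeros(n_all - total_kids)]), 0.0)
        lp1 = params.beta_sex * sex_all + params.beta_birth_year * by_all
        a1 = _solve_intercept(params.prevalence1, lp1)
        trait1 = rng.random(n_all) < expit(a1 + lp1)
        lp2 = (
            np.log(params.conditional_or) * trait1
            + params.beta_sex * sex_all
            + params.beta_birth_year * by_all
        )
        a2_ = _solve_intercept(params.prevalence2, lp2)
        trait2 = rng.random(n_all) < expit(a2_ + lp2)
    else:
        a_sd = np.sqrt(params.a2)
        c_sd = np.sqrt(params.c2)
        e_sd = np.sqrt(max(1.0 - params.a2 - params.c2, 0.0))
        # parents: independent A; children: midparent mean + segregation noise
        uniq_mothers = np.unique(mother_id)
        uniq_fathers = np.unique(father_key)
        A_m = dict(zip(uniq_mothers, a_sd * rng.standard_normal(len(uniq_mothers))))
        A_f = dict(zip(uniq_fathers, a_sd * rng.standard_normal(len(uniq_fathers))))
        C_house = dict(zip(uniq_mothers, c_sd * rng.standard_normal(len(uniq_mothers))))
        A_child = (
            0.5 * np.array([A_m[m] for m in mother_id])
            + 0.5 * np.array([A_f[f] for f in father_key])
            + np.sqrt(params.a2 / 2.0) * rng.standard_normal(total_kids)
        )
        A_all = np.concatenate(
            [A_child, [A_m[m] for m in np.unique(mother_id)], [A_f[f] for f in np.unique(father_key)]]
        )
        C_all = np.concatenate(
            [
                np.array([C_house[m] for m in mother_id]),
                c_sd * rng.standard_normal(n_all - total_kids),
            ]
        )
        liab1 = A_all + C_all + e_sd * rng.standard_normal(n_all)
        liab2 = A_all + C_all + e_sd * rng.standard_normal(n_all)
        trait1 = liab1 > norm.isf(params.prevalence1)
        trait2 = liab2 > norm.isf(params.prevalence2)

    phenotypes = pd.DataFrame(
        {
            "individual_id": all_ids,
            "trait1": trait1.astype(int),
            "trait2": trait2.astype(int),
        }
    )
    return pedigree, phenotypes


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SumstatSimParams:
    """Generating truth for LD-score-regression summary statistics.

    LD scores are drawn from a shifted gamma (positive, right-skewed).  In
    noiseless mode chi-square statistics sit exactly on the polygenicity
    line 1 + N h2 l / M (bivariate mode uses matched variant duos whose
    within-duo means sit exactly on all three regression lines), which
    turns regression recovery into an exact linear-algebra identity.
    """

    M: int = 20000
    N: int = 50000
    h2_obs: float = 0.2
    intercept: float = 1.0
    N2: int | None = None
    h2_obs2: float | None = None
    rg: float | None = None
    cross_intercept: float = 0.0
    noiseless: bool = False
    ld_gamma_shape: float = 2.0
    ld_gamma_scale: float = 40.0
    ld_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M <= 0 or self.N <= 0:
            raise ValueError("M and N must be positive")
        if self.h2_obs < 0:
            raise ValueError("h2 must be nonnegative")
        if self.rg is not None and abs(self.rg) > 1:
            raise ValueError("|rg| must be at most 1")


def simulate_sumstats(params: SumstatSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-variant z-scores (one or two traits) plus LD scores.

    Returns ``(sumstats, ldscores)``; bivariate mode adds ``z2``/``n2``
    columns to the sumstats frame.
    """
    rng = np.random.default_rng(params.seed)
    M = params.M
    bivariate = params.rg is not None
    N2 = params.N2 or params.N
    h2_2 = params.h2_obs2 if params.h2_obs2 is not None else params.h2_obs

    ld = params.ld_min + rng.gamma(params.ld_gamma_shape, params.ld_gamma_scale, size=M)
    if bivariate and params.noiseless and M % 2 == 0:
        ld[1::2] = ld[0::2]  # matched duos share an LD score
    chi1 = params.intercept + params.N * params.h2_obs * ld / M
    snp = np.array([f"rs{i}" for i in range(M)])
    a1 = np.full(M, "A")
    a2 = np.full(M, "G")

    if not bivariate:
        if params.noiseless:
            z1 = np.sqrt(chi1)
        else:
            z1 = rng.standard_normal(M) * np.sqrt(chi1)
        ss = pd.DataFrame({"snp": snp, "a1": a1, "a2": a2, "z": z1, "n": params.N})
        return ss, pd.DataFrame({"snp": snp, "l2": ld})

    chi2_ = 1.0 + N2 * h2_2 * ld / M
    gencov = params.rg * np.sqrt(params.h2_obs * h2_2)
    cross = params.cross_intercept + np.sqrt(params.N * N2) * gencov * ld / M
    if params.noiseless:
        # duos (j, j+1) with equal LD: z1 = sqrt(chi1) for both, z2 chosen so
        # duo means of z2^2 and z1*z2 are exact (regressions see duo means)
        z1 = np.sqrt(chi1)
        rho = np.clip(cross / np.sqrt(chi1 * chi2_), -1.0, 1.0)
        s = np.sqrt(np.clip(1.0 - rho**2, 0.0, None))
        sign = np.where(np.arange(M) % 2 == 0, 1.0, -1.0)
        z2 = np.sqrt(chi2_) * (rho + sign * s)
    else:
        rho = np.clip(cross / np.sqrt(chi1 * chi2_), -1.0, 1.0)
        u = rng.standard_normal(M)
        v = rng.standard_normal(M)
        z1 = u * np.sqrt(chi1)
        z2 = (rho * u + np.sqrt(1.0 - rho**2) * v) * np.sqrt(chi2_)
    ss = pd.DataFrame(
        {"snp": snp, "a1": a1, "a2": a2, "z": z1, "n": params.N, "z2": z2, "n2": N2}
    )
    return ss, pd.DataFrame({"snp": snp, "l2": ld})


# ---------------------------------------------------------------------------
# PRS cohort
# ---------------------------------------------------------------------------

@dataclass
class PrsSimParams:
    """Generating truth for a polygenic-score association cohort."""

    n: int
    or_per_sd: float = 1.0
    prevalence: float = 0.16
    beta_sex: float = 0.2
    beta_birth_year: float = 0.1
    twin_pairs: bool = True
    pair_score_corr: float = 0.5
    n_variants: int = 0   # > 0: also emit a dosage matrix + weights
    seed: int = 0

    def __post_init__(self) -> None:
        if self.or_per_sd <= 0:
            raise ValueError("per-SD odds ratio must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")


def simulate_prs_cohort(
    params: PrsSimParams,
) -> dict:
    """Standardized scores with a logit-linked binary outcome.

    Returns a dict with a ``cohort`` DataFrame (individual id, standardized
    score, outcome, sex, standardized birth year, cluster id) and, when
    ``n_variants > 0``, ``dosages`` / ``weights`` frames whose computed raw
    score standardizes to the stored score exactly.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n

    if params.n_variants > 0:
        m = params.n_variants
        w = rng.normal(scale=1.0 / np.sqrt(m), size=m)
        dos = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        raw = dos @ w
        score = (raw - raw.mean()) / raw.std()
        weights = pd.DataFrame(
            {
                "snp": [f"rs{j}" for j in range(m)],
                "chrom": 1,
                "pos": np.arange(m) * 1000 + 1,
                "a1": "A",
                "a2": "G",
                "weight": w,
                "provenance": "shrunken",
            }
        )
        dosages = pd.DataFrame(dos, columns=[f"rs{j}" for j in range(m)])
        dosages.insert(0, "individual_id", [f"I{i}" for i in range(n)])
    else:
        if params.twin_pairs:
            n_pairs = (n + 1) // 2
            shared = rng.standard_normal(n_pairs)
            uniq = rng.standard_normal((n_pairs, 2))
            r = params.pair_score_corr
            pair_scores = np.sqrt(r) * shared[:, None] + np.sqrt(1 - r) * uniq
            score = pair_scores.reshape(-1)[:n]
        else:
            score = rng.standard_normal(n)
        score = (score - score.mean()) / score.std()
        dosages = weights = None

    sex = rng.integers(0, 2, size=n)
    by = rng.uniform(0, 1, size=n)
    by_std = (by - by.mean()) / by.std()
    lp = (
        np.log(params.or_per_sd) * score
        + params.beta_sex * sex
        + params.beta_birth_year * by_std
    )
    alpha = _solve_intercept(params.prevalence, lp)
    outcome = (rng.random(n) < expit(alpha + lp)).astype(int)

    cluster = np.repeat(np.arange((n + 1) // 2), 2)[:n] if params.twin_pairs else np.arange(n)
    cohort = pd.DataFrame(
        {
            "individual_id": [f"I{i}" for i in range(n)],
            "score": score,
            "outcome": outcome,
            "sex": sex,
            "birth_year": by_std,
            "cluster_id": cluster,
        }
    )
    out = {"cohort": cohort}
    if dosages is not None:
        out["dosages"] = dosages
        out["weights"] = weights
    return out
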