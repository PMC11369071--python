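"""Familial co-aggregation: typed proband-relative pairs and odds ratios.

Familial co-aggregation asks whether disease X in a proband predicts
disease Y in a relative, stratified by genetic relatedness (self 1,
full sibling and parent 1/2, half-sibling 1/4).  Pairs are built from a
pedigree table by parent-sharing rules; associations are logistic
regressions of the outcome in the relative on the exposure in the proband
with a cluster-robust sandwich estimator, because one family contributes
every ordered pair of its members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "RELATIONSHIPS",
    "ORResult",
    "build_relative_pairs",
    "fit_pair_or",
    "apply_cohort_filters",
]

RELATIONSHIPS = ("self", "full-sibling", "parent", "maternal-half-sibling", "paternal-half-sibling")

_Z95 = 1.959963984540054


@dataclass
class ORResult:
    """Odds ratio with cluster-robust uncertainty."""

    odds_ratio: float
    log_or: float
    robust_se: float
    ci_low: float
    ci_high: float
    p_value: float
    adjustment: str
    n_pairs: int
    n_clusters: int
    separation_flag: bool = False

    def as_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "log_or": self.log_or,
            "robust_se": self.robust_se,
            "ci": [self.ci_low, self.ci_high],
            "p_value": self.p_value,
            "adjustment": self.adjustment,
            "n_pairs": self.n_pairs,
            "n_clusters": self.n_clusters,
            "separation_flag": self.separation_flag,
        }


def _validate_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    required = {"individual_id", "father_id", "mother_id"}
    missing = required - set(ped.columns)
    if missing:
        raise ValueError(f"pedigree is missing columns: {sorted(missing)}")
    if ped["individual_id"].duplicated().any():
        dup = ped.loc[ped["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"duplicate individual id in pedigree: {dup!r}")
    # an individual listed as its own parent is a cycle of length one
    own = ped["individual_id"].eq(ped["father_id"]) | ped["individual_id"].eq(ped["mother_id"])
    own = own.fillna(False)
    if own.any():
        raise ValueError("pedigree contains an individual who is its own parent")
    return ped


def build_relative_pairs(ped: pd.DataFrame, relationship: str) -> pd.DataFrame:
    """All ordered proband-relative pairs of the requested relationship.

    Full siblings share both (non-missing) parents; maternal (paternal)
    half-siblings share exactly the mother (father).  Cluster ids follow
    the shared parental unit: the parent couple for full siblings, the
    shared parent for half-siblings and parent-proband pairs, the
    individual for self pairs.  Output is deterministically ordered.
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(f"unknown relationship {relationship!r}; choose from {RELATIONSHIPS}")
    ped = _validate_pedigree(ped)

    if relationship == "self":
        out = pd.DataFrame(
            {
                "proband_id": ped["individual_id"],
                "relative_id": ped["individual_id"],
                "cluster_id": "self:" + ped["individual_id"].astype(str),
            }
        )
        return out.sort_values("proband_id", kind="stable").reset_index(drop=True)

    if relationship == "parent":
        rows = []
        for parent_col in ("father_id", "mother_id"):
            known = ped.dropna(subset=[parent_col])
            known = known[known[parent_col].isin(set(ped["individual_id"]))]
            rows.append(
                pd.DataFrame(
                    {
                        "proband_id": known["individual_id"],
                        "relative_id": known[parent_col],
                        "cluster_id": "par:" + known[parent_col].astype(str),
                    }
                )
            )
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["proband_id", "relative_id"], kind="stable").reset_index(drop=True)

    kids = ped.dropna(subset=["mother_id"]) if relationship == "maternal-half-sibling" else ped
    if relationship == "full-sibling":
        kids = ped.dropna(subset=["mother_id", "father_id"])
        merged = kids.merge(kids, on=["mother_id", "father_id"], suffixes=("_p", "_r"))
        merged = merged[merged["individual_id_p"] != merged["individual_id_r"]]
        cluster = (
            "fs:" + merged["mother_id"].astype(str) + "+" + merged["father_id"].astype(str)
        )
    elif relationship == "maternal-half-sibling":
        kids = ped.dropna(subset=["mother_id"])
        merged = kids.merge(kids, on="mother_id", suffixes=("_p", "_r"))
        merged = merged[merged["individual_id_p"] != merged["individual_id_r"]]
        same_father = (
            merged["father_id_p"].notna()
            & merged["father_id_r"].notna()
            & (merged["father_id_p"] == merged["father_id_r"])
        )
        merged = merged[~same_father]
        cluster = "mhs:" + merged["mother_id"].astype(str)
    else:  # paternal-half-sibling
        kids = ped.dropna(subset=["father_id"])
        merged = kids.merge(kids, on="father_id", suffixes=("_p", "_r"))
        merged = merged[merged["individual_id_p"] != merged["individual_id_r"]]
        same_mother = (
            merged["mother_id_p"].notna()
            & merged["mother_id_r"].notna()
            & (merged["mother_id_p"] == merged["mother_id_r"])
        )
        merged = merged[~same_mother]
        cluster = "phs:" + merged["father_id"].astype(str)

    out = pd.DataFrame(
        {
            "proband_id": merged["individual_id_p"].to_numpy(),
            "relative_id": merged["individual_id_r"].to_numpy(),
            "cluster_id": cluster.to_numpy(),
        }
    )
    return out.sort_values(["proband_id", "relative_id"], kind="stable").reset_index(drop=True)


_ADJUSTMENT_LABELS = {0: "crude", 1: "adjusted", 2: "adjusted+relative-exposure"}


def fit_pair_or(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    exposure: str,
    outcome: str,
    covariates: pd.DataFrame | None = None,
    adjustment: int = 0,
) -> ORResult:
    """Logistic regression of outcome-in-relative on exposure-in-proband.

    ``adjustment`` 0 is the crude model; 1 adds the covariate columns for
    both proband and relative (suffixes ``_p`` / ``_r`` looked up in
    ``covariates``, indexed by individual id); 2 additionally adjusts for
    the exposure trait in the relative.  Standard errors use the sandwich
    estimator clustered on ``cluster_id`` with the G/(G-1) small-sample
    factor.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs supplied")
    phen = phenotypes.set_index("individual_id")
    x = phen.loc[pairs["proband_id"], exposure].to_numpy(dtype=float)
    y = phen.loc[pairs["relative_id"], outcome].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("exposure is constant; odds ratio undefined")

    X = pd.DataFrame({"const": 1.0, "exposure": x})
    if adjustment >= 1 and covariates is not None:
        cov = covariates.set_index("individual_id")
        for col in cov.columns:
            X[f"{col}_p"] = cov.loc[pairs["proband_id"], col].to_numpy(dtype=float)
            self_pairs = (pairs["proband_id"] == pairs["relative_id"]).all()
            if not self_pairs:
                X[f"{col}_r"] = cov.loc[pairs["relative_id"], col].to_numpy(dtype=float)
    if adjustment >= 2:
        X["relative_exposure"] = phen.loc[pairs["relative_id"], exposure].to_numpy(dtype=float)

    groups = pairs["cluster_id"].to_numpy()
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(cov_type="cluster", cov_kwds={"groups": pd.Series(groups)})

    beta = float(res.params["exposure"])
    se = float(res.bse["exposure"])
    separation = abs(beta) > 15 or not np.isfinite(se)
    if separation:
        logger.warning("possible separation: |log OR| = %.2f, se = %.3g", abs(beta), se)

    return ORResult(
        odds_ratio=float(np.exp(beta)),
        log_or=beta,
        robust_se=se,
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p_value=float(res.pvalues["exposure"]),
        adjustment=_ADJUSTMENT_LABELS.get(adjustment, str(adjustment)),
        n_pairs=int(len(pairs)),
        n_clusters=int(pd.Series(groups).nunique()),
        separation_flag=bool(separation),
    )


def apply_cohort_filters(
    ped: pd.DataFrame,
    birth_year_range: tuple[float, float] | None = (1987, 2014),
    exclude_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Single exclusion step with before/after logging.

    ``exclude_flags`` may carry boolean columns (e.g. emigrated,
    died_before_6) indexed by ``individual_id``; flagged rows are dropped.
    Rows with a birth year outside the window are dropped (rows with
    missing birth year, i.e. parents, are kept).
    """
    n0 = len(ped)
    out = ped
    if birth_year_range is not None and "birth_year" in out.columns:
        by = out["birth_year"]
        keep = by.isna() | ((by >= birth_year_range[0]) & (by <= birth_year_range[1]))
        out = out[keep]
        logger.info("birth-year filter %s: %d -> %d rows", birth_year_range, n0, len(out))
    if exclude_flags is not None:
        flags = exclude_flags.set_index("individual_id")
        bad = flags.any(axis=1)
        bad_ids = set(bad[bad].index)
        n1 = len(out)
        out = out[~out["individual_id"].isin(bad_ids)]
        logger.info("exclusion flags: %d -> %d rows", n1, len(out))
    return out.reset_index(drop=True)
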