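"""Polygenic risk scores: weight assembly, scoring, and association.

Shrinkage-based per-variant weights (e.g. SBayesR output) are consumed,
not computed.  Because shrinkage methods exclude the major
histocompatibility complex (MHC), the single most significant MHC variant
is added back with its unshrunk effect size from the raw GWAS before
scoring.  Scores are effect-allele dosage sums, standardized over the
scored set; associations with a binary phenotype use a logit model with a
cluster-robust (independence working correlation) sandwich variance to
respect twin clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coaggregation import ORResult, _Z95

logger = logging.getLogger(__name__)

__all__ = ["MhcWindow", "DEFAULT_MHC_WINDOW", "assemble_weights", "compute_scores", "prs_association"]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class MhcWindow:
    """Chromosome interval treated as the MHC region (GRCh37 default)."""

    chrom: int = 6
    start: int = 25_000_000
    end: int = 34_000_000

    def contains(self, chrom, pos) -> np.ndarray:
        return (np.asarray(chrom).astype(str) == str(self.chrom)) & (
            (np.asarray(pos) >= self.start) & (np.asarray(pos) <= self.end)
        )


DEFAULT_MHC_WINDOW = MhcWindow()


def assemble_weights(
    raw_gwas: pd.DataFrame,
    shrunken: pd.DataFrame,
    mhc: MhcWindow = DEFAULT_MHC_WINDOW,
) -> pd.DataFrame:
    """Combine shrunken weights with the MHC add-back rule.

    Any shrunken rows inside the MHC window are dropped; the raw-GWAS
    variant with the smallest p-value inside the window is appended with
    its unshrunk effect size (provenance ``mhc-addback``).  Ties on p are
    broken by larger |effect|, then lexicographic variant id.  With no MHC
    variant in the raw GWAS, the shrunken input passes through unchanged.
    """
    for col in ("snp", "chrom", "pos", "weight"):
        if col not in shrunken.columns:
            raise ValueError(f"shrunken weights missing column {col!r}")
    out = shrunken.copy()
    if "provenance" not in out.columns:
        out["provenance"] = "shrunken"
    inside = mhc.contains(out["chrom"], out["pos"])
    if inside.any():
        logger.info("dropping %d shrunken weights inside the MHC window", int(inside.sum()))
        out = out[~inside]

    cand = raw_gwas[mhc.contains(raw_gwas["chrom"], raw_gwas["pos"])]
    if len(cand) == 0:
        return out.reset_index(drop=True)
    cand = cand.assign(_abs_eff=cand["beta"].abs())
    cand = cand.sort_values(
        by=["p", "_abs_eff", "snp"], ascending=[True, False, True], kind="stable"
    )
    if len(cand) > 1 and cand["p"].iloc[0] == cand["p"].iloc[1]:
        logger.info("MHC minimum-p tie broken by |effect| then id: kept %s", cand["snp"].iloc[0])
    top = cand.iloc[0]
    addback = pd.DataFrame(
        {
            "snp": [top["snp"]],
            "chrom": [top["chrom"]],
            "pos": [top["pos"]],
            "a1": [top["a1"]],
            "a2": [top["a2"]],
            "weight": [top["beta"]],
            "provenance": ["mhc-addback"],
        }
    )
    return pd.concat([out, addback], ignore_index=True)


def _harmonize(
    weights: pd.DataFrame, variant_alleles: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """Match weight alleles to dosage-panel alleles.

    Returns the kept weights and a flip mask (True: dosage counts the
    weight's other allele, so score uses 2 - dosage).  Strand-ambiguous
    A/T and C/G variants and unresolvable mismatches are dropped with a
    warning.
    """
    merged = weights.merge(
        variant_alleles, on="snp", suffixes=("", "_panel"), how="inner"
    )
    a1 = merged["a1"].str.upper()
    a2 = merged["a2"].str.upper()
    p1 = merged["a1_panel"].str.upper()
    p2 = merged["a2_panel"].str.upper()
    ambiguous = pd.Series(list(zip(a1, a2)), index=merged.index).isin(_AMBIGUOUS)
    same = (a1 == p1) & (a2 == p2)
    swapped = (a1 == p2) & (a2 == p1)
    keep = (same | swapped) & ~ambiguous
    dropped = (~keep).sum()
    if dropped:
        logger.warning("dropped %d variants (ambiguous or allele mismatch)", int(dropped))
    merged = merged[keep]
    return merged, swapped[keep].to_numpy()


def compute_scores(
    weights: pd.DataFrame,
    dosages: pd.DataFrame,
    variant_alleles: pd.DataFrame | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-individual weighted dosage sums, standardized over the scored set.

    ``dosages`` holds one row per individual (column ``individual_id``) and
    one column per variant id with allele counts in [0, 2].
    ``variant_alleles`` (columns snp, a1, a2) states which allele each
    dosage column counts; when given, weights are harmonized against it
    (swapped alleles flip the dosage to 2 - d, strand-ambiguous and
    mismatched variants are dropped).  Without it, dosage columns are
    assumed to count the weight's effect allele.  Missing dosages are
    mean-imputed per variant.
    """
    var_cols = [c for c in dosages.columns if c != "individual_id"]
    if variant_alleles is not None:
        kept, flip = _harmonize(weights, variant_alleles)
    else:
        kept = weights[weights["snp"].isin(var_cols)]
        missing = set(weights["snp"]) - set(var_cols)
        if missing:
            raise ValueError(f"weight variants absent from dosage matrix: {sorted(missing)[:5]}")
        flip = np.zeros(len(kept), dtype=bool)

    snps = kept["snp"].tolist()
    w = kept["weight"].to_numpy(dtype=float)
    D = dosages[snps].to_numpy(dtype=float)
    col_mean = np.nanmean(D, axis=0)
    nan_ct = np.isnan(D).sum()
    if nan_ct:
        logger.info("mean-imputing %d missing dosage entries", int(nan_ct))
        D = np.where(np.isnan(D), col_mean[None, :], D)
    D = np.where(flip[None, :], 2.0 - D, D)
    raw = D @ w
    out = pd.DataFrame({"individual_id": dosages["individual_id"], "raw_score": raw})
    if standardize:
        sd = raw.std()
        if sd == 0:
            out["score"] = 0.0
        else:
            out["score"] = (raw - raw.mean()) / sd
    return out


def prs_association(
    scores: pd.DataFrame,
    outcome: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    cluster_ids: np.ndarray | pd.Series | None = None,
    score_col: str = "score",
) -> ORResult:
    """Per-SD odds ratio from a cluster-robust logit fit.

    Generalized-estimating-equation estimate with independence working
    correlation: the logit point estimate with a sandwich covariance
    clustered on twin pair.  Covariate columns are entered additively.
    """
    y = np.asarray(outcome, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("outcome is constant")
    X = pd.DataFrame({"const": 1.0, "score": np.asarray(scores[score_col], dtype=float)})
    if covariates is not None:
        for col in covariates.columns:
            X[col] = covariates[col].to_numpy(dtype=float)
    if cluster_ids is None:
        cluster_ids = np.arange(len(y))
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
        cov_type="cluster", cov_kwds={"groups": pd.Series(np.asarray(cluster_ids))}
    )
    beta = float(res.params["score"])
    se = float(res.bse["score"])
    return ORResult(
        odds_ratio=float(np.exp(beta)),
        log_or=beta,
        robust_se=se,
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p_value=float(res.pvalues["score"]),
        adjustment="per-SD",
        n_pairs=int(len(y)),
        n_clusters=int(pd.Series(np.asarray(cluster_ids)).nunique()),
    )
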