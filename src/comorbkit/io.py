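"""Table readers/writers and the config-driven pipeline runner.

CSV/TSV is auto-detected from the file extension.  Readers validate the
schema (mandatory columns, unique ids) and log row counts; estimates are
written as JSON, per-variant/per-individual tables as TSV.  The pipeline
runner executes requested stages in order and writes a manifest recording
inputs, seed and package version, so a rerun with the same config and
seed reproduces the deterministic stages bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_table",
    "read_pedigree",
    "read_phenotypes",
    "read_twin_pairs",
    "read_sumstats",
    "read_ldscores",
    "read_weights",
    "read_dosages",
    "write_table",
    "write_json",
    "run_pipeline",
]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_table(path: str | Path, required: tuple[str, ...] = (), unique: str | None = None) -> pd.DataFrame:
    """Read a delimited table, checking mandatory columns and id uniqueness."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {sorted(missing)}")
    if unique is not None and df[unique].duplicated().any():
        dup = df.loc[df[unique].duplicated(), unique].iloc[0]
        raise ValueError(f"{path}: duplicate {unique}: {dup!r}")
    logger.info("read %s: %d rows", path, len(df))
    return df


def read_pedigree(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=("individual_id", "father_id", "mother_id"), unique="individual_id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=("individual_id",), unique="individual_id")


def read_twin_pairs(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=("zygosity",))
    bad = set(df["zygosity"].unique()) - {"MZ", "DZ"}
    if bad:
        raise ValueError(f"{path}: unknown zygosity label(s): {sorted(bad)}")
    return df


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read summary statistics, deriving z when beta/se or or/se are given."""
    df = read_table(path, required=("snp",), unique="snp")
    cols = {c.lower(): c for c in df.columns}
    df.columns = [c.lower() for c in df.columns]
    if "z" not in df.columns:
        if {"beta", "se"} <= set(df.columns):
            df["z"] = df["beta"] / df["se"]
        elif {"or", "se"} <= set(df.columns):
            df["z"] = np.log(df["or"]) / df["se"]
        else:
            raise ValueError(f"{path}: need a z column, or beta/se, or or/se")
    if "n" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column(s): ['n']")
    if not np.all(np.isfinite(df["z"])):
        raise ValueError(f"{path}: non-finite z scores")
    return df


def read_ldscores(path: str | Path) -> pd.DataFrame:
    df = read_table(path, unique="snp")
    df.columns = [c.lower() for c in df.columns]
    if "l2" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column(s): ['l2']")
    return df


def read_weights(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=("snp", "chrom", "pos", "a1", "a2", "weight"), unique="snp")


def read_dosages(path: str | Path) -> pd.DataFrame:
    df = read_table(path, required=("individual_id",), unique="individual_id")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False)
    logger.info("wrote %s: %d rows", path, len(df))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
    logger.info("wrote %s", path)


# ---------------------------------------------------------------------------
# config-driven pipeline
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"stages", "seed", "output_dir", "inputs", "options"}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` is an ordered list of stage names; ``inputs`` maps stage
    names to input paths (stages may also consume the outputs of earlier
    stages); ``options`` holds per-stage keyword options.
    """

    stages: list
    output_dir: str = "results"
    seed: int = 0
    inputs: dict = dc_field(default_factory=dict)
    options: dict = dc_field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" not in raw:
            raise ValueError("config must list stages")
        return cls(
            stages=list(raw["stages"]),
            output_dir=raw.get("output_dir", "results"),
            seed=int(raw.get("seed", 0)),
            inputs=dict(raw.get("inputs", {})),
            options=dict(raw.get("options", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage child seed below 2^31."""
    ss = np.random.SeedSequence([base_seed, abs(hash(stage)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the manifest.

    Each stage writes one JSON result (and tables where natural) under the
    output directory.  A stage failure stops the run with the manifest
    noting the failure; earlier results are preserved.
    """
    from . import coaggregation, ldsc, prs, simulate, tetrachoric, twinmodel

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "inputs": config.inputs,
    }
    state: dict = {}

    def opt(stage: str) -> dict:
        return dict(config.options.get(stage, {}))

    try:
        for stage in config.stages:
            o = opt(stage)
            seed = o.pop("seed", _stage_seed(config.seed, stage))
            if stage == "simulate-twins":
                comp = twinmodel.VarianceComponents(**o.pop("components", {"a2": 0.5, "e2": 0.5}))
                comp2 = o.pop("components2", None)
                cross = o.pop("cross", None)
                params = simulate.TwinSimParams(
                    components=comp,
                    components2=twinmodel.VarianceComponents(**comp2) if comp2 else None,
                    cross=twinmodel.CrossTraitCorrelations(**cross) if cross else None,
                    seed=seed,
                    **o,
                )
                state["twin_pairs"] = simulate.simulate_twin_pairs(params)
                write_table(state["twin_pairs"], out / "twin_pairs.tsv")
            elif stage == "simulate-cohort":
                params = simulate.FamilySimParams(seed=seed, **o)
                ped, phen = simulate.simulate_family_cohort(params)
                state["pedigree"], state["phenotypes"] = ped, phen
                write_table(ped, out / "pedigree.tsv")
                write_table(phen, out / "phenotypes.tsv")
            elif stage == "simulate-sumstats":
                params = simulate.SumstatSimParams(seed=seed, **o)
                ss, ld = simulate.simulate_sumstats(params)
                state["sumstats"], state["ldscores"] = ss, ld
                write_table(ss, out / "sumstats.tsv")
                write_table(ld, out / "ldscores.tsv")
            elif stage == "simulate-prs":
                params = simulate.PrsSimParams(seed=seed, **o)
                bundle = simulate.simulate_prs_cohort(params)
                state["prs_cohort"] = bundle["cohort"]
                write_table(bundle["cohort"], out / "prs_cohort.tsv")
            elif stage == "tetrachoric":
                pairs = state.get("twin_pairs")
                if pairs is None:
                    pairs = read_twin_pairs(config.inputs["twin_pairs"])
                res = {}
                for z in ("MZ", "DZ"):
                    est = tetrachoric.twin_correlations(pairs, o.get("trait", "trait1"), zygosity=z)
                    res[z] = {"r": est.r, "ci": [est.ci_low, est.ci_high], "se": est.se_r}
                write_json(res, out / "tetrachoric.json")
            elif stage == "twin-fit":
                pairs = state.get("twin_pairs")
                if pairs is None:
                    pairs = read_twin_pairs(config.inputs["twin_pairs"])
                family = o.get("family", "AE")
                if o.get("bivariate", False):
                    comps, cross_est, fit = twinmodel.fit_bivariate(
                        pairs, family, traits=("trait1", "trait2"),
                        covariates=o.get("covariates"), seed=seed,
                    )
                    res = {
                        "family": family,
                        "trait1": comps[0].as_dict(),
                        "trait2": comps[1].as_dict(),
                        "cross": cross_est.as_dict(),
                        "aic": fit.aic,
                        "log_likelihood": fit.log_likelihood,
                    }
                else:
                    comp, fit = twinmodel.fit_univariate(
                        pairs, family, trait=o.get("trait", "trait1"),
                        covariates=o.get("covariates"), seed=seed,
                    )
                    res = {
                        "family": family,
                        "components": comp.as_dict(),
                        "aic": fit.aic,
                        "log_likelihood": fit.log_likelihood,
                    }
                write_json(res, out / "twin_fit.json")
            elif stage == "coagg":
                ped = state.get("pedigree")
                phen = state.get("phenotypes")
                if ped is None:
                    ped = read_pedigree(config.inputs["pedigree"])
                    phen = read_phenotypes(config.inputs["phenotypes"])
                rel = o.get("relationship", "self")
                pairs = coaggregation.build_relative_pairs(ped, rel)
                cov = None
                if o.get("adjust", 0) >= 1:
                    cov_cols = [c for c in ("sex", "birth_year", "parity") if c in ped.columns]
                    cov = ped[["individual_id"] + cov_cols].dropna()
                    keep = set(cov["individual_id"])
                    pairs = pairs[
                        pairs["proband_id"].isin(keep) & pairs["relative_id"].isin(keep)
                    ]
                res = coaggregation.fit_pair_or(
                    pairs, phen, exposure=o.get("exposure", "trait1"),
                    outcome=o.get("outcome", "trait2"),
                    covariates=cov, adjustment=o.get("adjust", 0),
                )
                write_json({rel: res.as_dict()}, out / f"coagg_{rel}.json")
            elif stage == "prs-score":
                weights = read_weights(config.inputs["weights"])
                dosages = read_dosages(config.inputs["dosages"])
                scores = prs.compute_scores(weights, dosages)
                state["scores"] = scores
                write_table(scores, out / "scores.tsv")
            elif stage == "prs-assoc":
                cohort = state.get("prs_cohort")
                if cohort is None:
                    cohort = read_table(config.inputs["prs_cohort"], required=("score", "outcome"))
                res = prs.prs_association(
                    cohort,
                    cohort["outcome"],
                    covariates=cohort[[c for c in ("sex", "birth_year") if c in cohort.columns]],
                    cluster_ids=cohort.get("cluster_id"),
                )
                write_json(res.as_dict(), out / "prs_assoc.json")
            elif stage == "ldsc-h2":
                ss = state.get("sumstats")
                ld = state.get("ldscores")
                if ss is None:
                    ss = read_sumstats(config.inputs["sumstats"])
                    ld = read_ldscores(config.inputs["ldscores"])
                fit = ldsc.ldsc_h2(ss, ld, ldsc.LdscOptions(**o))
                write_json(fit.as_dict(), out / "ldsc_h2.json")
            elif stage == "ldsc-rg":
                ss = state.get("sumstats")
                ld = state.get("ldscores")
                if ss is None:
                    ss = read_sumstats(config.inputs["sumstats"])
                    ld = read_ldscores(config.inputs["ldscores"])
                ss1 = ss[["snp", "a1", "a2", "z", "n"]]
                ss2 = ss[["snp", "a1", "a2", "z2", "n2"]].rename(columns={"z2": "z", "n2": "n"})
                fit = ldsc.ldsc_rg(ss1, ss2, ld, ldsc.LdscOptions(**o))
                write_json(fit.as_dict(), out / "ldsc_rg.json")
            else:
                raise ValueError(f"unknown stage {stage!r}")
            manifest["stages"].append({"stage": stage, "status": "ok"})
    except Exception as exc:  # partial results stay on disk
        manifest["stages"].append({"stage": stage, "status": "failed", "error": str(exc)})
        write_json(manifest, out / "manifest.json")
        raise
    write_json(manifest, out / "manifest.json")
    return manifest
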