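"""End-to-end analysis pipeline: conductance → structure → comparative.

Stages run in the order of the study workflow:

1. per-egg regression, QC and conductance; species means (max 3 eggs)
2. log transforms and allometric residualization (conductance against
   egg mass; structural traits against egg volume, kept absolute when
   the allometry is non-significant)
3. per-trait evolution-model selection (BM / λ / OU / EB by AICc) and
   phylogenetic signal (Pagel's λ)
4. phylogenetic ANOVA across elevation bands plus a Levene-type
   variance-heterogeneity test
5. PGLS of each (residual) trait on elevation under the best-AICc
   covariance; per-family PGLS for families with more than two species;
   ordinary regression within designated species

Each stage persists its table to the output directory when one is
given, so a failed run can be inspected stage by stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ovoflux import conductance as cond
from ovoflux.comparative import (
    AnovaResult,
    PGLSFit,
    glm_model_selection,
    group_variance_test,
    pgls,
    phylo_anova,
)
from ovoflux.phylo import PhyloCovariance, Tree, transform_covariance, vcv_matrix
from ovoflux.trait_models import MODELS, akaike_weights, fit_model, phylo_signal_lambda

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "family_subset_analysis"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    deltap_mode: str = "per_temperature"   # or "standard"
    standard_deltap_torr: float = cond.STANDARD_DELTAP_TORR
    max_eggs_per_species: int = 3
    nsim_anova: int = 1000
    seed: int = 0
    min_family_species: int = 3            # "> 2 species" rule
    outdir: Optional[str] = None

    def deltap_for(self, temp_c: float) -> float:
        if self.deltap_mode == "standard":
            return self.standard_deltap_torr
        return cond.saturation_vapor_pressure(temp_c)


@dataclass
class AnalysisReport:
    species_conductance: pd.DataFrame
    egg_records: pd.DataFrame
    model_selection: dict[str, pd.DataFrame]
    signal: pd.DataFrame
    anova: Optional[AnovaResult]
    variance_test: Optional[AnovaResult]
    pgls_elevation: dict[str, PGLSFit]
    family_fits: dict[str, dict[str, PGLSFit]]
    best_model: dict[str, str]
    config_hash: str


def _persist(df: pd.DataFrame, outdir: Optional[str], name: str) -> None:
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        df.to_csv(os.path.join(outdir, name), index=False)


def conductance_stage(mass_series: pd.DataFrame, config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-egg conductance with QC, then species means."""
    records = []
    for egg_id, sub in mass_series.groupby("egg_id", sort=False):
        sub = sub.sort_values("day")
        series = cond.EggMassSeries(
            egg_id=str(egg_id), species=str(sub["species"].iloc[0]),
            station=str(sub["station"].iloc[0]),
            elevation_m=float(sub["elevation_m"].iloc[0]),
            temp_c=float(sub["temp_c"].iloc[0]),
            days=sub["day"].to_numpy(), masses_g=sub["mass_g"].to_numpy(),
        )
        records.append(cond.conductance_record(
            series, deltap_torr=config.deltap_for(series.temp_c)
            if config.deltap_mode == "standard" else None,
        ))
    egg_df = pd.DataFrame([{
        "egg_id": r.egg_id, "species": r.species, "station": r.station,
        "elevation_m": r.elevation_m, "slope_mg_day": r.slope_mg_day,
        "m_h2o": r.m_h2o, "deltap_torr": r.deltap_torr, "g_h2o": r.g_h2o,
        "r_squared": r.r_squared, "qc_pass": r.qc_pass,
        "qc_reasons": ";".join(r.qc_reasons),
    } for r in records])
    species_df = cond.conductance_table(records, max_eggs=config.max_eggs_per_species)
    return egg_df, species_df


def trait_inference_stage(
    tree: Tree,
    traits: Mapping[str, Mapping[str, float]],
    config: PipelineConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, str], dict[str, PhyloCovariance]]:
    """Evolution-model selection and phylogenetic signal per trait.

    Returns (model-selection tables, signal table, best model name per
    trait, best-model covariance per trait).
    """
    sel_tables: dict[str, pd.DataFrame] = {}
    best: dict[str, str] = {}
    covs: dict[str, PhyloCovariance] = {}
    signal_rows = []
    for name, x in traits.items():
        labels = [lab for lab in tree.tip_labels if lab in x]
        sub = tree.prune_to(labels)
        fits = {m: fit_model(sub, dict(x), m) for m in MODELS}
        aiccs = {m: f.aicc for m, f in fits.items()}
        w = akaike_weights(list(aiccs.values()))
        tbl = pd.DataFrame({
            "model": list(aiccs), "loglik": [fits[m].loglik for m in aiccs],
            "shape": [fits[m].shape for m in aiccs],
            "sigma2": [fits[m].sigma2 for m in aiccs],
            "AICc": list(aiccs.values()), "weight": w,
        }).sort_values("AICc", kind="stable").reset_index(drop=True)
        tbl["dAICc"] = tbl["AICc"] - tbl["AICc"].iloc[0]
        sel_tables[name] = tbl
        bm = str(tbl["model"].iloc[0])
        best[name] = bm
        shape = fits[bm].shape
        params = ({} if bm == "BM" else
                  {"lam": shape} if bm == "lambda" else
                  {"alpha": shape} if bm == "OU" else {"a": shape})
        covs[name] = transform_covariance(vcv_matrix(sub), bm, params)
        sig = phylo_signal_lambda(sub, dict(x))
        signal_rows.append({"trait": name, "lambda": sig.lam, "loglik": sig.loglik,
                            "lrt": sig.lrt, "p": sig.p, "best_model": bm})
    return sel_tables, pd.DataFrame(signal_rows), best, covs


def family_subset_analysis(
    trait: Mapping[str, float],
    elevation_m: Mapping[str, float],
    families: Mapping[str, str],
    tree: Tree,
    min_species: int = 3,
) -> dict[str, PGLSFit]:
    """PGLS of a trait on elevation separately within each family.

    Families with fewer than ``min_species`` members carrying data, or
    without elevation spread, are skipped with a log entry.
    """
    out: dict[str, PGLSFit] = {}
    fam_members: dict[str, list[str]] = {}
    for sp in trait:
        if sp in families and sp in elevation_m:
            fam_members.setdefault(families[sp], []).append(sp)
    for fam, members in sorted(fam_members.items()):
        if len(members) < min_species:
            logger.info("family %s skipped: %d species < %d", fam, len(members), min_species)
            continue
        elevs = np.array([elevation_m[sp] for sp in members])
        if np.ptp(elevs) == 0:
            logger.info("family %s skipped: no elevation spread", fam)
            continue
        sub = tree.prune_to(members)
        C = vcv_matrix(sub)
        X = pd.DataFrame({"elev_km": [elevation_m[sp] / 1000.0 for sp in C.labels]},
                         index=C.labels)
        out[fam] = pgls({sp: trait[sp] for sp in C.labels}, X, C, cov_model="BM")
    return out


def within_species_regression(
    table: pd.DataFrame, response: str, species: str,
) -> Optional[dict]:
    """Ordinary regression of a trait on elevation inside one species
    (no phylogeny applies below the species level)."""
    from scipy import stats

    sub = table[table["species"] == species]
    if len(sub) < 3 or np.ptp(sub["elevation_m"].to_numpy()) == 0:
        return None
    res = stats.linregress(sub["elevation_m"], sub[response])
    return {"species": species, "slope": res.slope, "r_squared": res.rvalue ** 2,
            "p": res.pvalue, "n": len(sub)}


def run_pipeline(
    tree: Tree,
    mass_series: pd.DataFrame,
    morphometry: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> AnalysisReport:
    """Run the complete workflow on in-memory tables.

    ``mass_series`` is long-format (egg_id, species, station,
    elevation_m, temp_c, day, mass_g); ``morphometry`` has one row per
    species (species, length_cm, width_cm, mass_g, optional family).
    """
    config = config or PipelineConfig()
    cfg_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:12]
    outdir = config.outdir

    egg_df, species_df = conductance_stage(mass_series, config)
    _persist(egg_df, outdir, "egg_conductance.csv")
    _persist(species_df, outdir, "species_conductance.csv")
    if len(species_df) < 3:
        raise RuntimeError("conductance stage left < 3 species; cannot continue")

    merged = species_df.merge(morphometry, on="species", how="inner",
                              suffixes=("", "_morph"))
    merged["volume_cm3"] = [cond.egg_volume(l, w) for l, w in
                            zip(merged["length_cm"], merged["width_cm"])]
    merged["log_g"] = np.log(merged["g_h2o"])
    merged["log_mass"] = np.log(merged["mass_g"])
    merged["band"] = [cond.elevation_category(e) for e in merged["elevation_m"]]
    _persist(merged, outdir, "species_table.csv")

    # allometric residualization (conductance ~ egg mass on log-log scale)
    log_g = dict(zip(merged["species"], merged["log_g"]))
    log_mass = dict(zip(merged["species"], merged["log_mass"]))
    allom = cond.allometric_residuals(log_g, log_mass)
    resid_g = allom.residuals.to_dict() if allom.significant else log_g
    if not allom.significant:
        logger.info("conductance-mass allometry not significant (p=%.3f); "
                    "using absolute log conductance", allom.p_value)

    traits = {"log_g_h2o": log_g}
    sel_tables, signal_df, best, covs = trait_inference_stage(tree, traits, config)
    for name, tbl in sel_tables.items():
        _persist(tbl, outdir, f"model_selection_{name}.csv")
    _persist(signal_df, outdir, "phylo_signal.csv")

    # elevation-band comparisons on mass-corrected conductance
    bands = dict(zip(merged["species"], merged["band"]))
    matched = [sp for sp in tree.tip_labels if sp in resid_g]
    sub = tree.prune_to(matched)
    anova = variance = None
    band_counts = pd.Series([bands[sp] for sp in matched]).value_counts()
    if (band_counts >= 2).sum() >= 2:
        usable = {sp for sp in matched if band_counts[bands[sp]] >= 2}
        anova = phylo_anova(sub, {s: resid_g[s] for s in usable},
                            {s: bands[s] for s in usable},
                            nsim=config.nsim_anova, seed=config.seed)
        variance = group_variance_test({s: resid_g[s] for s in usable},
                                       {s: bands[s] for s in usable}, sub,
                                       nsim=config.nsim_anova, seed=config.seed + 1)

    # PGLS of residual conductance on elevation under the best-AICc covariance
    elev = dict(zip(merged["species"], merged["elevation_m"]))
    Cbest = covs["log_g_h2o"]
    X = pd.DataFrame({"elev_km": [elev[sp] / 1000.0 for sp in Cbest.labels]},
                     index=Cbest.labels)
    pgls_fits = {"log_g_h2o": pgls({sp: resid_g[sp] for sp in Cbest.labels}, X,
                                   Cbest, cov_model=best["log_g_h2o"])}
    _persist(pd.DataFrame([{
        "trait": k, "slope": f.params["elev_km"], "se": f.bse["elev_km"],
        "t": f.tvalues["elev_km"], "p": f.pvalues["elev_km"],
        "r_squared": f.r_squared, "cov_model": f.cov_model, "n": f.n,
    } for k, f in pgls_fits.items()]), outdir, "pgls_elevation.csv")

    fam_fits: dict[str, dict[str, PGLSFit]] = {}
    if "family" in morphometry.columns:
        families = dict(zip(morphometry["species"], morphometry["family"]))
        fam_fits["log_g_h2o"] = family_subset_analysis(
            resid_g, elev, families, tree, min_species=config.min_family_species)

    if outdir is not None:
        with open(os.path.join(outdir, "provenance.json"), "w") as fh:
            json.dump({"config_hash": cfg_hash, "seed": config.seed,
                       "n_eggs": int(len(egg_df)),
                       "n_species": int(len(species_df))}, fh, indent=2)
    return AnalysisReport(
        species_conductance=species_df, egg_records=egg_df,
        model_selection=sel_tables, signal=signal_df, anova=anova,
        variance_test=variance, pgls_elevation=pgls_fits,
        family_fits=fam_fits, best_model=best, config_hash=cfg_hash,
    )
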