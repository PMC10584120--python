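"""End-to-end analysis pipeline.

Runs the study's analysis chain on either simulated or supplied data:

1. simulate (or load) the crossed starvation-survival experiment, larval
   morphometrics and clutch outcomes;
2. fit the ten candidate survival models and rank them by AICc;
3. permutation multivariate statistics (ANOSIM + SIMPER) on morphometrics;
4. one-way ANOVA with assumption checks on the clutch summaries;
5. solve the carbonate system for the treatment water conditions;

and writes the standard report tables (model ranking, per-cell parameter
estimates, SIMPER tables, water chemistry) plus a YAML manifest recording
the seed, settings and config hash, to the configured output directory.
"""

from __future__ import annotations

import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .carbonate import WaterSample, solve_from_ph_dic
from .io import RunConfig, read_morphometrics_csv, read_mortality_csv, write_mortality_csv
from .multivariate import anosim, euclidean_distance_matrix, simper, zscore_normalize
from .reference import (FEMALE_TANK_CONDITIONS, MORPHOMETRIC_MEANS_YEAR1,
                        MORPHOMETRIC_VARS, SURVIVAL_PARAMS)
from .reproduction import clutch_summary
from .simulate import (DesignSpec, gen_clutch_outcomes, gen_morphometrics,
                       gen_survival_experiment)
from .survival import SurvivalModelSpec, compare_models, fit_survival_model
from .univariate import anderson_darling, heteroscedastic_gate, levene_test, one_way_anova

log = logging.getLogger("opilio.pipeline")

__all__ = ["run_pipeline"]


def _simulate_morphometrics(config: RunConfig) -> pd.DataFrame:
    means = {g: np.array([m[v] for v in MORPHOMETRIC_VARS])
             for g, m in MORPHOMETRIC_MEANS_YEAR1.items()}
    cov = np.diag(np.full(len(MORPHOMETRIC_VARS), config.morphometrics_sd**2))
    return gen_morphometrics(means, cov, config.morphometrics_n_per_group,
                             seed=config.seed + 1, var_names=MORPHOMETRIC_VARS)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the in-memory result bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "opilio",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "stages": [],
    }
    results: dict = {}

    def _finish(status: str):
        manifest["status"] = status
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    try:
        # -- survival -------------------------------------------------
        log.info("stage survival: begin")
        if config.mortality_csv:
            data = read_mortality_csv(config.mortality_csv, max_day=config.max_day)
        else:
            design = DesignSpec(inserts_per_cell=config.inserts_per_cell,
                                larvae_per_insert=config.larvae_per_insert,
                                max_day=config.max_day, seed=config.seed)
            data = gen_survival_experiment(design, SURVIVAL_PARAMS[config.year],
                                           year=config.year)
            write_mortality_csv(data, out / "mortality_simulated.csv")
        comparison = compare_models(data, likelihood_mode=config.likelihood_mode,
                                    seed=config.seed)
        best = fit_survival_model(data, SurvivalModelSpec("E#L", "E#L"),
                                  likelihood_mode=config.likelihood_mode,
                                  seed=config.seed)
        comparison.to_csv(out / "model_comparison.csv", index=False)
        best.per_cell.to_csv(out / "survival_parameters.csv", index=False)
        results["model_comparison"] = comparison
        results["best_fit"] = best
        manifest["stages"].append({"survival": {
            "n_larvae": int(data.n_larvae),
            "best_model": comparison.model.iloc[0],
            "best_weight": float(comparison.weight.iloc[0]),
        }})
        log.info("stage survival: done (best model %s)", comparison.model.iloc[0])

        # -- multivariate ---------------------------------------------
        log.info("stage multivariate: begin")
        if config.morphometrics_csv:
            morpho = read_morphometrics_csv(config.morphometrics_csv)
        else:
            morpho = _simulate_morphometrics(config)
            morpho.to_csv(out / "morphometrics_simulated.csv", index=False)
        groups = morpho["group"].to_numpy()
        dm = euclidean_distance_matrix(zscore_normalize(morpho))
        ano = anosim(dm, groups, n_perm=config.n_perm, seed=config.seed)
        simper_tables = {}
        levels = list(pd.unique(groups))
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                pair = (levels[i], levels[j])
                tab = simper(morpho, groups, pair=pair)
                tab.to_csv(out / f"simper_{i}{j}.csv", index=False)
                simper_tables[pair] = tab
        results["anosim"] = ano
        results["simper"] = simper_tables
        manifest["stages"].append({"multivariate": {
            "anosim_R": float(ano.statistic), "anosim_p": float(ano.p_value)}})
        log.info("stage multivariate: done (R=%.3f, p=%.4f)", ano.statistic, ano.p_value)

        # -- univariate (clutch outcomes) -----------------------------
        log.info("stage univariate: begin")
        rows = []
        for k, treatment in enumerate(FEMALE_TANK_CONDITIONS):
            for oc in gen_clutch_outcomes(120000, 0.01, 0.02, config.n_females,
                                          seed=config.seed + 10 + k, treatment=treatment):
                rows.append({"treatment": treatment, **clutch_summary(oc)})
        clutch = pd.DataFrame(rows)
        anova_rows = []
        for resp in ("fecundity", "hatching_success"):
            res = one_way_anova(clutch[resp], clutch["treatment"])
            p_lev = levene_test(clutch[resp], clutch["treatment"])
            p_ad = anderson_darling(res.extra.get("residuals",
                                                  clutch[resp] - clutch.groupby("treatment")[resp].transform("mean")))
            gate = heteroscedastic_gate(res.term("group").p, p_lev)
            anova_rows.append({
                "response": resp, "F": res.term("group").F, "p": res.term("group").p,
                "levene_p": p_lev, "ad_p": p_ad,
                "significant": gate.significant, "alpha_used": gate.alpha_used,
            })
        anova_tbl = pd.DataFrame(anova_rows)
        anova_tbl.to_csv(out / "clutch_anova.csv", index=False)
        results["clutch_anova"] = anova_tbl
        manifest["stages"].append({"univariate": {"responses": list(anova_tbl.response)}})
        log.info("stage univariate: done")

        # -- carbonate ------------------------------------------------
        log.info("stage carbonate: begin")
        chem_rows = []
        for treatment, cond in FEMALE_TANK_CONDITIONS.items():
            st = solve_from_ph_dic(WaterSample(temperature=cond["temperature"],
                                               salinity=config.salinity,
                                               ph_free=cond["ph_free"], dic=cond["dic"]))
            chem_rows.append({
                "Treatment": treatment, "Temperature": st.temperature, "pH_F": st.ph_free,
                "pCO2": st.pco2, "HCO3": st.hco3, "CO3": st.co3, "DIC": st.dic,
                "Alkalinity": st.ta, "Omega_Aragonite": st.omega_aragonite,
                "Omega_Calcite": st.omega_calcite, "Salinity": st.salinity,
            })
        chem = pd.DataFrame(chem_rows)
        chem.to_csv(out / "water_chemistry.csv", index=False)
        results["water_chemistry"] = chem
        manifest["stages"].append({"carbonate": {"n_rows": len(chem)}})
        log.info("stage carbonate: done")
    except Exception:
        _finish("failed")
        raise
    _finish("complete")
    results["manifest"] = manifest
    return results
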