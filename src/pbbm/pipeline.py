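"""Pipeline orchestration: develop -> qualify -> verify in one run.

Ties the stages together: fit the micelle partition from the calibration
solubilities, simulate the requested fed/fasted dosing scenarios through
the gut and disposition models, run NCA on the simulated profiles, and
assemble the verification statistics (predicted/observed ratios, AAFE,
fold-error summary) against the packaged observed tables.  Outputs are
plain CSV plus a text summary; all rounding happens at render time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .absorption import MechPeffLite, build_physiology, simulate_gi
from .disposition import simulate_oral, plasma_clearance
from .fixtures import fixture
from .micelle import fit_logkmw, predict_solubility_table
from .physchem import CompoundRecord, ptrans0_from_logp
from .pk import ComparisonRow, aafe, fold_error_summary, nca, food_effect_ratio
from .presets import (
    calibration_measurements,
    default_compound,
    default_disposition,
    default_dlm_config,
    default_psd,
)

__all__ = ["ConfigurationError", "load_config", "run_pipeline"]

logger = logging.getLogger("pbbm")

_REQUIRED_SECTIONS = ("compound", "scenarios")


class ConfigurationError(ValueError):
    """A run configuration is missing or malformed; names the section."""


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config root must be a mapping")
    return cfg


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _resolve_compound(config: dict) -> CompoundRecord:
    block = config.get("compound")
    if block is None:
        raise ConfigurationError("missing config section: 'compound'")
    if block == "default":
        return default_compound()
    return CompoundRecord.from_dict(block)


def run_pipeline(
    config: Union[dict, str, Path], out_dir: Union[str, Path], seed: Optional[int] = None
) -> dict:
    """Execute the full fit -> simulate -> verify workflow.

    Parameters
    ----------
    config : dict or path
        Run configuration (YAML).  Sections: ``compound`` (block or
        ``default``), ``scenarios`` (list of {study, dose_mg, state,
        n_doses, tau_h}), optional ``media_set``, ``simulation``
        ({n_bins, t_end_h}) and ``seed``.
    out_dir : path
        Output directory for the report bundle (created if needed).
    seed : int, optional
        Overrides the config seed; echoed in the log and the summary.

    Returns the report bundle as a dict of DataFrames/objects.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    for section in _REQUIRED_SECTIONS:
        if section not in config:
            raise ConfigurationError(f"missing config section: '{section}'")
    seed = int(seed if seed is not None else config.get("seed", 0))
    rng = np.random.default_rng(seed)  # funnel for any stochastic stage
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _config_hash(config)
    logger.info("run config hash=%s seed=%d", cfg_hash, seed)

    compound = _resolve_compound(config)
    disposition = default_disposition()
    media_set = config.get("media_set", "oa_ch")
    sim_cfg = config.get("simulation", {})
    n_bins = int(sim_cfg.get("n_bins", 20))
    t_end = float(sim_cfg.get("t_end_h", 36.0))

    # --- stage 1: solubility fit -----------------------------------------
    measurements = calibration_measurements(media_set)
    partition = fit_logkmw(measurements, compound)
    logger.info(
        "fitted partition logK_n=%.3f logK_ion=%.3f residual=%.2e",
        partition.logk_neutral, partition.logk_ion, partition.fit_residual,
    )
    sol_table = predict_solubility_table(
        partition,
        [m.medium for m in measurements],
        [m.mean_mg_per_ml for m in measurements],
        compound,
    )

    # --- stage 2: scenario simulations ------------------------------------
    mech = MechPeffLite(p_trans0=ptrans0_from_logp(compound.logP))
    psd, dlm = default_psd(), default_dlm_config()
    scenario_rows = []
    metrics_by_key = {}
    for scen in config["scenarios"]:
        study = scen.get("study", "scenario")
        dose = float(scen["dose_mg"])
        state = scen["state"]
        if state not in ("fasted", "fed"):
            raise ConfigurationError(f"scenario state must be fasted/fed: {scen}")
        n_doses = int(scen.get("n_doses", 1))
        tau_h = float(scen.get("tau_h", 24.0))
        phys = build_physiology(state)
        gi = simulate_gi(
            dose, psd, dlm, phys, partition, mech, compound,
            t_end_h=t_end, n_bins=n_bins,
        )
        profile = simulate_oral(
            (gi.times, gi.input_rate_mg_h), disposition,
            n_doses=n_doses, tau_h=tau_h,
        )
        metrics = nca(profile)
        key = (study, dose, state)
        metrics_by_key[key] = metrics
        scenario_rows.append(
            {
                "study": study,
                "dose_mg": dose,
                "state": state,
                "fa": gi.fa,
                "cmax_ug_mL": metrics.cmax / 1000.0,
                "tmax_h": metrics.tmax,
                "auc_0_t_ug_h_mL": metrics.auc_0_t / 1000.0,
                "auc_0_inf_ug_h_mL": (
                    metrics.auc_0_inf / 1000.0
                    if metrics.auc_0_inf is not None else np.nan
                ),
                "t_half_h": metrics.t_half,
            }
        )
        pd.DataFrame(
            {"t_h": gi.times, "rate_mg_per_h": gi.input_rate_mg_h}
        ).to_csv(out / f"input_rate_{study}_{dose:g}mg_{state}.csv", index=False)
        logger.info("scenario %s %gmg %s: fa=%.4f cmax=%.1f ng/mL",
                    study, dose, state, gi.fa, metrics.cmax)
    scenarios = pd.DataFrame(scenario_rows)

    # --- stage 3: verification statistics ---------------------------------
    t8 = fixture("table8")
    included = t8[t8.aafe_included]
    aafe_row = {
        metric: aafe(
            list(zip(g.predicted.astype(float), g.observed.astype(float)))
        )
        for metric, g in included.groupby("metric")
    }
    fed_pred = (
        t8[(t8.study == "FoodEffect") & (t8.state == "moderate-fat")]
        .set_index("metric")["predicted"]
    )
    rows = [
        ComparisonRow(
            r.study, r.dose_mg, r.metric, float(r.observed),
            float(r.predicted if r.aafe_included else fed_pred[r.metric]),
            r.state,
        )
        for r in t8.itertuples()
    ]
    folds = fold_error_summary(rows)

    report = pd.DataFrame(
        [
            {"quantity": "AAFE_Cmax", "value": round(aafe_row["Cmax"], 2)},
            {"quantity": "AAFE_Tmax", "value": round(aafe_row["Tmax"], 2)},
            {"quantity": "AAFE_AUC", "value": round(aafe_row["AUC"], 2)},
            {"quantity": "max_fold_deviation", "value": round(folds.max_fold_deviation, 3)},
            {"quantity": "fraction_within_1.25_fold", "value": round(folds.fraction_within_1_25, 3)},
            {"quantity": "fraction_within_2_fold", "value": round(folds.fraction_within_2, 3)},
        ]
    )

    food_effect = None
    fed_keys = [k for k in metrics_by_key if k[2] == "fed"]
    fasted_keys = [k for k in metrics_by_key if k[2] == "fasted"]
    for fk in fed_keys:
        match = [k for k in fasted_keys if k[0] == fk[0] and k[1] == fk[1]]
        if match:
            cr, ar = food_effect_ratio(metrics_by_key[fk], metrics_by_key[match[0]])
            food_effect = {"study": fk[0], "dose_mg": fk[1],
                           "cmax_ratio_fed_fasted": cr, "auc_ratio_fed_fasted": ar}
            break

    # --- render ------------------------------------------------------------
    scenarios.to_csv(out / "scenario_metrics.csv", index=False)
    sol_table.to_csv(out / "solubility_fit.csv", index=False)
    report.to_csv(out / "verification_report.csv", index=False)
    cl, e_h = plasma_clearance(disposition)
    lines = [
        f"run: seed={seed} config_hash={cfg_hash}",
        f"fitted partition: logK_neutral={partition.logk_neutral:.4f} "
        f"logK_ion={partition.logk_ion:.4f} (media set '{media_set}')",
        f"plasma clearance: {cl:.3f} L/h (hepatic extraction {e_h:.4f})",
        f"AAFE (Cmax, Tmax, AUC): {aafe_row['Cmax']:.2f}, "
        f"{aafe_row['Tmax']:.2f}, {aafe_row['AUC']:.2f}",
        f"fold errors: max {folds.max_fold_deviation:.2f}, "
        f"{100*folds.fraction_within_1_25:.0f}% within 1.25-fold, "
        f"{100*folds.fraction_within_2:.0f}% within 2-fold",
    ]
    if food_effect:
        lines.append(
            f"food effect ({food_effect['study']} {food_effect['dose_mg']:g} mg): "
            f"fed/fasted Cmax {food_effect['cmax_ratio_fed_fasted']:.2f}, "
            f"AUC {food_effect['auc_ratio_fed_fasted']:.2f}"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    for line in lines:
        logger.info(line)

    return {
        "partition": partition,
        "solubility_fit": sol_table,
        "scenarios": scenarios,
        "aafe": aafe_row,
        "fold_summary": folds,
        "food_effect": food_effect,
        "report": report,
    }
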