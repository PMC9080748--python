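"""End-to-end orchestration: simulate -> extract -> scale -> path.

Every stage reads and writes plain CSV/JSON in the run directory; the run
log records the seed, package and library versions and per-stage status so
every numeric output is traceable to configuration plus seed.  Per-trial
work is independent, so results are identical whether a trial is processed
alone or in a batch.
"""

from __future__ import annotations

import json
import platform
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as swio
from .kinextract import KinextractConfig, extract_trial_kinematics
from .pathfit import (build_model_menu, default_speed_path_model,
                      fit_path_model, lrt_path, model_menu_search,
                      pearson_matrix, residualize)
from .scalestats import (ancova_search, detect_outliers, handedness_summary,
                         isometry_expectation, scaling_fits)
from .smoothing import SmoothConfig, smooth_trial
from .synthgen import (MorphoGenConfig, default_study_grid, write_fixture_set)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

#: morphometric traits entering the scaling analysis (scale counts are
#: excluded by default: dorsal rows barely vary, ventral counts violate
#: variance homogeneity)
DEFAULT_SCALING_TRAITS = [
    "mass_g", "tail_cm", "width25_cm", "width50_cm", "width75_cm",
    "neck_width_cm", "head_width_cm", "head_length_cm",
]

KINEMATIC_VARS = [
    "centroid_mean_speed", "centroid_peak_speed", "centroid_mean_accel",
    "centroid_peak_accel", "marker_peak_speed_mean", "height_lifted_mean",
    "frequency_hz", "wavelength_cm", "amplitude_cm", "skew_deg",
]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    data_dir: str | None = None        # existing input tables; None -> simulate
    n_individuals: int = 74
    noise_sd_cm: float = 0.1
    scaling_traits: list[str] = field(default_factory=lambda:
                                      list(DEFAULT_SCALING_TRAITS))
    outlier_rule: str = "and"
    smoothing: SmoothConfig = field(default_factory=SmoothConfig)
    kinextract: KinextractConfig = field(default_factory=KinextractConfig)
    use_model_menu: bool = False
    path_restarts: int = 10


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    smooth = SmoothConfig(**raw.pop("smoothing", {}))
    kin = KinextractConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in raw.pop("kinextract", {}).items()})
    return PipelineConfig(smoothing=smooth, kinextract=kin, **raw)


def _stage_simulate(cfg: PipelineConfig, out: Path) -> dict:
    grid = default_study_grid(seed=cfg.seed, noise_sd_cm=cfg.noise_sd_cm)
    morph = MorphoGenConfig(n_individuals=cfg.n_individuals, seed=cfg.seed)
    manifest = write_fixture_set(grid, morph, out / "inputs")
    return {"n_trials": len(grid), "manifest": manifest}


def _stage_extract(cfg: PipelineConfig, out: Path, data_dir: Path) -> dict:
    meta = swio.read_trial_metadata(data_dir / "trial_metadata.csv")
    rows = {}
    for rec in meta.to_dict("records"):
        trial_id = rec["trial_id"]
        try:
            from .smoothing import TrialMeta
            tracks = swio.read_marker_tracks(
                data_dir / rec["coord_file"],
                meta=TrialMeta(
                    trial_id=trial_id,
                    individual_id=str(rec["individual_id"]),
                    sex=str(rec["sex"]), age_class=str(rec["age_class"]),
                    temperature_C=float(rec["temperature_C"]),
                    handedness=str(rec["handedness"]),
                ))
            smoothed = smooth_trial(tracks, cfg.smoothing)
            rows[trial_id] = extract_trial_kinematics(smoothed, cfg.kinextract)
        except Exception as exc:
            raise RuntimeError(
                f"extract stage failed on trial {trial_id}: {exc}") from exc
    swio.write_kinematics_table(rows, out / "kinematics.csv")
    return {"n_trials": len(rows)}


def _stage_scale(cfg: PipelineConfig, out: Path, data_dir: Path) -> dict:
    morph = swio.read_morphometrics(data_dir / "morphometrics.csv")
    morph = morph.assign(log_svl=np.log10(morph["svl_cm"]))
    scaling_rows = []
    ancova_rows = []
    outlier_info = {}
    for trait in cfg.scaling_traits:
        rep = detect_outliers(morph, trait, rule=cfg.outlier_rule)
        outlier_info[trait] = rep.flagged_ids
        keep = morph[~morph["id"].isin(rep.flagged_ids)].copy()
        keep[f"log_{trait}"] = np.log10(keep[trait])
        anc = ancova_search(keep, f"log_{trait}")
        for rank, row in anc.table.iterrows():
            ancova_rows.append({
                "response": trait, "terms": "+".join(row["terms"]) or "~1",
                "k": row["k"], "aicc": row["aicc"], "delta": row["delta"],
                "rank": row["rank"],
                "selected": list(row["terms"]) == anc.selected_terms,
            })
        for fit in scaling_fits(keep, trait, grouping=anc.grouping,
                                expected=isometry_expectation(trait)):
            scaling_rows.append({
                "trait": trait, "group": fit.group, "n": fit.rma.n,
                "rma_slope": fit.rma.slope, "rma_ci_low": fit.rma.ci_low,
                "rma_ci_high": fit.rma.ci_high,
                "ols_slope": fit.ols.slope, "ols_ci_low": fit.ols.ci_low,
                "ols_ci_high": fit.ols.ci_high,
                "rma_intercept": fit.rma.intercept,
                "ols_intercept": fit.ols.intercept,
                "expected": fit.isometry_expected, "verdict": fit.verdict,
            })
    pd.DataFrame(scaling_rows).to_csv(out / "scaling_report.csv", index=False)
    pd.DataFrame(ancova_rows).to_csv(out / "ancova_report.csv", index=False)

    # handedness summary over all trials
    meta = swio.read_trial_metadata(data_dir / "trial_metadata.csv")
    hand = handedness_summary(meta)
    (out / "handedness.json").write_text(json.dumps(hand, indent=1))
    return {"outliers": outlier_info, "handedness": hand}


def _stage_path(cfg: PipelineConfig, out: Path, data_dir: Path) -> dict:
    kin = swio.read_kinematics_table(out / "kinematics.csv")
    meta = swio.read_trial_metadata(data_dir / "trial_metadata.csv")
    morph = swio.read_morphometrics(data_dir / "morphometrics.csv")
    rep = meta[meta["representative"].astype(bool)]
    df = (rep.merge(kin, on="trial_id")
             .merge(morph, left_on="individual_id", right_on="id",
                    how="left"))
    ren = {"frequency_hz": "frequency", "wavelength_cm": "wavelength",
           "amplitude_cm": "amplitude", "skew_deg": "skew",
           "height_lifted_mean": "height", "centroid_mean_speed": "speed",
           "width50_cm": "width50", "tail_cm": "tail", "mass_g": "mass",
           "ventral_count": "ventral"}
    df = df.rename(columns=ren)
    rescfg = {v: {"log": v != "skew", "covariates": []}
              for v in ren.values() if v in df.columns}
    resid = residualize(df, svl="svl_cm", config=rescfg)

    r, p = pearson_matrix(resid)
    r.to_csv(out / "pearson_r.csv")
    p.to_csv(out / "pearson_p.csv")

    spec = default_speed_path_model()
    menu_selected = None
    if cfg.use_model_menu:
        report = model_menu_search(build_model_menu(), resid,
                                   restarts=cfg.path_restarts, seed=cfg.seed)
        report.table.to_csv(out / "path_menu.csv", index=False)
        if report.selected is not None:
            spec = build_model_menu()[report.selected]
            menu_selected = report.selected

    sub = resid[list(spec.variables)].dropna()
    S = np.corrcoef(sub.to_numpy(), rowvar=False)
    fit = fit_path_model(spec, S, len(sub), restarts=cfg.path_restarts,
                         seed=cfg.seed)
    rows = []
    for (kind, a, b), est in fit.estimates.items():
        row = {"kind": kind, "from": a, "to": b, "estimate": est,
               "se": fit.se[(kind, a, b)], "lrt_chi2": np.nan, "lrt_p": np.nan}
        if kind == "path":
            chi2, pv = lrt_path(spec, (a, b), S, len(sub), full=fit,
                                restarts=max(2, cfg.path_restarts // 2),
                                seed=cfg.seed)
            row["lrt_chi2"], row["lrt_p"] = chi2, pv
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "path_report.csv", index=False)
    summary = {"chi_square": fit.chi_square, "df": fit.df,
               "p_lack_of_fit": fit.p_lack_of_fit, "rmsea": fit.rmsea,
               "aicc": fit.aicc, "n": fit.n, "converged": fit.converged,
               "menu_selected": menu_selected}
    (out / "path_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_pipeline(cfg: PipelineConfig,
                 stages: tuple[str, ...] = ("simulate", "extract", "scale",
                                            "path")) -> dict:
    """Run the requested stages; returns the run log (also written to disk).

    Deterministic for a given seed; a stage failure aborts with the stage
    name and offending trial in the exception message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import scipy
    import statsmodels

    log: dict = {
        "seed": cfg.seed,
        "config": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                   for k, v in asdict(cfg).items()},
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__,
                     "statsmodels": statsmodels.__version__},
        "stages": {},
    }
    data_dir = Path(cfg.data_dir) if cfg.data_dir else out / "inputs"
    for stage in stages:
        t0 = time.time()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if stage == "simulate":
                info = _stage_simulate(cfg, out)
            elif stage == "extract":
                info = _stage_extract(cfg, out, data_dir)
            elif stage == "scale":
                info = _stage_scale(cfg, out, data_dir)
            elif stage == "path":
                info = _stage_path(cfg, out, data_dir)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        log["stages"][stage] = {"seconds": round(time.time() - t0, 2),
                                **{k: v for k, v in info.items()
                                   if k != "manifest"}}
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return log
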