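"""End-to-end orchestration: simulate -> preprocess -> quantify -> model ->
stratify -> correlate, with a reproducible run manifest.

A run is fully described by a :class:`RunConfig` (YAML-loadable).  Every
stage writes its outputs under the run directory; the manifest records the
config, package version and SHA-256 checksums of all artefacts, so a rerun
with the same config is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import cohort_summary, tumor_regression_pct
from .oplsda import (cv_anova, fit_oplsda, misclassification_table, predict,
                     permutation_test)
from .panel import DEFAULT_PANEL, WATER_WINDOW
from .preprocess import (BucketGrid, ParetoScaler, bucket_spectra,
                         exclude_water, reference_to_alanine)
from .quantify import quantify_panel
from .spectra import CHANNEL_CPMG
from .stratify import correlate_response, detect_mixing, paired_battery
from .synth import CohortSpec, EffectProfile, generate_cohort

log = logging.getLogger("nmrstrat")


@dataclass
class RunConfig:
    """Configuration of a pipeline run (all stages)."""

    outdir: str = "run"
    seed: int | None = 0
    # simulation
    n_patients: int = 53
    male_fraction: float = 0.66
    proportions: tuple[float, float, float] = (34 / 53, 10 / 53, 9 / 53)
    # preprocessing
    grid_upper: float = 9.0
    grid_lower: float = 0.5
    bucket_width: float = 0.002
    water_window: tuple[float, float] = WATER_WINDOW
    reference_window: tuple[float, float] = (1.3, 1.7)
    reference_target: float = 1.48
    # modelling
    n_orth: int = 2
    n_folds: int = 7
    n_perm: int = 199
    run_permutation: bool = True
    # external test set (mirrors a post-hoc validation cohort)
    external_n_pre: int = 1
    external_n_post: int = 23
    # plots
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.proportions, list):
            cfg.proportions = tuple(cfg.proportions)
        if isinstance(cfg.water_window, list):
            cfg.water_window = tuple(cfg.water_window)
        if isinstance(cfg.reference_window, list):
            cfg.reference_window = tuple(cfg.reference_window)
        return cfg

    def validate(self) -> None:
        if self.run_permutation and self.seed is None:
            raise ValueError("a seed is mandatory when permutation testing "
                             "(or any stochastic step) is enabled")
        if self.seed is None:
            raise ValueError("a seed is mandatory for cohort simulation")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict[str, str] = {}
    results: dict[str, object] = {}

    try:
        # -- simulate -----------------------------------------------------
        spec = CohortSpec(n_patients=config.n_patients,
                          male_fraction=config.male_fraction,
                          proportions=config.proportions, seed=config.seed)
        profile = EffectProfile()
        spectra, clinical, truth = generate_cohort(spec, profile)
        clinical.to_csv(outdir / "clinical.csv")
        truth[["subgroup", "sex"]].to_csv(outdir / "truth_labels.csv")
        log.info("simulated %d patients (%d spectra)", config.n_patients,
                 len(spectra))

        # -- preprocess ---------------------------------------------------
        grid = BucketGrid(upper=config.grid_upper, lower=config.grid_lower,
                          width=config.bucket_width,
                          exclusions=(tuple(config.water_window),))
        cpmg = [reference_to_alanine(s, config.reference_window,
                                     target=config.reference_target)
                for s in spectra if s.channel == CHANNEL_CPMG]
        table = exclude_water(bucket_spectra(cpmg, grid), config.water_window)
        table.to_csv(outdir / "buckets.csv")
        scaler = ParetoScaler()
        X = scaler.fit_transform(table.values)
        y = np.array([s.timepoint for s in cpmg])
        log.info("bucketed %d spectra into %d retained buckets",
                 len(cpmg), table.n_retained)

        # -- quantify -----------------------------------------------------
        metabolites = quantify_panel(spectra, DEFAULT_PANEL)
        metabolites.to_csv(outdir / "metabolites.csv")

        # -- fit & validate ----------------------------------------------
        model = fit_oplsda(X, y, n_orth=config.n_orth)
        report = permutation_test(X, y, n_orth=config.n_orth,
                                  n_perm=config.n_perm, seed=config.seed,
                                  n_folds=config.n_folds) \
            if config.run_permutation else None
        from .oplsda import cross_validate
        q2, y_cv = cross_validate(X, y, n_orth=config.n_orth,
                                  n_folds=config.n_folds,
                                  return_predictions=True)
        model.q2 = q2
        f_stat, p_cv = cv_anova(y, y_cv, n_components=1 + config.n_orth)
        model.to_json(outdir / "model.json")
        results.update({
            "r2x": model.r2x, "r2x_orth": model.r2x_orth.tolist(),
            "r2y": model.r2y, "q2": q2,
            "cv_anova_F": f_stat, "cv_anova_p": p_cv,
        })
        if report is not None:
            results["perm_p_r2y"] = report.p_r2y
            results["perm_p_q2"] = report.p_q2

        # external test set: weak-response-free cohort predicted through
        # the trained model (mirrors a post-treatment validation group)
        if config.external_n_pre + config.external_n_post > 0:
            ext_spec = CohortSpec(
                n_patients=config.external_n_pre + config.external_n_post,
                male_fraction=config.male_fraction,
                proportions=(1.0, 0.0, 0.0), seed=config.seed + 1)
            ext_spectra, _, _ = generate_cohort(ext_spec, profile)
            wanted = (["pre"] * config.external_n_pre
                      + ["post"] * config.external_n_post)
            ext_cpmg = []
            for i, tp in enumerate(wanted):
                pid = f"P{i + 1:03d}"
                ext_cpmg.extend(
                    reference_to_alanine(s, config.reference_window,
                                         target=config.reference_target)
                    for s in ext_spectra
                    if s.channel == CHANNEL_CPMG and s.patient_id == pid
                    and s.timepoint == tp)
            ext_table = exclude_water(bucket_spectra(ext_cpmg, grid),
                                      config.water_window)
            X_ext = scaler.transform(ext_table.values)
            _, calls = predict(model, X_ext)
            truth_ext = np.array([s.timepoint for s in ext_cpmg])
            mis = misclassification_table(calls, truth_ext)
            mis.to_csv(outdir / "misclassification_external.csv")
            results["external_pct_correct"] = float(
                (calls == truth_ext).mean() * 100.0)

        # -- stratify -----------------------------------------------------
        scores = pd.Series(model.t_pred)
        timepoints = pd.Series([s.timepoint for s in cpmg])
        patients = pd.Series([s.patient_id for s in cpmg])
        trajectories = detect_mixing(scores, timepoints, patients)
        trajectories.to_csv(outdir / "trajectories.csv")
        strata = trajectories["stratum"]
        results["strata_counts"] = strata.value_counts().to_dict()

        battery = paired_battery(metabolites, strata=strata,
                                 sex=clinical["sex"])
        battery.to_csv(outdir / "univariate_stats.csv", index=False)

        # -- correlate ----------------------------------------------------
        panel_cols = [r.name for r in DEFAULT_PANEL]
        wide = metabolites.pivot_table(index="patient_id", columns="timepoint",
                                       values=panel_cols, observed=True)
        deltas = pd.DataFrame(
            {met: wide[(met, "pre")] - wide[(met, "post")] for met in panel_cols})
        responses = pd.DataFrame(index=clinical.index)
        responses["cT-yT"] = [
            int(str(c)[0]) - int(str(y_)[0])
            for c, y_ in zip(clinical["cT"], clinical["yT"])]
        responses["cN-yN"] = [
            int(str(c)[0]) - int(str(y_)[0])
            for c, y_ in zip(clinical["cN"], clinical["yN"])]
        responses["regression_pct"] = [
            tumor_regression_pct(pre, post) for pre, post in
            zip(clinical["pre_volume_cm3"], clinical["post_volume_cm3"])]
        splits = {
            "all": list(clinical.index),
            "M": list(clinical.index[clinical["sex"] == "M"]),
            "F": list(clinical.index[clinical["sex"] == "F"]),
            **{s: list(strata[strata == s].index) for s in strata.unique()},
        }
        correlations = correlate_response(deltas, responses, splits)
        correlations.to_csv(outdir / "response_correlations.csv", index=False)
        results["n_retained_correlations"] = int(len(correlations))

        summary = cohort_summary(clinical)
        summary.to_csv(outdir / "cohort_summary.csv", index=False)

        if config.make_plots:
            from .plots import metabolite_boxplots, sline_plot, trajectory_plot
            trajectory_plot(trajectories, outdir / "trajectories.png")
            Xc = table.values - table.values.mean(axis=0)
            cov = Xc.T @ (model.t_pred - model.t_pred.mean()) / len(model.t_pred)
            sline_plot(table.retained_centers, cov, model.p_corr,
                       outdir / "sline.png")
            metabolite_boxplots(metabolites,
                                ["lipid_1.3", "alanine_1.48", "NAG_2.07",
                                 "glucose_3.24"],
                                outdir / "boxplots.png")
    except Exception:
        log.exception("pipeline stage failed; partial outputs preserved")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            artifacts[p.name] = _sha256(p)
    manifest = {
        "package": "nmrstrat",
        "version": __version__,
        "config": asdict(config),
        "results": results,
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    return manifest
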