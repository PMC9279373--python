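"""End-to-end pipeline: simulate → condition → label → features → model → IGM.

``run_pipeline`` executes every stage on a synthetic cohort (or on
user-supplied tables), writes all intermediate tables, the exclusion
ledger, the metrics and a run manifest, and returns the in-memory results.
A fixed seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from fastlabel import cohort_features, fasting_labeler, glucose_conditioning
from fastlabel import igm_reporting, model_eval, synthetic_emr

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    ``verification_source`` selects what "algorithm-verified fasting" means
    for the IGM report: ``"model"`` uses predicted probability of
    nonfasting < 0.5 from the fitted classifier (``verification_model``
    picks which one), ``"theoretical"`` uses the HbA1c-anchored label
    (samples without same-day HbA1c count as not verified).
    """

    generator: synthetic_emr.GeneratorConfig = field(
        default_factory=synthetic_emr.GeneratorConfig
    )
    labeler: fasting_labeler.LabelerConfig = field(
        default_factory=fasting_labeler.LabelerConfig
    )
    sd_mode: str = "cohort"
    train_fraction: float = 0.8
    bootstrap_reps: int = 2000
    verification_source: str = "model"  # {"model", "theoretical"}
    verification_model: str = "gbt"  # {"gbt", "logistic"}
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.generator, dict):
            self.generator = synthetic_emr.GeneratorConfig(**self.generator)
        if isinstance(self.labeler, dict):
            self.labeler = fasting_labeler.LabelerConfig(**self.labeler)
        if self.verification_source not in ("model", "theoretical"):
            raise ValueError("verification_source must be 'model' or 'theoretical'")
        if self.verification_model not in ("gbt", "logistic"):
            raise ValueError("verification_model must be 'gbt' or 'logistic'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage; optionally write the full report bundle to ``outdir``.

    Returns a dict with the generated tables, the conditioning ledger, the
    labeled samples, model metrics, the AUROC comparison, the period IGM
    report and the density summaries.
    """
    cfg = config
    seed = cfg.seed

    cohort = _stage("simulate")(synthetic_emr.generate_cohort)(cfg.generator)
    conditioned, ledger = _stage("condition")(glucose_conditioning.condition)(
        cohort.glucose
    )
    labeled, sd_ref = _stage("label")(fasting_labeler.label_cohort)(
        conditioned, cohort.hba1c, cohort.patients, cfg.labeler, sd_mode=cfg.sd_mode
    )
    features_all = _stage("features")(cohort_features.build_features)(
        labeled,
        cohort.patients,
        hospital_lat=cfg.generator.hospital_lat,
        hospital_lon=cfg.generator.hospital_lon,
        require_label=False,
    )
    features_lab = features_all[features_all["label_nonfasting"].notna()].reset_index(
        drop=True
    )

    balanced = _stage("balance")(cohort_features.curate_balanced)(features_lab, seed)
    train, test = _stage("split")(cohort_features.split_train_test)(
        balanced, cohort_features.SplitSpec(cfg.train_fraction, seed)
    )

    fit = _stage("train")(model_eval.fit_model)
    logit = fit(train, model_eval.ModelConfig("logistic", seed=seed))
    gbt = fit(train, model_eval.ModelConfig("gbt", seed=seed))

    y_test = test["label_nonfasting"].to_numpy(dtype=bool)
    s_logit = logit.predict_proba(test)
    s_gbt = gbt.predict_proba(test)
    evaluate = _stage("evaluate")(model_eval.confusion_metrics)
    metrics = {
        "logistic": evaluate(s_logit, y_test).to_dict(),
        "gbt": evaluate(s_gbt, y_test).to_dict(),
    }
    auroc_cmp = _stage("evaluate")(model_eval.bootstrap_auroc_difference)(
        s_gbt, s_logit, y_test, reps=cfg.bootstrap_reps, seed=seed
    )

    # algorithm verification over *all* conditioned samples
    samples = labeled.copy()
    if cfg.verification_source == "model":
        scorer = gbt if cfg.verification_model == "gbt" else logit
        scores = _stage("igm")(scorer.predict_proba)(features_all)
        samples["algorithm_fasting"] = scores < 0.5
    else:
        samples["algorithm_fasting"] = (
            samples["theoretical_fasting"].fillna(False).to_numpy(dtype=bool)
        )

    igm_table = _stage("igm")(igm_reporting.period_prevalence)(
        samples, cohort.patients, cfg.generator.period_range
    )
    densities = _stage("igm")(igm_reporting.density_summaries)(labeled)

    manifest = {
        "package": "fastlabel",
        "config": cfg.to_dict(),
        "seed": seed,
        "sd_reference": sd_ref,
        "n_patients": int(len(cohort.patients)),
        "n_glucose_records": int(len(cohort.glucose)),
        "n_ac_ontological": int(len(conditioned)),
        "n_labelable": int(labeled["labelable"].sum()),
        "n_balanced": int(len(balanced)),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
    }
    results = {
        "cohort": cohort,
        "conditioned": conditioned,
        "ledger": ledger,
        "labeled": labeled,
        "sd_reference": sd_ref,
        "features": features_all,
        "balanced": balanced,
        "train": train,
        "test": test,
        "models": {"logistic": logit, "gbt": gbt},
        "metrics": metrics,
        "auroc_comparison": auroc_cmp,
        "igm_periods": igm_table,
        "density_summaries": densities,
        "manifest": manifest,
    }
    if outdir is not None:
        _write_bundle(results, cfg, Path(outdir))
    return results


def _write_bundle(results: dict, cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic_emr.write_cohort(results["cohort"], outdir, cfg.generator)
    results["conditioned"].to_csv(outdir / "ac_ontological.csv", index=False)
    results["ledger"].to_csv(outdir / "exclusion_ledger.csv", index=False)
    results["labeled"].to_csv(outdir / "labeled_samples.csv", index=False)
    results["features"].to_csv(outdir / "features.csv", index=False)
    results["balanced"].to_csv(outdir / "balanced.csv", index=False)
    results["train"].to_csv(outdir / "train.csv", index=False)
    results["test"].to_csv(outdir / "test.csv", index=False)
    results["igm_periods"].to_csv(outdir / "igm_periods.csv", index=False)
    results["density_summaries"].to_csv(outdir / "density_summaries.csv", index=False)
    results["models"]["logistic"].odds_ratios().to_csv(outdir / "odds_ratios.csv")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(
            {
                "metrics": results["metrics"],
                "auroc_comparison": results["auroc_comparison"],
            },
            fh, indent=2, sort_keys=True,
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(results["manifest"], fh, indent=2, sort_keys=True, default=str)
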