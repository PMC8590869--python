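"""End-to-end pipeline: simulate -> label -> sample -> featurize -> train
-> predict -> evaluate, with a manifest for reproducibility.

Every stage writes plain CSV/JSON artifacts into the run directory and is
skipped on re-run when its outputs already exist under the same config
hash, so deleting a downstream artifact resumes the pipeline without
re-simulating.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, labeler, model, sampler, synthetic, uncertainty
from .features import (PROV_ABSENT, PROV_IMPUTED, PROV_MASKED,
                       PopulationStats, build_feature_matrix,
                       compute_population_stats, merge_blood_pressure)
from .registry import Registry, default_registry

log = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    registry_path: str | None = None
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    lead: float = 1.0
    test_fraction: float = 0.2
    label_filter: str | None = None
    calibration_fraction: float = 0.2
    n_rounds: int = 200
    learning_rate: float = 0.1
    uncertainty_enabled: bool = True
    n_bootstrap: int = 20
    n_feature_draws: int = 20
    z: float = 1.96
    eval_modes: tuple = ("all", "basic+labs", "basic+ventilation", "basic")
    eval_leads: tuple = (1.0, 6.0, 12.0)

    def validate(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if not 0 < self.calibration_fraction < 1:
            raise ValueError("calibration_fraction must be in (0, 1)")
        if self.lead <= 0:
            raise ValueError("lead must be > 0")
        synthetic.GeneratorConfig(seed=self.seed, **self.generator).validate()

    def config_hash(self) -> str:
        doc = {"schema": CONFIG_SCHEMA_VERSION, **asdict(self)}
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        version = doc.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        for key in ("eval_modes", "eval_leads"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = {"schema_version": CONFIG_SCHEMA_VERSION, **asdict(self)}
        doc["eval_modes"] = list(self.eval_modes)
        doc["eval_leads"] = list(self.eval_leads)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _train_model(features: pd.DataFrame, samples: pd.DataFrame,
                 split: dict[str, str], config: RunConfig,
                 registry: Registry) -> model.StumpEnsemble:
    """Boost on most training stays, Platt-calibrate on a held-out slice."""
    train_ids = sorted({sid for sid, part in split.items() if part == "train"})
    rng = np.random.default_rng(config.seed + 17)
    order = rng.permutation(len(train_ids))
    n_cal = max(1, int(round(config.calibration_fraction * len(train_ids))))
    cal_ids = {train_ids[i] for i in order[:n_cal]}
    boost_ids = {train_ids[i] for i in order[n_cal:]}

    merged = features.merge(samples[["stay_id", "time", "label"]],
                            on=["stay_id", "time"])
    names = registry.names
    in_boost = merged["stay_id"].isin(boost_ids)
    in_cal = merged["stay_id"].isin(cal_ids)
    X = merged[names].to_numpy(dtype=float)
    y = merged["label"].to_numpy(dtype=int)

    boost_cfg = model.BoostConfig(n_rounds=config.n_rounds,
                                  learning_rate=config.learning_rate)
    ens = model.fit(X[in_boost.to_numpy()], y[in_boost.to_numpy()], names,
                    boost_cfg, registry_hash=registry.content_hash())
    model.calibrate(ens, X[in_cal.to_numpy()], y[in_cal.to_numpy()])
    return ens


def _redrawable_mask(features: pd.DataFrame, names: list[str]) -> np.ndarray:
    prov = features[[f"{n}_prov" for n in names]].to_numpy(dtype=object)
    return np.isin(prov, (PROV_IMPUTED, PROV_ABSENT, PROV_MASKED))


def run_pipeline(config: RunConfig,
                 registry: Registry | None = None) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    registry = registry or (Registry.from_yaml(config.registry_path)
                            if config.registry_path else default_registry())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    manifest_path = out / "manifest.json"
    manifest = {"config_hash": chash, "seed": config.seed, "stages": []}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != chash:
            log.warning("config changed; ignoring existing artifacts")
            for p in out.glob("*"):
                if p.name != "manifest.json" and p.is_file():
                    p.unlink()

    def stage(name, outputs, fn):
        paths = [out / o for o in outputs]
        t0 = time.perf_counter()
        if all(p.exists() for p in paths) and manifest_path.exists() and \
                json.loads(manifest_path.read_text()).get("config_hash") == chash:
            log.info("stage %s: outputs present, skipping", name)
            result = None
        else:
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({
            "name": name, "outputs": outputs,
            "seconds": round(time.perf_counter() - t0, 3),
        })
        manifest_path.write_text(json.dumps(manifest, indent=1))
        return result

    # -- simulate ----------------------------------------------------------
    gen_cfg = synthetic.GeneratorConfig(seed=config.seed, **config.generator)
    stage("simulate",
          ["stays.csv", "observations.csv", "treatments.csv"],
          lambda: synthetic.write_cohort(
              synthetic.generate_cohort(gen_cfg, registry), out))
    stays, observations, treatments = synthetic.read_cohort(out)
    observations = merge_blood_pressure(observations)

    # -- label -------------------------------------------------------------
    stage("label", ["segments.csv"],
          lambda: labeler.label_cohort(treatments).to_csv(
              out / "segments.csv", index=False))
    segments = pd.read_csv(out / "segments.csv", dtype={"stay_id": str})

    # -- sample + split ----------------------------------------------------
    def do_sample():
        samples = sampler.draw_samples(stays, segments, observations,
                                       lead=config.lead, seed=config.seed,
                                       label_filter=config.label_filter,
                                       registry=registry)
        samples.to_csv(out / "samples.csv", index=False)
        split = sampler.split_patients(samples, config.test_fraction,
                                       seed=config.seed)
        sampler.save_split(split, out / "split.json")
    stage("sample", ["samples.csv", "split.json"], do_sample)
    samples = pd.read_csv(out / "samples.csv", dtype={"stay_id": str})
    split = sampler.load_split(out / "split.json")

    # -- population stats (training split only) ----------------------------
    def do_stats():
        train_ids = {sid for sid, part in split.items() if part == "train"}
        train_obs = observations[observations["stay_id"].isin(train_ids)]
        train_stays = stays[stays["stay_id"].isin(train_ids)]
        compute_population_stats(train_obs, train_stays, registry,
                                 seed=config.seed).save(out / "stats.json")
    stage("stats", ["stats.json"], do_stats)
    stats = PopulationStats.load(out / "stats.json")

    # -- featurize ---------------------------------------------------------
    stage("featurize", ["features.csv"],
          lambda: build_feature_matrix(
              observations, stays, stats, samples[["stay_id", "time"]],
              mode="all", registry=registry).to_csv(
                  out / "features.csv", index=False))
    features = pd.read_csv(out / "features.csv", dtype={"stay_id": str})

    # -- train -------------------------------------------------------------
    stage("train", ["model.json"],
          lambda: model.save_model(
              _train_model(features, samples, split, config, registry),
              out / "model.json"))
    ens = model.load_model(out / "model.json", registry.content_hash())

    # -- predict (test split) ----------------------------------------------
    test_mask = samples["stay_id"].map(split).eq("test")
    test_samples = samples[test_mask].reset_index(drop=True)
    test_features = features[test_mask.to_numpy()].reset_index(drop=True)

    def do_predict():
        X = test_features[registry.names].to_numpy(dtype=float)
        raw = ens.raw_scores(X)
        p = ens.calibrated_probability(raw)
        pred = test_samples[["stay_id", "time", "label"]].copy()
        pred["raw_score"] = raw
        pred["p_unstable"] = p
        pred["hsi"] = 100.0 * (1.0 - p)
        top = [";".join(f"{n}:{r:.4f}" for n, r in sorted(
            ens.per_feature_risks(row).items(),
            key=lambda kv: -abs(kv[1]))[:5]) for row in X]
        pred["top_features"] = top
        if config.uncertainty_enabled:
            ucfg = uncertainty.UncertaintyConfig(
                n_bootstrap=config.n_bootstrap,
                n_feature_draws=config.n_feature_draws,
                z=config.z, seed=config.seed)
            train_mask = samples["stay_id"].map(split).eq("train")
            merged = features[train_mask.to_numpy()].merge(
                samples[["stay_id", "time", "label"]], on=["stay_id", "time"])
            boots = uncertainty.fit_bootstrap_ensembles(
                merged[registry.names].to_numpy(dtype=float),
                merged["label"].to_numpy(dtype=int),
                merged["stay_id"].to_numpy(), registry.names, ucfg,
                model.BoostConfig(n_rounds=config.n_rounds,
                                  learning_rate=config.learning_rate))
            ci = uncertainty.predict_with_ci_batch(
                ens, boots, X, _redrawable_mask(test_features, registry.names),
                stats, ucfg)
            # abstain against the breakeven threshold of the training data
            train_raw = ens.raw_scores(merged[registry.names].to_numpy(dtype=float))
            tau = evaluation.operating_points(
                train_raw, merged["label"].to_numpy())["breakeven"].threshold
            for col in ("sigma_model", "sigma_feature", "ci_low", "ci_high"):
                pred[col] = ci[col]
            pred["abstain"] = uncertainty.decide_abstain(
                raw, ci["ci_low"], ci["ci_high"], ci["sigma_model"],
                ci["sigma_feature"], tau, ucfg)
        pred.to_csv(out / "predictions.csv", index=False)
    stage("predict", ["predictions.csv"], do_predict)
    predictions = pd.read_csv(out / "predictions.csv", dtype={"stay_id": str})

    # -- evaluate ----------------------------------------------------------
    def do_evaluate():
        test_ids = {sid for sid, part in split.items() if part == "test"}
        test_obs = observations[observations["stay_id"].isin(test_ids)]
        test_stays = stays[stays["stay_id"].isin(test_ids)]
        test_segments = segments[segments["stay_id"].isin(test_ids)]
        mode_reports = evaluation.evaluate_modes(
            ens, test_obs, test_stays, stats, test_samples,
            modes=config.eval_modes, registry=registry)
        lead_reports = evaluation.evaluate_leads(
            ens, test_stays, test_segments, test_obs, stats,
            leads=config.eval_leads, seed=config.seed, registry=registry)
        sub_reports = evaluation.evaluate_subgroups(
            predictions["raw_score"].to_numpy(), test_samples)
        base = evaluation.baseline_scores(test_features)
        labels = test_samples["label"].to_numpy(dtype=int)
        base_reports = {name: evaluation.make_report(sc, labels,
                                                     {"baseline": name})
                        for name, sc in base.items()}
        frames = []
        for tag, reports in (("mode", mode_reports), ("lead", lead_reports),
                             ("subgroup", sub_reports), ("baseline", base_reports)):
            frame = evaluation.reports_to_frame(reports)
            frame.insert(0, "kind", tag)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(out / "report.csv",
                                                    index=False)
        auc, auprc, roc_points, pr_points = evaluation.roc_pr(
            predictions["raw_score"], labels)
        roc_points.merge(pr_points, on="threshold", how="outer").to_csv(
            out / "curves.csv", index=False)
        summary = {
            "auc_all_features": auc,
            "auprc_all_features": auprc,
            "mode_auc": {m: r.auc for m, r in mode_reports.items()},
            "lead_auc": {str(k): r.auc for k, r in lead_reports.items()},
            "baseline_auc": {m: r.auc for m, r in base_reports.items()},
        }
        (out / "report.json").write_text(json.dumps(summary, indent=1))
    stage("evaluate", ["report.csv", "report.json", "curves.csv"], do_evaluate)

    manifest["row_counts"] = {
        "stays": len(stays), "observations": len(observations),
        "treatments": len(treatments), "segments": len(segments),
        "samples": len(samples), "predictions": len(predictions),
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return out
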