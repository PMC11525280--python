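"""End-to-end orchestration: simulate -> extract -> pca -> predict -> cluster.

A :class:`RunConfig` (YAML/JSON-loadable, schema-validated, unknown keys
rejected) drives the full analysis and writes a reproducible report bundle:
the cohort metric table, variance-explained curves, the prediction report,
cluster labels with the dominance table, and a run manifest carrying the
config hash, seeds and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from pdmotion import __version__
from pdmotion.dimensionality import dimensionality_report, impute_median, standardize
from pdmotion.errors import ConfigError
from pdmotion.motor_metrics import METRIC_NAMES, data_dictionary, extract_all, metrics_table
from pdmotion.phenotyping import (
    classify_cohort,
    compare_partitions,
    dominance,
    rf_importance,
    train_som,
    tsne_kmeans,
    ward_cut,
)
from pdmotion.prediction import cluster_augmented_fit, grid_search
from pdmotion.session_io import UPDRS_ITEMS, write_session, write_updrs_table
from pdmotion.simulator import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

_SOM_DEFAULTS = {
    "grid_sizes": [[6, 6]],
    "epochs": [50],
    "neighborhoods": [2.0, 3.0],
    "restarts": 10,
}
_PREDICT_DEFAULTS = {"n_lambda": 50, "df_cap_frac": 0.5}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``simulator`` keys must be :class:`SimConfig` fields; ``som`` and
    ``predict`` accept only their documented keys. Unknown keys anywhere
    raise :class:`ConfigError` before any stage runs.
    """

    out_dir: str = "pdmotion_run"
    seed: int = 0
    cluster_k: int = 3
    write_sessions: bool = False
    log_level: str = "INFO"
    simulator: dict = field(default_factory=dict)
    som: dict = field(default_factory=lambda: dict(_SOM_DEFAULTS))
    predict: dict = field(default_factory=lambda: dict(_PREDICT_DEFAULTS))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(cfg.simulator) - sim_known
        if bad:
            raise ConfigError(f"unknown simulator keys: {sorted(bad)}")
        if set(cfg.som) - set(_SOM_DEFAULTS):
            raise ConfigError(f"unknown som keys: {sorted(set(cfg.som) - set(_SOM_DEFAULTS))}")
        if set(cfg.predict) - set(_PREDICT_DEFAULTS):
            raise ConfigError(
                f"unknown predict keys: {sorted(set(cfg.predict) - set(_PREDICT_DEFAULTS))}"
            )
        cfg.som = {**_SOM_DEFAULTS, **cfg.som}
        cfg.predict = {**_PREDICT_DEFAULTS, **cfg.predict}
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_config(self) -> SimConfig:
        return SimConfig(**{"seed": self.seed, **self.simulator})


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        raw = yaml.safe_load(text) or {}
    else:
        raw = json.loads(text)
    return RunConfig.from_dict(raw)


def run_pipeline(config: RunConfig, stages: Optional[list[str]] = None) -> dict:
    """Execute the requested stages in order and write the report bundle.

    Stages: simulate, extract, pca, predict, cluster (default all).
    Returns a dict of in-memory results; on-disk outputs land in
    ``config.out_dir``. Partial outputs from completed stages are kept if
    a later stage fails.
    """
    stages = stages or ["simulate", "extract", "pca", "predict", "cluster"]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    results: dict = {}

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "pdmotion": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))

    cohort = None
    if "simulate" in stages:
        logger.info("stage: simulate")
        cohort = simulate_cohort(config.sim_config())
        results["cohort"] = cohort
        cohort.updrs.to_csv(out / "updrs.csv", index=False)
        cohort.truth.to_csv(out / "truth.csv", index=False)
        if config.write_sessions:
            for session in cohort.sessions:
                write_session(session, out / "sessions" / session.subject_id)
            write_updrs_table(
                [(s.subject_id, s.visit_day, s.updrs) for s in cohort.sessions],
                out / "updrs.csv",
            )

    metrics = None
    if "extract" in stages:
        if cohort is None:
            raise ConfigError("extract requires the simulate stage in this run")
        logger.info("stage: extract")
        vectors = [extract_all(s) for s in cohort.sessions]
        metrics = metrics_table(vectors)
        metrics.to_csv(out / "metrics.csv", index=False)
        data_dictionary().to_csv(out / "data_dictionary.csv", index=False)
        results["metrics"] = metrics

    if metrics is None:
        return results
    feature_df = impute_median(metrics[list(METRIC_NAMES)])
    X = feature_df.to_numpy(float)
    Xs = standardize(feature_df)
    y = cohort.updrs["total"].to_numpy(float)

    if "pca" in stages:
        logger.info("stage: pca")
        items = cohort.updrs[list(UPDRS_ITEMS)].astype(float)
        report = dimensionality_report(items, metrics[list(METRIC_NAMES)])
        for name, res in report.items():
            res.curve().to_csv(out / f"pca_{name}.csv", index=False)
        results["pca"] = report

    if "predict" in stages:
        logger.info("stage: predict")
        fit, cv = grid_search(
            X, y,
            n_lambda=config.predict["n_lambda"],
            df_cap_frac=config.predict["df_cap_frac"],
            feature_names=list(METRIC_NAMES),
        )
        pred_report = {
            "alpha": cv.extra["alpha"],
            "lambda": cv.extra["lambda"],
            "df": fit.df,
            "df_cap": cv.extra["df_cap"],
            "mae": cv.mae,
            "r2": cv.r2,
            "coefficients": {
                name: float(c)
                for name, c in zip(METRIC_NAMES, fit.coef)
                if c != 0.0
            },
            "per_subject_predictions": cv.y_pred.tolist(),
        }
        (out / "prediction.json").write_text(json.dumps(pred_report, indent=1))
        results["prediction"] = (fit, cv)

    if "cluster" in stages:
        logger.info("stage: cluster")
        som = train_som(
            Xs.to_numpy(),
            grid_sizes=[tuple(g) for g in config.som["grid_sizes"]],
            epochs_list=config.som["epochs"],
            neighborhood_list=config.som["neighborhoods"],
            restarts=config.som["restarts"],
            seed=config.seed,
        )
        cuts = ward_cut(som, Xs.to_numpy(), k_list=(2, 3, config.cluster_k, 4))
        assignment = cuts[config.cluster_k]
        tsne_assign, _ = tsne_kmeans(Xs.to_numpy(), k=config.cluster_k, seed=config.seed)
        clinical = classify_cohort(cohort.updrs)
        labels = pd.DataFrame(
            {
                "subject_id": metrics["subject_id"],
                "som_ward": assignment.labels,
                "tsne_kmeans": tsne_assign.labels,
                "clinical_subtype": clinical.labels,
            }
        )
        labels.to_csv(out / "cluster_labels.csv", index=False)
        sizes = np.bincount(assignment.labels)[1:]
        dom = imp = None
        if (sizes >= 2).all() and len(sizes) >= 2:
            dom = dominance(Xs.to_numpy(), assignment.labels, feature_names=list(Xs.columns))
            dom.counts.to_csv(out / "dominance.csv")
            imp = rf_importance(
                Xs.to_numpy(), assignment.labels, feature_names=list(Xs.columns),
                seed=config.seed,
            )
            imp.to_csv(out / "rf_importance.csv", index=False)
        else:
            logger.warning("skipping dominance/importance: cluster sizes %s", sizes)
        comp = compare_partitions(assignment, clinical, Xs.to_numpy())
        (out / "cluster_comparison.json").write_text(
            json.dumps(
                {
                    "ari_som_vs_clinical": comp["ari"],
                    "silhouette_som": comp["silhouette_a"],
                    "silhouette_clinical": comp["silhouette_b"],
                },
                indent=1,
            )
        )
        if "prediction" in results:
            aug_fit, aug_cv = cluster_augmented_fit(
                X, y, assignment.labels,
                n_lambda=config.predict["n_lambda"],
                df_cap_frac=config.predict["df_cap_frac"],
            )
            (out / "prediction_cluster_augmented.json").write_text(
                json.dumps(
                    {"mae": aug_cv.mae, "r2": aug_cv.r2, "df": aug_fit.df}, indent=1
                )
            )
            results["prediction_augmented"] = (aug_fit, aug_cv)
        results["clusters"] = {"som": som, "cuts": cuts, "labels": labels,
                               "dominance": dom, "importance": imp}
    return results
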