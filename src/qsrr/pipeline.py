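"""End-to-end orchestration: descriptors -> split -> GA repeats -> consensus ->
validation -> applicability domain, one model per chromatographic column.

Each stage communicates with the next only through serialized artifacts in the
output directory, so the pipeline is resumable per stage. A manifest records
every artifact with its SHA-256 checksum, the master seed, and a hash of the
configuration, making a rerun verifiable bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cns
from . import dataset as ds
from . import validation as val
from .descriptors import read_descriptors
from .ga import GAConfig

__all__ = ["PipelineConfig", "run_full_pipeline"]

log = logging.getLogger("qsrr")


@dataclass
class PipelineConfig:
    descriptors_csv: str
    retention_csv: str
    columns: list[str] | None = None  # default: every column in the retention table
    out_dir: str = "qsrr_out"
    ga: GAConfig = field(default_factory=GAConfig)
    n_runs: int = 1000
    train_fraction: float = 0.7
    lv_policy: str = "min"
    df_policy: str | int = "lv2"
    master_seed: int = 0
    exclude: dict[str, list[str]] = field(default_factory=dict)  # per-column analyte drops

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ga = GAConfig(**raw.pop("ga", {}))
        return cls(ga=ga, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_one_column(
    config: PipelineConfig, descriptors: pd.DataFrame, retention: pd.Series,
    column: str, out: Path,
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    try:
        data = ds.QSRRDataset.from_tables(
            descriptors,
            retention,
            train_fraction=config.train_fraction,
            exclude=config.exclude.get(column),
        )
        data = data.dropna()
        data.to_csv(out / "dataset.csv", out / "split.csv")

        X_train, y_train = data.train
        X_val, y_val = data.validation
        log.info("%s: %d training / %d validation analytes",
                 column, len(y_train), len(y_val))

        model, runs = cns.build_consensus(
            X_train, y_train, config.ga, n_runs=config.n_runs,
            master_seed=config.master_seed, lv_policy=config.lv_policy,
        )
        for run in runs:
            log.debug("%s: GA run seed=%d rmsecv=%.5f", column, run.seed,
                      run.best_rmsecv)
        log.info("%s: consensus %s, %d LVs, RMSECV %.4f ln (%.3f min)",
                 column, model.selected_names, model.n_lv, model.rmsecv_ln,
                 model.rmsecv_minutes)

        model.occurrence.rename("percent").to_csv(out / "occurrence.csv")
        model.to_json(out / "consensus_model.json")
        model.cv.to_frame().to_csv(out / "cv_curve.csv", index=False)

        metrics = val.external_validate(model, X_val[model.selected_names], y_val)

        k = model.cv.lv_candidates.index(model.n_lv)
        anova = val.cv_anova(
            y_train.to_numpy(), model.cv.predictions_ln[:, k], n_lv=model.n_lv,
            df_policy=config.df_policy,
            n_descriptors=len(model.selected_names),
        )
        frame = anova.to_frame()
        frame.attrs["df_policy"] = anova.df_policy
        frame.to_csv(out / "anova.csv", index=False)

        ad = val.applicability_domain(model, X_query=X_val, y_query=y_val)
        ad.table.to_csv(out / "williams.csv", index=False)

        summary = {
            "column": column,
            "selected": model.selected_names,
            "n_lv": model.n_lv,
            "rmsecv_ln": model.rmsecv_ln,
            "rmsecv_min": model.rmsecv_minutes,
            "anova_F": anova.F,
            "anova_p": anova.p_value,
            "df_policy": anova.df_policy,
            "h_star": ad.h_star,
            **metrics,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed for column {column!r}: {exc}") from exc


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Run every stage for every requested column; returns the output directory."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    descriptors = read_descriptors(config.descriptors_csv)
    retention = ds.read_retention(config.retention_csv)
    columns = config.columns or list(retention.columns)

    # cross-column similarity runs once on the shared retention table
    if retention.shape[1] >= 2:
        ds.correlation_matrix(retention).to_csv(
            out_root / "column_correlations.csv", index=False
        )

    for column in columns:
        if column not in retention.columns:
            raise RuntimeError(f"pipeline stage failed for column {column!r}: "
                               "not present in the retention table")
        _fit_one_column(
            config, descriptors, retention[column], column, out_root / column
        )

    artifacts = sorted(
        p for p in out_root.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "master_seed": config.master_seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "artifacts": {
            str(p.relative_to(out_root)): _sha256(p) for p in artifacts
        },
    }
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_root
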