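"""End-to-end orchestration: simulate → normalize → stats → select → evaluate.

A run is a pure function of (config, seed): every random choice derives
from the master seed through named sub-seeds, artifacts carry no
timestamps, and the manifest records the config hash plus a checksum of
every file written, so identical configs reproduce identical bytes.

Two contrasts are supported.  ``IA_vs_NC`` pools ruptured and unruptured
patients as cases against healthy controls; ``R_vs_UR`` uses ruptured
patients as cases against unruptured ones.  In the default (paper-style)
mode the differential statistics and DFR filter are computed on the full
discovery cohort before the train/validation split; ``strict_mode``
recomputes them inside the training partition only, avoiding the filter
leakage of the default order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff_stats, evaluation, panel_select, prm_quant, syndata

CONTRASTS = ("IA_vs_NC", "R_vs_UR")


@dataclass
class RunConfig:
    contrast: str = "IA_vs_NC"
    seed: int = 0
    strict_mode: bool = False
    train_fraction: float = 0.75
    folds: int = 10
    repeats: int = 10
    l2: float = 1e-4
    n_orthogonal: int = 1
    dfr: panel_select.DFRCriteria = field(default_factory=panel_select.DFRCriteria)
    cohort1: syndata.SynConfig = field(default_factory=syndata.default_config)
    cohort2_group_sizes: dict[str, int] = field(
        default_factory=lambda: {"NC": 20, "UR": 6, "R": 6}
    )
    cohort2_n_batches: int = 1

    def validate(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}, got {self.contrast!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.folds < 2 or self.repeats < 1:
            raise ValueError("folds >= 2 and repeats >= 1 required")
        self.cohort1.validate()


def load_config(path) -> RunConfig:
    """Read a YAML run configuration, reporting unknown keys by path."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    cfg = RunConfig()
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key, value in raw.items():
        if key not in known:
            raise ValueError(f"unknown config key: {key}")
        if key == "dfr":
            cfg.dfr = panel_select.DFRCriteria(**value)
        elif key == "cohort1":
            syn_known = {f.name for f in dataclasses.fields(syndata.SynConfig)}
            bad = set(value) - syn_known
            if bad:
                raise ValueError(f"unknown config key: cohort1.{sorted(bad)[0]}")
            for k, v in value.items():
                setattr(cfg.cohort1, k, v)
        else:
            setattr(cfg, key, value)
    cfg.validate()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def sub_seeds(master: int, n: int = 8) -> list[int]:
    """Named sub-seeds (< 2^31) derived from the master seed."""
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def contrast_labels(sample_meta: pd.DataFrame, contrast: str) -> pd.Series:
    """Boolean case labels over study (non-QC) samples for a contrast."""
    meta = sample_meta[~sample_meta["is_qc"].astype(bool)]
    if contrast == "IA_vs_NC":
        keep = meta["group"].isin(["R", "UR", "NC"])
        labels = meta.loc[keep, "group"].isin(["R", "UR"])
    elif contrast == "R_vs_UR":
        keep = meta["group"].isin(["R", "UR"])
        labels = meta.loc[keep, "group"] == "R"
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return labels.astype(bool)


def _normalized_log_matrix(cfg: syndata.SynConfig) -> tuple[prm_quant.PeakAreaMatrix, pd.DataFrame]:
    matrix, meta, _truth = syndata.generate_cohort(cfg)
    norm = prm_quant.normalize_two_step(prm_quant.log10_transform(matrix))
    return norm, meta


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    model: panel_select.PanelModel
    stats: pd.DataFrame
    candidates: list[str]
    metrics: dict[str, evaluation.MetricSet]
    report: pd.DataFrame
    train_ids: list[str] = field(default_factory=list)
    val_ids: list[str] = field(default_factory=list)
    external_ids: list[str] = field(default_factory=list)
    out_dir: Path | None = None


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Execute DFR → dedup → split → RFE-CV → final fit → evaluation.

    Returns the fitted panel, the statistics table, the per-dataset
    metrics, and (when ``out_dir`` is given) writes the artifact set with
    a checksum manifest.
    """
    config.validate()
    seeds = sub_seeds(config.seed)
    # Both cohorts share the biological layer (seeds[4]); instrument and
    # sampling layers are cohort-specific.
    syn1 = dataclasses.replace(config.cohort1, seed=seeds[0], biology_seed=seeds[4])
    syn2 = dataclasses.replace(
        config.cohort1,
        group_sizes=dict(config.cohort2_group_sizes),
        n_batches=config.cohort2_n_batches,
        seed=seeds[1],
        biology_seed=seeds[4],
    )

    norm1, _ = _normalized_log_matrix(syn1)
    norm2, _ = _normalized_log_matrix(syn2)

    labels1 = contrast_labels(norm1.sample_meta, config.contrast)
    labels2 = contrast_labels(norm2.sample_meta, config.contrast)

    split = panel_select.SplitSpec(config.train_fraction, seed=seeds[2])
    train_ids, val_ids = panel_select.stratified_split(labels1, split)

    stats_cols = list(labels1.index) if not config.strict_mode else train_ids
    stats = diff_stats.compute_feature_stats(
        norm1.light[stats_cols],
        labels1[stats_cols],
        protein_of=norm1.feature_meta["protein"],
        n_orthogonal=config.n_orthogonal,
    )

    retained = panel_select.dfr_filter(stats, config.dfr)
    if len(retained) < 2:
        raise RuntimeError(
            f"DFR retained only {len(retained)} feature(s); "
            "not enough signal to build a panel under these thresholds"
        )
    candidates = panel_select.best_peptide_per_protein(stats.loc[retained])

    X1 = norm1.light.T  # samples × features, log10 normalized
    X2 = norm2.light.T
    folds = min(config.folds, int(min(labels1[train_ids].sum(),
                                      (~labels1[train_ids]).sum())))
    model = panel_select.rfe_cv(
        X1.loc[train_ids, candidates],
        labels1[train_ids],
        folds=folds,
        repeats=config.repeats,
        seed=seeds[3],
        l2=config.l2,
        p_values=stats["p"],
    )

    metrics = {
        "training": evaluation.evaluate_scores(
            model.predict_proba(X1.loc[train_ids]), labels1[train_ids]
        ),
        "internal_validation": evaluation.evaluate_scores(
            model.predict_proba(X1.loc[val_ids]), labels1[val_ids]
        ),
        "external_validation": evaluation.evaluate_scores(
            model.predict_proba(X2.loc[labels2.index]), labels2
        ),
    }
    report = evaluation.metrics_table(metrics)

    result = PipelineResult(
        model, stats, candidates, metrics, report,
        train_ids=train_ids, val_ids=val_ids, external_ids=list(labels2.index),
    )
    if out_dir is not None:
        result.out_dir = Path(out_dir)
        _write_artifacts(config, result)
    return result


def validate_external(
    model: panel_select.PanelModel, X: pd.DataFrame, labels: pd.Series
) -> evaluation.MetricSet:
    """Apply a trained panel unchanged to an external matrix and score it."""
    labels = labels.reindex(X.index)
    if labels.isna().any():
        raise ValueError("labels missing for some external samples")
    return evaluation.evaluate_scores(model.predict_proba(X), labels.astype(bool))


def _write_artifacts(config: RunConfig, result: PipelineResult) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)

    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))
    diff_stats.write_feature_stats(result.stats, out / "feature_stats.tsv")
    result.model.to_json(out / "panel_model.json")
    result.report.to_csv(out / "report.tsv", sep="\t", index=False)
    metrics_json = {
        name: {k: v for k, v in ms.as_dict().items()}
        for name, ms in result.metrics.items()
    }
    (out / "metrics.json").write_text(json.dumps(metrics_json, indent=2, sort_keys=True))
    (out / "candidates.json").write_text(
        json.dumps({"dfr_candidates": result.candidates,
                    "selected": result.model.features}, indent=2, sort_keys=True)
    )

    artifacts = sorted(
        p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_sha256": hashlib.sha256(config_path.read_bytes()).hexdigest(),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
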