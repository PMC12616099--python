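"""End-to-end experiment recipes: multi-seed evaluation, baseline comparison,
BAG analysis, saliency, regional profiling and the disease protocol.

A single :class:`ExperimentConfig` (YAML-serialisable) drives every stage;
each result bundle embeds a hash of the configuration so that a run can be
reproduced seed-for-seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .age_head import aggregate_runs, evaluate_mae
from .bag import (apply_bias_correction, compare_groups, compute_bag,
                  fit_bias_correction)
from .baselines import BaselineConfig, run_pca_gp, run_supervised_cnn
from .contrastive import KernelConfig, NeighbourhoodSchedule
from .data import split_dataset
from .encoder import EncoderConfig, TrainConfig
from .phantom import PhantomConfig, RegionSpec, generate_atlas, generate_cohort
from .predictor import train_age_predictor
from .types import Cohort, Modality, MultiChannelVolume, SubjectRecord

__all__ = ["ExperimentConfig", "run_experiment", "compare_baselines",
           "disease_protocol", "ensure_disjoint_controls", "config_hash",
           "load_config", "save_config"]

MODALITY_SETS = {
    "mre": [Modality.STIFFNESS, Modality.DAMPING],
    "stiffness_only": [Modality.STIFFNESS],
    "damping_only": [Modality.DAMPING],
    "mri_like": [Modality.T1_LIKE],
    "combined": [Modality.STIFFNESS, Modality.DAMPING, Modality.T1_LIKE],
}


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    rho_start: float = 1.0
    rho_end: float = 0.25
    modality_set: str = "mre"
    n_seeds: int = 10
    train_fraction: float = 0.8
    ridge_lambda: float = 1.0
    reshuffle_split_per_seed: bool = True
    per_image_norm: bool = False
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if self.modality_set not in MODALITY_SETS:
            raise ValueError(f"unknown modality_set {self.modality_set!r}")

    def schedule(self) -> NeighbourhoodSchedule:
        return NeighbourhoodSchedule(total_epochs=self.train.epochs,
                                     rho_start=self.rho_start, rho_end=self.rho_end)


def _to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_dict(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    return obj


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(_to_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=True))


def load_config(path: str | Path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return _config_from_dict(raw or {})


def _config_from_dict(raw: dict) -> ExperimentConfig:
    def build(cls, d):
        if d is None:
            return cls()
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
        return cls(**d)

    kwargs = dict(raw)
    ph = dict(kwargs.pop("phantom", {}) or {})
    if "region_spec" in ph:
        ph["region_spec"] = [RegionSpec(**r) if isinstance(r, dict) else RegionSpec(*r)
                             for r in ph["region_spec"]]
    if "grid_shape" in ph:
        ph["grid_shape"] = tuple(ph["grid_shape"])
    if "age_range" in ph:
        ph["age_range"] = tuple(ph["age_range"])
    if "disease_spec" in ph:
        ph["disease_spec"] = {k: [tuple(e) for e in v]
                              for k, v in ph["disease_spec"].items()}
    kwargs["phantom"] = build(PhantomConfig, ph)
    kwargs["encoder"] = build(EncoderConfig, kwargs.pop("encoder", None))
    kwargs["train"] = build(TrainConfig, kwargs.pop("train", None))
    kwargs["kernel"] = build(KernelConfig, kwargs.pop("kernel", None))
    return ExperimentConfig(**kwargs)


def _select_channels(volumes: Sequence[MultiChannelVolume],
                     modality_set: str) -> list[MultiChannelVolume]:
    wanted = MODALITY_SETS[modality_set]
    out = []
    for v in volumes:
        by_mod = {ch.modality: ch for ch in v.channels}
        missing = [m.value for m in wanted if m not in by_mod]
        if missing:
            raise ValueError(f"subject {v.subject_id} lacks channels: {missing}")
        out.append(MultiChannelVolume(v.subject_id, [by_mod[m] for m in wanted]))
    return out


def run_experiment(cfg: ExperimentConfig,
                   volumes: Sequence[MultiChannelVolume] | None = None,
                   records: Sequence[SubjectRecord] | None = None,
                   write_outputs: bool = True) -> dict:
    """Per-seed train/evaluate with aggregation.

    Generates a phantom HC cohort unless volumes/records are supplied.
    Each seed re-randomises the train/test split (configurable) and the
    encoder initialisation/batch order.
    """
    if volumes is None:
        volumes, records = generate_cohort(cfg.phantom, Cohort.HC)
    volumes = _select_channels(volumes, cfg.modality_set)
    ecfg = dataclasses.replace(cfg.encoder, in_channels=len(MODALITY_SETS[cfg.modality_set]))
    by_id = {v.subject_id: v for v in volumes}
    ages_by_id = {r.subject_id: r.age for r in records}
    per_seed_mae, per_seed_null, preds_rows = [], [], []
    for seed in range(cfg.n_seeds):
        split_seed = seed if cfg.reshuffle_split_per_seed else 0
        split = split_dataset(records, cfg.train_fraction, seed=split_seed)
        tr_vols = [by_id[i] for i in split.train_ids]
        te_vols = [by_id[i] for i in split.test_ids]
        tr_ages = np.array([ages_by_id[i] for i in split.train_ids])
        te_ages = np.array([ages_by_id[i] for i in split.test_ids])
        tcfg = dataclasses.replace(cfg.train, seed=seed)
        predictor, _ = train_age_predictor(
            tr_vols, tr_ages, ecfg, tcfg, cfg.kernel, cfg.schedule(),
            lam=cfg.ridge_lambda, per_image_norm=cfg.per_image_norm)
        preds = predictor.predict(te_vols)
        per_seed_mae.append(evaluate_mae(preds, te_ages))
        per_seed_null.append(evaluate_mae(np.full_like(te_ages, tr_ages.mean()),
                                          te_ages))
        for sid, age, p in zip(split.test_ids, te_ages, preds):
            preds_rows.append({"subject_id": sid, "age": age,
                               "predicted_age": float(p), "split": "test",
                               "seed": seed})
    result = {
        "config_hash": config_hash(cfg),
        "modality_set": cfg.modality_set,
        "per_seed_mae": [float(m) for m in per_seed_mae],
        "mean_predictor_mae": [float(m) for m in per_seed_null],
    }
    if cfg.n_seeds >= 2:
        agg = aggregate_runs(per_seed_mae)
        result["mean_mae"] = agg.mean_mae
        result["ci95"] = list(agg.ci95)
    else:
        result["mean_mae"] = float(per_seed_mae[0])
    if write_outputs:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(preds_rows).to_csv(out / "predictions.csv", index=False)
        (out / "aggregate.json").write_text(json.dumps(result, indent=2,
                                                       sort_keys=True))
        save_config(cfg, out / "config.yaml")
    return result


def compare_baselines(cfg: ExperimentConfig, seeds: Sequence[int] = (0, 1, 2),
                      baseline_cfg: BaselineConfig | None = None) -> pd.DataFrame:
    """Three-way comparison (contrastive, PCA+GP, supervised CNN) on shared splits."""
    volumes, records = generate_cohort(cfg.phantom, Cohort.HC)
    volumes = _select_channels(volumes, cfg.modality_set)
    ecfg = dataclasses.replace(cfg.encoder,
                               in_channels=len(MODALITY_SETS[cfg.modality_set]))
    bcfg = baseline_cfg or BaselineConfig()
    by_id = {v.subject_id: v for v in volumes}
    ages_by_id = {r.subject_id: r.age for r in records}
    rows = []
    for seed in seeds:
        split = split_dataset(records, cfg.train_fraction, seed=seed)
        tr = [by_id[i] for i in split.train_ids]
        te = [by_id[i] for i in split.test_ids]
        ytr = np.array([ages_by_id[i] for i in split.train_ids])
        yte = np.array([ages_by_id[i] for i in split.test_ids])
        tcfg = dataclasses.replace(cfg.train, seed=seed)
        predictor, _ = train_age_predictor(tr, ytr, ecfg, tcfg, cfg.kernel,
                                           cfg.schedule(), lam=cfg.ridge_lambda)
        rows.append({"model": "contrastive", "seed": seed,
                     "mae": evaluate_mae(predictor.predict(te), yte)})
        b1 = dataclasses.replace(bcfg, kind="pca_gp", seed=seed)
        rows.append({"model": "pca_gp", "seed": seed,
                     "mae": evaluate_mae(run_pca_gp(tr, ytr, te, b1), yte)})
        b2 = dataclasses.replace(bcfg, kind="supervised_cnn", seed=seed,
                                 epochs=cfg.train.epochs,
                                 batch_size=cfg.train.batch_size)
        rows.append({"model": "supervised_cnn", "seed": seed,
                     "mae": evaluate_mae(run_supervised_cnn(tr, ytr, te, b2), yte)})
    return pd.DataFrame(rows)


def ensure_disjoint_controls(train_records: Sequence[SubjectRecord],
                             control_records: Sequence[SubjectRecord]) -> None:
    """Guard: matched controls must not appear in the normative training set."""
    overlap = ({r.subject_id for r in train_records}
               & {r.subject_id for r in control_records})
    if overlap:
        raise ValueError(
            f"controls overlap normative training set: {sorted(overlap)}")


def disease_protocol(cfg: ExperimentConfig, patient_cohort: Cohort | str,
                     n_controls: int = 30, n_patients: int = 30,
                     seed: int = 0) -> dict:
    """Normative-model protocol for one patient cohort.

    A normative model is trained on healthy subjects only (the matched
    controls are excluded from training), the Theil-Sen bias model is fitted
    on the matched controls, and corrected BAGs of patients vs controls are
    compared with the normality-gated two-sided test.
    """
    patient_cohort = Cohort(patient_cohort)
    if patient_cohort is Cohort.HC:
        raise ValueError("patient cohort must be MCI or AD")
    ph = dataclasses.replace(cfg.phantom, seed=cfg.phantom.seed + 7919 * seed)
    hc_vols, hc_recs = generate_cohort(ph, Cohort.HC)
    ctrl_cfg = dataclasses.replace(ph, n_subjects=n_controls,
                                   seed=ph.seed + 104729)
    ctrl_vols, ctrl_recs = generate_cohort(ctrl_cfg, Cohort.HC)
    ctrl_recs = [dataclasses.replace(r, subject_id="CTRL" + r.subject_id)
                 for r in ctrl_recs]
    for v, r in zip(ctrl_vols, ctrl_recs):
        v.subject_id = r.subject_id
    pat_cfg = dataclasses.replace(ph, n_subjects=n_patients)
    pat_vols, pat_recs = generate_cohort(pat_cfg, patient_cohort)

    ensure_disjoint_controls(hc_recs, ctrl_recs)

    hc_vols = _select_channels(hc_vols, cfg.modality_set)
    ctrl_vols = _select_channels(ctrl_vols, cfg.modality_set)
    pat_vols = _select_channels(pat_vols, cfg.modality_set)
    ecfg = dataclasses.replace(cfg.encoder,
                               in_channels=len(MODALITY_SETS[cfg.modality_set]))
    ages = np.array([r.age for r in hc_recs])
    tcfg = dataclasses.replace(cfg.train, seed=seed)
    predictor, _ = train_age_predictor(hc_vols, ages, ecfg, tcfg, cfg.kernel,
                                       cfg.schedule(), lam=cfg.ridge_lambda)

    ctrl_pred = dict(zip([r.subject_id for r in ctrl_recs],
                         predictor.predict(ctrl_vols)))
    pat_pred = dict(zip([r.subject_id for r in pat_recs],
                        predictor.predict(pat_vols)))
    ctrl_bags = compute_bag(ctrl_pred, ctrl_recs)
    pat_bags = compute_bag(pat_pred, pat_recs)
    bias = fit_bias_correction(ctrl_bags)
    ctrl_bags = apply_bias_correction(bias, ctrl_bags)
    pat_bags = apply_bias_correction(bias, pat_bags)
    cmp = compare_groups([b.corrected_bag for b in pat_bags],
                         [b.corrected_bag for b in ctrl_bags])
    return {
        "config_hash": config_hash(cfg),
        "cohort": patient_cohort.value,
        "bias_slope": bias.slope,
        "bias_intercept": bias.intercept,
        "control_median_bag": float(np.median([b.corrected_bag for b in ctrl_bags])),
        "patient_median_bag": float(np.median([b.corrected_bag for b in pat_bags])),
        "test_name": cmp.test_name,
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
        "group_sizes": list(cmp.group_sizes),
        "records": {"controls": ctrl_bags, "patients": pat_bags},
    }
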