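"""End-to-end experiment orchestration.

Chains the stages: connectome preprocessing (SC absolute threshold 0.1,
FC Fisher z + density threshold 0.5) -> SMOTE balancing -> multimodal node
features -> stratified 10%/80%/20% test/train/val split -> min-max
normalization -> GAT training -> metrics / 10-fold CV -> interpretability
reports. Every stage is driven by one JSON-serializable ``RunConfig`` and
a single seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import AtlasParcellation
from .augmentation import augment_cohort
from .connectomes import CohortDataset, load_cohort, preprocess_fc, preprocess_sc
from .features import NodeFeatureMatrix, subject_features
from .gat import GATConfig
from .interpret import (
    attention_summary,
    correlate_clinical,
    fidelity_scores,
    saliency_map,
    select_salient,
)
from .synthetic import SyntheticConfig, generate_cohort
from .training import (
    GraphSample,
    SplitSpec,
    TrainConfig,
    cross_validate,
    evaluate,
    normalize_samples,
    replace_features,
    split_dataset,
    train_model,
)

log = logging.getLogger("connectogat")

MODES = ("multimodal-sc", "multimodal-fc", "unimodal-sc", "unimodal-fc")


@dataclass
class RunConfig:
    schema_version: int = 1
    mode: str = "multimodal-sc"
    sc_threshold: float = 0.1
    fc_density: float = 0.5
    fc_ranking: str = "signed"
    smote: bool = True
    smote_k: int = 5
    smote_timing: str = "pre_split"  # or "train_only" (leakage-safe)
    split: SplitSpec = field(default_factory=SplitSpec)
    model: GATConfig = field(default_factory=GATConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    cv_folds: int = 10
    run_cv: bool = True
    saliency_threshold: float = 0.02
    attention_display_threshold: float = 0.0
    clinical_alpha: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.smote_timing not in ("pre_split", "train_only"):
            raise ValueError("smote_timing must be 'pre_split' or 'train_only'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        d = json.loads(s)
        d["split"] = SplitSpec(**d.get("split", {}))
        d["train"] = TrainConfig(**d.get("train", {}))
        m = d.get("model", {})
        if "mlp_hidden" in m:
            m["mlp_hidden"] = tuple(m["mlp_hidden"])
        d["model"] = GATConfig(**m)
        return cls(**d)


def preprocess_cohort(cohort: CohortDataset, cfg: RunConfig) -> CohortDataset:
    """Threshold SC and Fisher-z + density-threshold FC for every subject."""
    subjects = []
    for s in cohort.subjects:
        subjects.append(
            dataclasses.replace(
                s,
                sc=preprocess_sc(s.sc, cfg.sc_threshold),
                fc=preprocess_fc(s.fc, cfg.fc_density, cfg.fc_ranking),
            )
        )
    return CohortDataset(subjects, cohort.atlas, cohort.provenance)


def _feature_mode(mode: str) -> str:
    return {"multimodal-sc": "multimodal", "multimodal-fc": "multimodal",
            "unimodal-sc": "unimodal-sc", "unimodal-fc": "unimodal-fc"}[mode]


def build_samples(
    cohort: CohortDataset, cfg: RunConfig
) -> tuple[list[GraphSample], list[NodeFeatureMatrix]]:
    """Model-ready graphs + raw (unnormalized) feature matrices.

    The attention neighborhood graph is the thresholded SC for the *-sc
    modes and the thresholded FC otherwise.
    """
    use_sc_graph = cfg.mode.endswith("-sc")
    fmode = _feature_mode(cfg.mode)
    samples, feats = [], []
    for s in cohort.subjects:
        morph = s.morphology if fmode == "multimodal" else None
        f = subject_features(s.sc, s.fc, morph, mode=fmode, seed=cfg.seed)
        graph = s.sc.values if use_sc_graph else s.fc.values
        samples.append(
            GraphSample(f.values, (graph != 0).astype(float), s.label,
                        s.subject_id, s.origin)
        )
        feats.append(f)
    return samples, feats


def run_pipeline(
    cfg: RunConfig,
    out_dir: str | Path,
    cohort: CohortDataset | None = None,
    manifest: str | Path | None = None,
    matrix_dir: str | Path | None = None,
    atlas: AtlasParcellation | None = None,
    synthetic: SyntheticConfig | None = None,
) -> dict:
    """Execute the full experiment; returns the report dict written to disk.

    Exactly one input source must be given: an in-memory cohort, a
    manifest + matrix directory, or a synthetic-cohort configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        if manifest is not None:
            if atlas is None:
                raise ValueError("loading a cohort requires an atlas")
            cohort = load_cohort(manifest, matrix_dir, atlas)
        elif synthetic is not None:
            cohort = generate_cohort(synthetic)
        else:
            raise ValueError("no input cohort specified")
    log.info("cohort: %d subjects (%d patients)", len(cohort), int(cohort.labels.sum()))

    model_cfg = cfg.model
    n = cohort.atlas.n_regions
    expected_f = 24 if _feature_mode(cfg.mode) == "multimodal" else 11
    if model_cfg.n_features != expected_f:
        model_cfg = replace(model_cfg, n_features=expected_f)
    if model_cfg.readout_k > n:
        model_cfg = replace(model_cfg, readout_k=n)

    pre = preprocess_cohort(cohort, cfg)
    if cfg.smote and cfg.smote_timing == "pre_split":
        pre = augment_cohort(pre, k_neighbors=cfg.smote_k, seed=cfg.seed)
        log.info("after SMOTE: %d samples", len(pre))
    samples, feats = build_samples(pre, cfg)

    split = replace(cfg.split, seed=cfg.seed)
    idx = list(range(len(samples)))
    tr_i, va_i, te_i = split_dataset(idx, np.array([s.label for s in samples]), split)

    if cfg.smote and cfg.smote_timing == "train_only":
        # leakage-safe ordering: synthetic subjects derive from, and join,
        # the training split only (class ratios of val/test stay imbalanced)
        log.warning(
            "smote_timing='train_only' balances the training split only; "
            "this deviates from the augment-then-split reference design"
        )
        train_cohort = CohortDataset(
            [pre.subjects[i] for i in tr_i], pre.atlas, pre.provenance
        )
        aug = augment_cohort(train_cohort, k_neighbors=cfg.smote_k, seed=cfg.seed)
        new = CohortDataset(
            aug.subjects[len(train_cohort) :], pre.atlas, aug.provenance
        )
        new_samples, new_feats = build_samples(new, cfg)
        tr_i = tr_i + list(range(len(samples), len(samples) + len(new_samples)))
        samples = samples + new_samples
        feats = feats + new_feats
        pre = CohortDataset(
            pre.subjects + new.subjects, pre.atlas, aug.provenance
        )
        log.info("after train-only SMOTE: %d train samples", len(tr_i))
    tr_norm, rest_norm, scaler = normalize_samples(
        [feats[i] for i in tr_i], [feats[i] for i in va_i + te_i]
    )
    va_norm = rest_norm[: len(va_i)]
    te_norm = rest_norm[len(va_i):]
    train = [replace_features(samples[i], f.values) for i, f in zip(tr_i, tr_norm)]
    val = [replace_features(samples[i], f.values) for i, f in zip(va_i, va_norm)]
    test = [replace_features(samples[i], f.values) for i, f in zip(te_i, te_norm)]

    train_cfg = replace(cfg.train, seed=cfg.seed)
    model, history = train_model(train, val, model_cfg, train_cfg)
    report: dict = {
        "config": json.loads(cfg.to_json()),
        "config_hash": hashlib.sha256(cfg.to_json().encode()).hexdigest()[:16],
        "seed": cfg.seed,
        "software": {"connectogat": __version__, "python": platform.python_version()},
        "n_samples": len(samples),
        "split_sizes": {"train": len(train), "val": len(val), "test": len(test)},
        "split_membership": {
            "train": [samples[i].subject_id for i in tr_i],
            "val": [samples[i].subject_id for i in va_i],
            "test": [samples[i].subject_id for i in te_i],
        },
    }
    report["val_metrics"] = evaluate(model, val).to_dict()
    report["test_metrics"] = evaluate(model, test).to_dict()
    log.info("val acc %.3f / test acc %.3f",
             report["val_metrics"]["accuracy"], report["test_metrics"]["accuracy"])

    if cfg.run_cv:
        dev_idx = tr_i + va_i
        cv = cross_validate(
            [samples[i] for i in dev_idx],
            [feats[i] for i in dev_idx],
            model_cfg,
            train_cfg,
            folds=cfg.cv_folds,
            seed=cfg.seed,
        )
        report["cv"] = cv.to_dict()
        log.info("CV accuracy %.3f +/- %.3f", cv.mean_accuracy, cv.sd_accuracy)

    # ---- interpretability on the validation split ----
    feature_names = feats[0].feature_names
    node_names = cohort.atlas.names
    fid = fidelity_scores(model, val)
    report["fidelity"] = {
        f"L{l + 1}H{h + 1}": fid.scores[(l, h)] for l, h in sorted(fid.scores)
    }
    report["fidelity_baseline_accuracy"] = fid.baseline_accuracy
    try:
        sal = saliency_map(model, val, feature_names, node_names)
        salient = select_salient(sal, cfg.saliency_threshold)
        report["n_salient"] = len(salient)
        report["salient"] = [
            {"node": node_names[i], "feature": feature_names[j], "score": v}
            for i, j, v in salient[:50]
        ]
        pd.DataFrame(sal.values, index=node_names, columns=feature_names).to_csv(
            out_dir / "saliency.csv"
        )
        feat_by_id = {
            s.subject_id: f.values for s, f in zip(pre.subjects, feats)
        }
        corr = correlate_clinical(salient, pre, feat_by_id, cfg.clinical_alpha)
        report["clinical_correlations"] = [
            {**r, "node": node_names[r["node"]], "feature": feature_names[r["feature"]]}
            for r in corr.rows
            if r["significant"]
        ]
        att = attention_summary(model, val, cfg.attention_display_threshold)
        for (l, h), a in att.symmetric.items():
            np.savetxt(out_dir / f"attention_L{l + 1}H{h + 1}.csv", a, delimiter=",")
    except ValueError as err:  # no correctly predicted validation samples
        report["interpretability_error"] = str(err)

    model.save(out_dir / "model.npz")
    pd.DataFrame(
        {
            "train_loss": history.train_loss,
            "train_accuracy": history.train_accuracy,
            "val_loss": history.val_loss,
            "val_accuracy": history.val_accuracy,
        }
    ).to_csv(out_dir / "history.csv", index_label="epoch")
    (out_dir / "config.json").write_text(cfg.to_json())
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
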