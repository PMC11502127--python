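"""End-to-end workflow: normalise, select, optimise, train, ensemble, score.

Stages (leak-free default order):

1. stratified 80:20 train/test split;
2. per-gene standard scaling, statistics from the training split only;
3. CFS greedy merit search on the training split;
4. IGWO wrapper refinement of the CFS candidate set (training split only);
5. seven base learners fitted on the masked training genes, ranked on an
   inner validation split;
6. top-3 majority-voting and accuracy-weighted-averaging ensembles;
7. six-metric report for every learner and both ensembles on the held-out
   test split.

``paper_order=True`` instead applies scaling and feature selection to the
full matrix *before* splitting (the workflow some studies describe); this
lets the held-out samples influence selection and is off by default.

All stage outputs (masks, optimizer trace, per-model reports, predictions)
are written to a run directory as deterministic text files: re-running an
identical configuration reproduces them byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cfs import FeatureMask, cfs_select
from .ensemble import majority_vote, select_top_k, weighted_average
from .learners import train_base_learners
from .metrics import METRIC_ORDER, evaluate_predictions
from .preprocess import ExpressionMatrix, load_matrix, standard_scale, \
    stratified_split
from .synthetic import SyntheticConfig, make_microarray
from .wrapper import igwo_feature_select

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (with the code version)."""

    # input: either a file pair or a synthetic generator config
    matrix_path: str | None = None
    label_column_or_file: str = "label"
    synthetic: dict | None = None

    split_ratio: float = 0.8
    seed: int = 0
    paper_order: bool = False

    # CFS
    cfs_max_features: int = 50
    cfs_patience: int = 5

    # IGWO wrapper
    use_igwo: bool = True
    igwo_n_wolves: int = 30
    igwo_max_iter: int = 100
    igwo_alpha_weight: float = 0.99
    igwo_cv_folds: int = 5
    chaotic_map: str = "logistic"

    # learners / ensemble
    val_fraction: float = 0.2
    ensemble_k: int = 3

    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    config: RunConfig
    cfs_mask: FeatureMask
    final_mask: FeatureMask
    reports: list
    members: list
    weights: np.ndarray
    y_test: np.ndarray
    voting_pred: np.ndarray
    averaging_pred: np.ndarray
    metrics: dict = field(default_factory=dict)
    run_dir: Path | None = None


def _load_input(cfg: RunConfig) -> ExpressionMatrix:
    if cfg.matrix_path is not None:
        return load_matrix(cfg.matrix_path, cfg.label_column_or_file)
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        syn.setdefault("seed", cfg.seed)
        return make_microarray(SyntheticConfig(**syn)).matrix
    raise ValueError("config needs either matrix_path or synthetic settings")


def _select_features(train: ExpressionMatrix, cfg: RunConfig):
    cfs_mask = cfs_select(train, max_features=cfg.cfs_max_features,
                          patience=cfg.cfs_patience)
    if cfg.use_igwo and cfs_mask.n_selected > 1:
        final = igwo_feature_select(
            train, cfs_mask, n_wolves=cfg.igwo_n_wolves,
            max_iter=cfg.igwo_max_iter, alpha_weight=cfg.igwo_alpha_weight,
            cv_folds=cfg.igwo_cv_folds, chaotic_map=cfg.chaotic_map,
            seed=cfg.seed,
        )
    else:
        final = cfs_mask
    return cfs_mask, final


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full workflow; write the run directory if configured."""
    X = _load_input(cfg)

    if cfg.paper_order:
        Xs = standard_scale(X)
        cfs_mask, final_mask = _select_features(Xs, cfg)
        split = stratified_split(Xs, cfg.split_ratio, cfg.seed)
        train, test = split.train, split.test
    else:
        split = stratified_split(X, cfg.split_ratio, cfg.seed)
        train, test = standard_scale(split.train, test=split.test)
        cfs_mask, final_mask = _select_features(train, cfg)

    reports = train_base_learners(train, final_mask,
                                  val_fraction=cfg.val_fraction, seed=cfg.seed)
    members = select_top_k(reports, cfg.ensemble_k)
    accs = np.array([m.validation_accuracy for m in members])
    weights = accs / accs.sum() if accs.sum() > 0 else \
        np.full(len(members), 1.0 / len(members))

    member_labels = np.column_stack([m.model.predict_labels(test)
                                     for m in members])
    member_scores = np.column_stack([m.model.predict_scores(test)
                                     for m in members])
    voting_pred = majority_vote(member_labels)
    averaging_pred = weighted_average(member_scores, weights)

    metrics = {r.name: evaluate_predictions(test.labels,
                                            r.model.predict_labels(test))
               for r in reports}
    metrics["voting_ensemble"] = evaluate_predictions(test.labels, voting_pred)
    metrics["averaging_ensemble"] = evaluate_predictions(test.labels,
                                                         averaging_pred)

    result = PipelineResult(
        config=cfg, cfs_mask=cfs_mask, final_mask=final_mask,
        reports=reports, members=members, weights=weights,
        y_test=test.labels, voting_pred=voting_pred,
        averaging_pred=averaging_pred, metrics=metrics,
    )
    if cfg.out_dir is not None:
        result.run_dir = _write_run_dir(result, train, test)
    return result


def _write_run_dir(res: PipelineResult, train: ExpressionMatrix,
                   test: ExpressionMatrix) -> Path:
    out = Path(res.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "config.json", "w") as fh:
        json.dump(asdict(res.config), fh, indent=2, sort_keys=True)
        fh.write("\n")

    res.cfs_mask.to_text(out / "cfs_genes.txt", train)
    res.cfs_mask.to_json(out / "cfs_mask.json", train)
    res.final_mask.to_text(out / "selected_genes.txt", train)
    res.final_mask.to_json(out / "selected_mask.json", train)

    trace = getattr(res.final_mask, "trace", None)
    if trace is not None:
        with open(out / "igwo_trace.csv", "w") as fh:
            fh.write("iteration,best_fitness\n")
            for i, f in enumerate(trace):
                fh.write(f"{i + 1},{f!r}\n")

    with open(out / "learner_reports.json", "w") as fh:
        json.dump({r.name: r.validation_accuracy for r in res.reports},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")

    report = {name: {k: m.to_row()[k] for k in METRIC_ORDER}
              for name, m in res.metrics.items()}
    report["_ensemble_members"] = [m.name for m in res.members]
    report["_ensemble_weights"] = [float(w) for w in res.weights]
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    scores = np.column_stack([m.model.predict_scores(test)
                              for m in res.members]) @ res.weights
    with open(out / "predictions.csv", "w") as fh:
        fh.write("sample_id,true_label,voting_label,averaging_label,"
                 "combined_score\n")
        for sid, yt, v, a, s in zip(test.sample_ids, test.labels,
                                    res.voting_pred, res.averaging_pred,
                                    scores):
            fh.write(f"{sid},{yt},{v},{a},{s!r}\n")
    return out
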