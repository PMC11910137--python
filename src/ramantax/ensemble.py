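"""Two-step growth-stage-then-taxonomy classifier ensemble (G-T).

The G-step first predicts each cell's growth stage (Exp, S1, S2 or S3) from
its spectrum; the T-step then predicts taxonomy with a stage-specific model,
routed by the *predicted* stage.  G-step and T-step models have independent
DR + classifier setups; by default the T-step models are trained on the
ground-truth stage partitions of the training data (a flag switches to
predicted-stage partitions).

With a perfect (oracle) G-step the ensemble reduces exactly to the
stage-conditioned taxonomy evaluation; with a predicted G-step, routing
errors can only propagate, so joint accuracy is bounded by the oracle-gated
accuracy in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import (CVPlan, ModelCombo, Task, accuracy, fit_combo,
                        g_step, make_folds, t_given_stage)
from .classify import FittedClassifier, predict
from .dataset import STAGES, SpectraDataset
from .dimred import FittedDR, transform


class EnsembleError(ValueError):
    pass


@dataclass
class GTModel:
    """Fitted G-step model plus one fitted T-step model per growth stage."""

    g_model: tuple[FittedDR, FittedClassifier]
    t_models: dict[str, tuple[FittedDR, FittedClassifier]]
    t_label_field: str = "strain"


def _as_stage_map(t_combos) -> dict[str, ModelCombo]:
    if isinstance(t_combos, ModelCombo):
        return {s: t_combos for s in STAGES}
    out = dict(t_combos)
    if set(out) != set(STAGES):
        raise EnsembleError(
            f"t_combos must cover exactly the stages {STAGES}, got {sorted(out)}"
        )
    return out


def train_gt(ds: SpectraDataset, g_combo: ModelCombo, t_combos,
             plan: CVPlan | None = None, t_label_field: str = "strain",
             train_on_predicted: bool = False) -> GTModel:
    """Train the ensemble on a duo-labelled dataset.

    ``t_combos`` is either one combo used for all four stages or a
    stage -> combo map.  Every stage must be present in the data.
    """
    plan = plan or CVPlan()
    stage_map = _as_stage_map(t_combos)
    stages_present = set(ds.labels["stage"].unique())
    missing = [s for s in STAGES if s not in stages_present]
    if missing:
        raise EnsembleError(f"dataset is missing growth stages: {missing}")

    g_dr, g_clf, _ = fit_combo(g_combo, ds, g_step(), plan)

    if train_on_predicted:
        stage_for_partition = predict(g_clf, transform(g_dr, ds).features)
    else:
        stage_for_partition = ds.labels["stage"].to_numpy()

    t_models = {}
    t_task = Task("T_only") if t_label_field == "strain" else Task("genus")
    for s in STAGES:
        sub = ds.subset(stage_for_partition == s)
        t_dr, t_clf, _ = fit_combo(stage_map[s], sub, t_task, plan)
        t_models[s] = (t_dr, t_clf)
    return GTModel(g_model=(g_dr, g_clf), t_models=t_models,
                   t_label_field=t_label_field)


def predict_gt(model: GTModel, ds: SpectraDataset,
               oracle_stages: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Predict (stage, taxonomy) for every cell.

    Taxonomy for cell *i* comes from the T-step model of its predicted
    stage; passing ``oracle_stages`` forces the routing (used for
    oracle-gated evaluation).  Misrouting never crashes — every stage has a
    model.
    """
    g_dr, g_clf = model.g_model
    stage_pred = predict(g_clf, transform(g_dr, ds).features)
    routing = stage_pred if oracle_stages is None else np.asarray(oracle_stages)
    tax_pred = np.empty(ds.n_cells, dtype=object)
    for s in STAGES:
        mask = routing == s
        if not mask.any():
            continue
        t_dr, t_clf = model.t_models[s]
        tax_pred[mask] = predict(t_clf, transform(t_dr, ds.subset(mask)).features)
    unrouted = pd.isna(tax_pred)
    if unrouted.any():  # routing produced a label outside the 4 stages
        raise EnsembleError("G-step produced an unknown stage label")
    return stage_pred, tax_pred.astype(str)


@dataclass
class GTEvalResult:
    g_fold_accuracies: np.ndarray
    joint_fold_accuracies: np.ndarray
    oracle_fold_accuracies: np.ndarray
    per_stage_fold_accuracies: dict[str, np.ndarray]  # oracle-routed, by true stage
    confusion: pd.DataFrame  # stage confusion, rows = true, cols = predicted
    predictions: list[pd.DataFrame] = field(default_factory=list)

    @property
    def g_accuracy(self) -> float:
        return float(np.mean(self.g_fold_accuracies))

    @property
    def joint_accuracy(self) -> float:
        return float(np.mean(self.joint_fold_accuracies))

    @property
    def oracle_accuracy(self) -> float:
        return float(np.mean(self.oracle_fold_accuracies))


def evaluate_gt(ds: SpectraDataset, g_combo: ModelCombo, t_combos,
                plan: CVPlan, folds=None, t_label_field: str = "strain",
                train_on_predicted: bool = False) -> GTEvalResult:
    """Cross-validated ensemble evaluation with shared G/T folds.

    Folds stratify on the strain x stage combination so both steps see
    every class in every training fold; within a fold the same split feeds
    the G-step, the T-step and the joint accuracy, which keeps the joint
    metric well-defined per fold.  Also reports the oracle-gated accuracy
    (routing by true stage) and the stage confusion matrix summed over
    folds.
    """
    labels = ds.labels
    for s in STAGES:
        n_s = int((labels["stage"] == s).sum())
        if n_s < plan.n_folds:
            raise EnsembleError(
                f"stage {s} has {n_s} samples < n_folds {plan.n_folds}"
            )
    if folds is None:
        strata = (labels[t_label_field] + "/" + labels["stage"]).to_numpy()
        folds = make_folds(strata, plan)[0]

    y_tax = labels[t_label_field].to_numpy()
    y_stage = labels["stage"].to_numpy()

    g_accs, joint_accs, oracle_accs = [], [], []
    per_stage: dict[str, list[float]] = {s: [] for s in STAGES}
    conf = np.zeros((len(STAGES), len(STAGES)), dtype=int)
    preds = []
    for tr, te in folds:
        model = train_gt(ds.subset(tr), g_combo, t_combos, plan,
                         t_label_field=t_label_field,
                         train_on_predicted=train_on_predicted)
        test_ds = ds.subset(te)
        stage_pred, tax_pred = predict_gt(model, test_ds)
        _, tax_oracle = predict_gt(model, test_ds, oracle_stages=y_stage[te])

        g_accs.append(accuracy(stage_pred, y_stage[te]))
        joint_accs.append(accuracy(tax_pred, y_tax[te]))
        oracle_accs.append(accuracy(tax_oracle, y_tax[te]))
        for si, s in enumerate(STAGES):
            mask = y_stage[te] == s
            if mask.any():
                per_stage[s].append(accuracy(tax_oracle[mask], y_tax[te][mask]))
            for sj, s2 in enumerate(STAGES):
                conf[si, sj] += int(np.sum(mask & (stage_pred == s2)))
        preds.append(pd.DataFrame({
            "cell_id": test_ds.labels["cell_id"],
            "true_stage": y_stage[te], "pred_stage": stage_pred,
            "true_taxon": y_tax[te], "pred_taxon": tax_pred,
            "oracle_taxon": tax_oracle,
        }))
    return GTEvalResult(
        g_fold_accuracies=np.array(g_accs),
        joint_fold_accuracies=np.array(joint_accs),
        oracle_fold_accuracies=np.array(oracle_accs),
        per_stage_fold_accuracies={s: np.array(v) for s, v in per_stage.items()},
        confusion=pd.DataFrame(conf, index=list(STAGES), columns=list(STAGES)),
        predictions=preds,
    )
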