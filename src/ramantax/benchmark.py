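"""Evaluation engine: stratified k-fold CV, nested grid search, the
DR x classifier benchmark grid, output-dimensionality sweeps and the
genus-level reference-extension procedure.

Evaluation protocol: an outer (evaluation) CV estimates accuracy — by
default stratified 10-fold, so nine splits train and one tests.  When a
classifier carries a hyperparameter grid, an inner (optimization) CV
re-splits the outer training data and grid-searches the candidates; the
outer test split is never touched during tuning.  The DR is fitted on the
outer training split only, and hyperparameter candidates are scored on the
resulting reduced features (the DR is not refitted inside inner folds).

The default benchmark grid is the 6 DR methods x 9 classifiers = 54 model
combinations; the MLP (NN) is excluded from the default grid and enabled
with an explicit flag, mirroring its separate treatment in the benchmark
design.
"""

from __future__ import annotations

import itertools
import json
import pickle
import warnings
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import (CLASSIFIER_METHODS, ClassifierSpec, FittedClassifier,
                       fit_classifier, predict)
from .dataset import STAGES, SpectraDataset
from .dimred import DR_METHODS, DRSpec, FittedDR, capped_spec, fit_dr, transform

TASK_KINDS = ("T_only", "T_given_stage", "G_step", "genus")

_TASK_LABEL_FIELD = {
    "T_only": "strain",
    "T_given_stage": "strain",
    "G_step": "stage",
    "genus": "genus",
}


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class Task:
    """What to classify: taxonomy over everything (T_only), taxonomy within
    one true growth stage (T_given_stage), the growth stage itself (G_step),
    or genus-level taxonomy (genus)."""

    kind: str
    stage: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise BenchmarkError(f"unknown task kind {self.kind!r}")
        if (self.kind == "T_given_stage") != (self.stage is not None):
            raise BenchmarkError("T_given_stage needs a stage; others must not")
        if self.stage is not None and self.stage not in STAGES:
            raise BenchmarkError(f"unknown stage {self.stage!r}")

    @property
    def label_field(self) -> str:
        return _TASK_LABEL_FIELD[self.kind]

    @property
    def name(self) -> str:
        return f"{self.kind}:{self.stage}" if self.stage else self.kind


def t_only() -> Task:
    return Task("T_only")


def t_given_stage(stage: str) -> Task:
    return Task("T_given_stage", stage)


def g_step() -> Task:
    return Task("G_step")


def genus_task() -> Task:
    return Task("genus")


@dataclass(frozen=True)
class CVPlan:
    """Cross-validation layout.

    ``n_folds`` outer evaluation folds (default 10), ``n_repeats``
    independent repeats with reshuffled folds (10 for split-randomness
    studies), ``inner_folds`` for the optimization CV that re-splits the
    outer training data during grid search.
    """

    n_folds: int = 10
    n_repeats: int = 1
    stratify_by: str | None = None  # None = the task's label field
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise BenchmarkError("n_folds must be >= 2")
        if self.n_repeats < 1 or self.inner_folds < 2:
            raise BenchmarkError("n_repeats >= 1 and inner_folds >= 2 required")


@dataclass(frozen=True)
class ModelCombo:
    dr: DRSpec
    clf: ClassifierSpec

    @property
    def name(self) -> str:
        return f"{self.dr.method}+{self.clf.method}"


@dataclass
class FoldPrediction:
    test_index: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    chosen_params: dict
    model_hash: str


@dataclass
class EvalResult:
    combo: ModelCombo
    task: Task
    fold_accuracies: np.ndarray
    folds: list[FoldPrediction]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=0))


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def accuracy(predicted, truth) -> float:
    """Fraction of samples whose predicted label equals the true label."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise BenchmarkError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise BenchmarkError("cannot score an empty prediction")
    return float(np.mean(p == t))


def make_folds(strata, plan: CVPlan) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Disjoint, exhaustive (train, test) index pairs per repeat.

    Stratified on ``strata`` when every stratum has >= n_folds members;
    otherwise falls back to plain shuffled k-fold with a warning.
    """
    y = np.asarray(strata)
    n = y.size
    if n < plan.n_folds:
        raise BenchmarkError(f"{n} samples cannot fill {plan.n_folds} folds")
    out = []
    _, counts = np.unique(y, return_counts=True)
    stratified = counts.min() >= plan.n_folds
    if not stratified:
        warnings.warn(
            f"smallest stratum has {counts.min()} < {plan.n_folds} samples; "
            "falling back to unstratified folds", UserWarning, stacklevel=2,
        )
    for r in range(plan.n_repeats):
        seed = plan.seed + r
        if stratified:
            splitter = StratifiedKFold(n_splits=plan.n_folds, shuffle=True,
                                       random_state=seed)
        else:
            splitter = KFold(n_splits=plan.n_folds, shuffle=True,
                             random_state=seed)
        out.append([(tr.copy(), te.copy())
                    for tr, te in splitter.split(np.zeros(n), y)])
    return out


def restrict_folds(folds: list[tuple[np.ndarray, np.ndarray]],
                   keep: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Map global fold indices onto the subset selected by boolean ``keep``.

    Returned indices address rows of ``ds.subset(keep)``; order within each
    fold follows the original order.
    """
    keep = np.asarray(keep, dtype=bool)
    pos = np.full(keep.size, -1)
    pos[np.flatnonzero(keep)] = np.arange(keep.sum())
    out = []
    for tr, te in folds:
        out.append((pos[tr[keep[tr]]], pos[te[keep[te]]]))
    return out


def _candidates(grid: dict) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def nested_grid_search(clf_spec: ClassifierSpec, features: np.ndarray,
                       labels: np.ndarray, plan: CVPlan) -> dict:
    """Pick the grid candidate with the best inner-CV mean accuracy.

    Exact ties keep the first candidate in declared grid order.  Classifiers
    without a grid return ``{}`` untouched.
    """
    grid = clf_spec.tunable_grid
    if not grid:
        return {}
    cands = _candidates(grid)
    if len(cands) == 1:
        return cands[0]
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    k = min(plan.inner_folds, int(counts.min()), y.size)
    k = max(k, 2)
    splitter = (StratifiedKFold(k, shuffle=True, random_state=plan.seed + 1)
                if counts.min() >= k
                else KFold(k, shuffle=True, random_state=plan.seed + 1))
    splits = list(splitter.split(features, y))
    best, best_acc = None, -1.0
    for cand in cands:
        accs = []
        for tr, te in splits:
            fc = fit_classifier(clf_spec, features[tr], y[tr], hyperparams=cand)
            accs.append(accuracy(predict(fc, features[te]), y[te]))
        m = float(np.mean(accs))
        if m > best_acc:  # strict: first candidate wins ties
            best, best_acc = cand, m
    return best


def _model_hash(fdr: FittedDR, fc: FittedClassifier) -> str:
    dr_payload = {k: v for k, v in fdr.payload.items()}
    if "model" in dr_payload:  # sklearn PCA/KPCA object
        dr_payload["model"] = pickle.dumps(dr_payload["model"])
    return joblib.hash((fdr.spec.method, dr_payload,
                        pickle.dumps(fc.estimator), fc.hyperparams))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _prepare_task_ds(ds: SpectraDataset, task: Task) -> SpectraDataset:
    if task.kind == "T_given_stage":
        mask = (ds.labels["stage"] == task.stage).to_numpy()
        if not mask.any():
            raise BenchmarkError(f"no samples in stage {task.stage}")
        return ds.subset(mask)
    return ds


def fit_combo(combo: ModelCombo, ds: SpectraDataset, task: Task,
              plan: CVPlan, fitted_dr: FittedDR | None = None,
              ) -> tuple[FittedDR, FittedClassifier, dict]:
    """Fit DR (unless supplied pre-fitted) + tuned classifier on a dataset."""
    y = ds.labels[task.label_field].to_numpy()
    dr_spec = capped_spec(combo.dr, n_classes=np.unique(y).size,
                          n_channels=ds.n_channels, n_samples=ds.n_cells)
    if fitted_dr is None:
        fitted_dr = fit_dr(dr_spec, ds,
                           label_field=task.label_field if dr_spec.supervised
                           else None)
    Z = transform(fitted_dr, ds).features
    chosen = nested_grid_search(combo.clf, Z, y, plan)
    fc = fit_classifier(combo.clf, Z, y, hyperparams=chosen)
    return fitted_dr, fc, chosen


def evaluate_combo(combo: ModelCombo, ds: SpectraDataset, task: Task,
                   plan: CVPlan, folds=None,
                   dr_cache: dict | None = None) -> EvalResult:
    """Cross-validated accuracy of one DR+classifier pairing on one task.

    DR and classifier are fitted inside each training fold only.  ``folds``
    may supply precomputed (train, test) index pairs (one flat list, or one
    list per repeat); ``dr_cache`` shares fitted DRs between classifiers
    evaluated on identical folds.
    """
    tds = _prepare_task_ds(ds, task)
    y_all = tds.labels[task.label_field].to_numpy()
    if np.unique(y_all).size < 2:
        raise BenchmarkError(f"task {task.name} has fewer than 2 classes")

    if folds is None:
        strata = tds.labels[plan.stratify_by].to_numpy() if plan.stratify_by \
            else y_all
        folds_per_repeat = make_folds(strata, plan)
    elif folds and isinstance(folds[0], tuple):
        folds_per_repeat = [list(folds)]
    else:
        folds_per_repeat = [list(f) for f in folds]

    accs, fold_records = [], []
    for r, rep_folds in enumerate(folds_per_repeat):
        for f, (tr, te) in enumerate(rep_folds):
            train_ds = tds.subset(tr)
            fitted_dr = None
            key = None
            if dr_cache is not None:
                key = (combo.dr, task, r, f)
                fitted_dr = dr_cache.get(key)
            fitted_dr, fc, chosen = fit_combo(combo, train_ds, task, plan,
                                              fitted_dr=fitted_dr)
            if dr_cache is not None and key is not None:
                dr_cache[key] = fitted_dr
            Zte = transform(fitted_dr, tds.subset(te)).features
            y_pred = predict(fc, Zte)
            y_true = y_all[te]
            accs.append(accuracy(y_pred, y_true))
            fold_records.append(FoldPrediction(
                test_index=np.asarray(te), y_true=y_true, y_pred=y_pred,
                chosen_params=chosen, model_hash=_model_hash(fitted_dr, fc),
            ))
    return EvalResult(combo=combo, task=task,
                      fold_accuracies=np.array(accs), folds=fold_records)


# ---------------------------------------------------------------------------
# the benchmark grid
# ---------------------------------------------------------------------------


def enumerate_grid(include_nn: bool = False, dr_methods=None, clf_methods=None,
                   out_dim: int = 35, kernel_scale: float | None = None,
                   seed: int = 0) -> list[ModelCombo]:
    """All DR x classifier combinations; 6 x 9 = 54 by default (NN opt-in)."""
    drs = tuple(dr_methods) if dr_methods else DR_METHODS
    if clf_methods:
        clfs = tuple(clf_methods)
    else:
        clfs = tuple(m for m in CLASSIFIER_METHODS if include_nn or m != "NN")
    return [
        ModelCombo(DRSpec(d, out_dim=out_dim, kernel_scale=kernel_scale),
                   ClassifierSpec(c, seed=seed))
        for d in drs for c in clfs
    ]


@dataclass
class BenchmarkTable:
    results: list[EvalResult]
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for res in self.results:
            for i, fp in enumerate(res.folds):
                rows.append({
                    "dr": res.combo.dr.method,
                    "classifier": res.combo.clf.method,
                    "combo": res.combo.name,
                    "task": res.task.name,
                    "fold": i,
                    "accuracy": res.fold_accuracies[i],
                    "chosen_params": json.dumps(fp.chosen_params, sort_keys=True),
                })
        for combo_name, task_name, err in self.failures:
            rows.append({"dr": combo_name.split("+")[0],
                         "classifier": combo_name.split("+")[1],
                         "combo": combo_name, "task": task_name,
                         "fold": -1, "accuracy": np.nan,
                         "chosen_params": json.dumps({"error": err})})
        return pd.DataFrame(rows)


def run_grid(ds: SpectraDataset, tasks: list[Task], plan: CVPlan,
             include_nn: bool = False, out_dim: int = 35,
             stage_out_dim: int = 3, dr_methods=None,
             clf_methods=None) -> BenchmarkTable:
    """Evaluate every DR x classifier combination on each task.

    Taxonomy tasks use ``out_dim`` (default 35), the 4-class stage task
    ``stage_out_dim`` (default 3, the LDA maximum).  A failing combination
    is recorded and the run continues.  Fitted DRs are cached per
    (DR, task, fold) so classifiers sharing a DR do not refit it.
    """
    results, failures = [], []
    for task in tasks:
        dim = stage_out_dim if task.kind == "G_step" else out_dim
        combos = enumerate_grid(include_nn=include_nn, dr_methods=dr_methods,
                                clf_methods=clf_methods, out_dim=dim,
                                seed=plan.seed)
        dr_cache: dict = {}
        for combo in combos:
            try:
                results.append(evaluate_combo(combo, ds, task, plan,
                                              dr_cache=dr_cache))
            except Exception as exc:  # record, keep going
                failures.append((combo.name, task.name, str(exc)))
    return BenchmarkTable(results=results, failures=failures)


@dataclass
class DimSweepResult:
    per_dim: dict[int, EvalResult]
    selected_dim: int


def dim_sweep(ds: SpectraDataset, combo: ModelCombo, dims, plan: CVPlan,
              task: Task | None = None) -> DimSweepResult:
    """Accuracy as a function of DR output dimensionality.

    Infeasible dimensionalities (beyond the LDA class bound or the channel
    count) are skipped with a warning.  Selection rule: highest mean
    accuracy, ties to the smaller dimensionality.
    """
    task = task or t_only()
    tds = _prepare_task_ds(ds, task)
    n_classes = tds.labels[task.label_field].nunique()
    per_dim = {}
    for d in dims:
        spec = replace(combo.dr, out_dim=int(d))
        feasible = capped_spec(spec, n_classes, tds.n_channels, tds.n_cells)
        if feasible.out_dim != spec.out_dim:
            warnings.warn(f"skipping infeasible out_dim {d} for "
                          f"{combo.dr.method}", UserWarning, stacklevel=2)
            continue
        per_dim[int(d)] = evaluate_combo(replace(combo, dr=spec), ds, task, plan)
    if not per_dim:
        raise BenchmarkError("no feasible dimensionality in the sweep")
    best = min(per_dim, key=lambda d: (-per_dim[d].mean, d))
    return DimSweepResult(per_dim=per_dim, selected_dim=best)


# ---------------------------------------------------------------------------
# environmental reference extension
# ---------------------------------------------------------------------------


def extend_reference(base: SpectraDataset, extra: SpectraDataset,
                     quota: int, seed: int = 0,
                     level: str = "genus") -> SpectraDataset:
    """Merge two libraries and re-balance every ``level`` class to ``quota``.

    Subsampling is without replacement; if a class holds fewer than
    ``quota`` spectra it is resampled with replacement under a warning.
    Deterministic given the seed.
    """
    if base.grid != extra.grid:
        raise BenchmarkError("reference datasets must share a wavenumber grid")
    if quota < 1:
        raise BenchmarkError("quota must be >= 1")
    X = np.vstack([base.intensities, extra.intensities])
    labels = pd.concat([base.labels, extra.labels], ignore_index=True)
    y = labels[level].to_numpy()
    rng = np.random.default_rng(seed)
    keep = []
    for cls in sorted(pd.unique(y)):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            raise BenchmarkError(f"{level} {cls!r} has no spectra")
        if idx.size >= quota:
            keep.append(rng.choice(idx, size=quota, replace=False))
        else:
            warnings.warn(
                f"{level} {cls!r} has {idx.size} < quota {quota} spectra; "
                "sampling with replacement", UserWarning, stacklevel=2)
            keep.append(rng.choice(idx, size=quota, replace=True))
    sel = np.concatenate(keep)
    out_labels = labels.iloc[sel].reset_index(drop=True)
    # resampling with replacement may duplicate cell_ids; disambiguate
    if out_labels["cell_id"].duplicated().any():
        out_labels = out_labels.copy()
        out_labels["cell_id"] = [
            f"{cid}#{i}" for i, cid in enumerate(out_labels["cell_id"])
        ]
    return SpectraDataset(grid=base.grid, intensities=X[sel],
                          labels=out_labels,
                          meta={"extended_reference": {"quota": quota,
                                                       "level": level,
                                                       "seed": seed}})
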