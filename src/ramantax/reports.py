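"""Tabular (and optional heatmap) reports over benchmark result tables.

All reports are pure functions of a results TSV as written by
``BenchmarkTable.to_dataframe()``: columns ``dr, classifier, combo, task,
fold, accuracy, chosen_params``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    pass


_REQUIRED = {"dr", "classifier", "combo", "task", "fold", "accuracy"}


def _check(df: pd.DataFrame) -> pd.DataFrame:
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise SchemaError(f"results table missing columns: {sorted(missing)}")
    return df[df["fold"] >= 0]  # drop failure marker rows


def grid_table(df: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy pivoted classifier (rows) x DR method (columns)."""
    df = _check(df)
    return df.pivot_table(index="classifier", columns="dr",
                          values="accuracy", aggfunc="mean")


def per_stage_table(df: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy per task (stage) per combo."""
    df = _check(df)
    return df.pivot_table(index="combo", columns="task",
                          values="accuracy", aggfunc="mean")


def confusion_table(y_true, y_pred, normalize: bool = False) -> pd.DataFrame:
    """Confusion counts (or row-normalized rates), rows = true labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise SchemaError("y_true and y_pred must be equal-length and nonempty")
    classes = sorted(set(y_true) | set(y_pred))
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=float)
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    if normalize:
        M = M / np.maximum(M.sum(axis=1, keepdims=True), 1)
    return pd.DataFrame(M, index=classes, columns=classes)


def render_report(results_path, kind: str, out_path) -> pd.DataFrame:
    """Read a results TSV, pivot it, write the rendered table as TSV."""
    df = pd.read_csv(results_path, sep="\t")
    if kind == "grid_table":
        table = grid_table(df)
    elif kind == "per_stage":
        table = per_stage_table(df)
    elif kind == "confusion":
        need = {"true", "predicted"}
        if not need <= set(df.columns):
            raise SchemaError("confusion report needs 'true'/'predicted' columns")
        table = confusion_table(df["true"], df["predicted"])
    else:
        raise SchemaError(f"unknown report kind {kind!r}")
    table.to_csv(out_path, sep="\t")
    return table


def plot_grid(table: pd.DataFrame, path) -> None:
    """Optional heatmap of a grid table (headless-safe)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * table.shape[1] + 2,
                                    0.5 * table.shape[0] + 2))
    im = ax.imshow(table.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=45, ha="right")
    ax.set_yticks(range(table.shape[0]), table.index)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            v = table.iat[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.3f}", ha="center", va="center",
                        color="white", fontsize=8)
    fig.colorbar(im, ax=ax, label="mean accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
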