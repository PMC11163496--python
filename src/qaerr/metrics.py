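"""One-vs-rest classification metrics, ROC/AUC, confusion matrix, t-SNE.

Conventions: *accuracy* is the overall multiclass fraction correct and is
reported identically for every class; precision/F1 with a zero denominator
are defined as 0 and logged; a class absent from the true labels has its
metrics flagged undefined (NaN) rather than silently zeroed.  The
confusion matrix is row-normalized over true labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.metrics import auc as sk_auc, roc_curve

from qaerr.plans import ERROR_FAMILIES

log = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Per-class and macro-averaged one-vs-rest classification metrics."""

    per_class: pd.DataFrame          # index: class; columns: metric
    macro: dict[str, float]
    auc: dict[str, float]
    roc: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    confusion: np.ndarray            # row-normalized over true labels
    confusion_counts: np.ndarray
    classes: tuple[str, ...]
    undefined_classes: tuple[str, ...] = ()


def _one_vs_rest_counts(y_true: np.ndarray, y_pred: np.ndarray,
                        k: int) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_pred == k) & (y_true == k)))
    fp = int(np.sum((y_pred == k) & (y_true != k)))
    fn = int(np.sum((y_pred != k) & (y_true == k)))
    tn = int(np.sum((y_pred != k) & (y_true != k)))
    return tp, fp, fn, tn


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        log.info("zero denominator for %s; reporting 0", what)
        return 0.0
    return num / den


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray,
                    classes: tuple[str, ...] = ERROR_FAMILIES) -> MetricsReport:
    """Score class-probability rows against integer or string labels.

    ``probabilities`` is (N, n_classes) with rows on the simplex; ``labels``
    are indices into ``classes`` (or the class names themselves).
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        labels = np.array([classes.index(l) for l in labels])
    n_classes = len(classes)
    if probabilities.shape != (labels.shape[0], n_classes):
        raise ValueError("probabilities/labels shape mismatch")

    y_pred = probabilities.argmax(axis=1)
    accuracy = float(np.mean(y_pred == labels))

    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (labels, y_pred), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(row_sums > 0, counts / row_sums, np.nan)

    rows = []
    aucs: dict[str, float] = {}
    rocs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    undefined = []
    for k, name in enumerate(classes):
        present = bool(np.any(labels == k))
        if not present:
            undefined.append(name)
            rows.append({m: np.nan for m in
                         ("accuracy", "precision", "sensitivity",
                          "specificity", "f1")})
            aucs[name] = np.nan
            rocs[name] = (np.array([]), np.array([]))
            continue
        tp, fp, fn, tn = _one_vs_rest_counts(labels, y_pred, k)
        precision = _safe_div(tp, tp + fp, f"precision[{name}]")
        sensitivity = _safe_div(tp, tp + fn, f"sensitivity[{name}]")
        specificity = _safe_div(tn, tn + fp, f"specificity[{name}]")
        f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity,
                       f"f1[{name}]")
        rows.append({"accuracy": accuracy, "precision": precision,
                     "sensitivity": sensitivity, "specificity": specificity,
                     "f1": f1})
        fpr, tpr, _ = roc_curve(labels == k, probabilities[:, k])
        rocs[name] = (fpr, tpr)
        aucs[name] = float(sk_auc(fpr, tpr))

    per_class = pd.DataFrame(rows, index=list(classes))
    macro = {m: float(np.nanmean(per_class[m])) for m in per_class.columns}
    macro["auc"] = float(np.nanmean([v for v in aucs.values()]))
    return MetricsReport(
        per_class=per_class,
        macro=macro,
        auc=aucs,
        roc=rocs,
        confusion=confusion,
        confusion_counts=counts,
        classes=tuple(classes),
        undefined_classes=tuple(undefined),
    )


def tsne_embed(embeddings: np.ndarray, seed: int = 0,
               perplexity: float | None = None) -> np.ndarray:
    """Project feature vectors to 2-D with t-SNE (seeded, reproducible)."""
    embeddings = np.asarray(embeddings, dtype=float)
    n = embeddings.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.allclose(embeddings, embeddings[0]):
        log.warning("degenerate identical embeddings; t-SNE layout arbitrary")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(embeddings)


def plot_report(report: MetricsReport, out_dir) -> list[str]:
    """Write ROC and confusion-matrix figures; returns the file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 4))
    for name in report.classes:
        fpr, tpr = report.roc[name]
        if fpr.size:
            ax.plot(fpr, tpr, label=f"{name} (AUC {report.auc[name]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    p = out_dir / "roc.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    paths.append(str(p))

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(report.confusion, vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(len(report.classes)), report.classes, rotation=45,
                  fontsize=7)
    ax.set_yticks(range(len(report.classes)), report.classes, fontsize=7)
    for i in range(len(report.classes)):
        for j in range(len(report.classes)):
            v = report.confusion[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    p = out_dir / "confusion.png"
    fig.savefig(p, dpi=150, bbox_inches="tight")
    plt.close(fig)
    paths.append(str(p))
    return paths
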