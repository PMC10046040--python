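"""Quantitative evaluation of 2-D embeddings.

Embedding quality is summarized by two families of measures:

* Separability — SVMs (linear and RBF kernels) fitted on training
  embeddings and scored with Cohen's kappa on the train and test splits.
  Kappa corrects for chance agreement, which matters because the category
  sizes are unbalanced.
* Cluster structure — k-means over k = 2..50; the k maximizing the mean
  silhouette score is reported as the cluster count C.

Methods are compared with a chi-square test on their correct/incorrect
counts; when the omnibus test is significant, the best method is compared
pairwise against the others with Bonferroni-adjusted p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.svm import SVC


def cohens_kappa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement rate; p_e the agreement expected from the
    marginal label frequencies.  Returns 0 when p_e = 1 (both raters
    constant).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    if len(y_true) < 2:
        raise ValueError("need at least 2 examples")
    n = len(y_true)
    p_o = np.mean(y_true == y_pred)
    classes = np.union1d(y_true, y_pred)
    p_e = sum(
        np.mean(y_true == c) * np.mean(y_pred == c) for c in classes
    )
    if p_e >= 1.0 - 1e-15:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def svm_separability(
    fit_embedding: np.ndarray,
    fit_labels: np.ndarray,
    eval_embedding: np.ndarray,
    eval_labels: np.ndarray,
    kernel: str = "rbf",
) -> float:
    """Kappa of an SVM fitted on one split and evaluated on another.

    The SVM is a fixed measuring stick, not a tuned classifier: C = 1 and
    the default bandwidth heuristic for the RBF kernel.
    """
    fit_labels = np.asarray(fit_labels)
    if len(np.unique(fit_labels)) < 2:
        raise ValueError("fit split must contain at least two classes")
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")
    clf = SVC(kernel=kernel, C=1.0, gamma="scale")
    clf.fit(fit_embedding, fit_labels)
    return cohens_kappa(eval_labels, clf.predict(eval_embedding))


def cluster_count(
    embedding: np.ndarray,
    k_min: int = 2,
    k_max: int = 50,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Silhouette-selected k-means cluster count.

    Runs seeded k-means (k-means++ init, 10 restarts) for each k in
    [k_min, k_max] and returns the k with the best mean silhouette score
    (ties broken toward smaller k) together with the full curve.
    """
    n = len(embedding)
    if n <= k_max:
        warnings.warn(
            f"only {n} points; restricting k_max from {k_max} to {n - 1}"
        )
        k_max = n - 1
    curve: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, init="k-means++", random_state=seed)
        labels = km.fit_predict(embedding)
        if len(np.unique(labels)) < 2:
            curve[k] = -1.0
            continue
        curve[k] = float(silhouette_score(embedding, labels))
    best = max(curve, key=lambda k: (curve[k], -k))
    return best, curve


def compare_methods(
    predictions: dict[str, np.ndarray],
    truth: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Chi-square comparison of classification outcomes across methods.

    Builds the methods x {correct, incorrect} contingency table and runs an
    omnibus chi-square test (no continuity correction, plain sum of
    (O-E)^2/E).  If significant at ``alpha``, the method with the most
    correct predictions is compared pairwise against each other method,
    with Bonferroni adjustment over the post hoc pairs.
    """
    truth = np.asarray(truth)
    names = list(predictions)
    if len(names) < 2:
        raise ValueError("need at least two methods to compare")
    counts = {}
    for name, pred in predictions.items():
        pred = np.asarray(pred)
        if len(pred) != len(truth):
            raise ValueError(f"prediction length mismatch for {name}")
        c = int(np.sum(pred == truth))
        counts[name] = (c, len(truth) - c)
    table = np.array([counts[n] for n in names])
    if np.all(table[:, 0] == table[0, 0]):
        omnibus_stat, omnibus_p = 0.0, 1.0
    else:
        omnibus_stat, omnibus_p = chi2_contingency(table, correction=False)[:2]
    result = {
        "counts": counts,
        "omnibus": {"statistic": float(omnibus_stat), "p": float(omnibus_p)},
        "posthoc": {},
    }
    if omnibus_p < alpha:
        best = max(names, key=lambda n: counts[n][0])
        others = [n for n in names if n != best]
        m = len(others)
        for other in others:
            sub = np.array([counts[best], counts[other]])
            stat, p = chi2_contingency(sub, correction=False)[:2]
            result["posthoc"][f"{best}_vs_{other}"] = {
                "statistic": float(stat),
                "p_raw": float(p),
                "p_adjusted": float(min(1.0, m * p)),
            }
    return result


@dataclass
class EvaluationReport:
    """Kappa per kernel and split, silhouette-selected cluster counts, and
    optional between-method comparisons."""

    kappa: dict[str, float] = field(default_factory=dict)  # "<kernel>_<split>"
    cluster_count: dict[str, int] = field(default_factory=dict)  # per split
    silhouette_curve: dict[str, dict[int, float]] = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "cluster_count": self.cluster_count,
            "silhouette_curve": {
                split: {str(k): v for k, v in curve.items()}
                for split, curve in self.silhouette_curve.items()
            },
            "comparisons": self.comparisons,
        }


def evaluate_embedding(
    train_embedding: np.ndarray,
    train_labels: np.ndarray,
    test_embedding: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    k_max: int = 50,
    seed: int = 0,
) -> EvaluationReport:
    """Full protocol: SVM kappa (both kernels, both splits) and cluster counts."""
    report = EvaluationReport()
    splits = {"train": (train_embedding, train_labels)}
    if test_embedding is not None:
        splits["test"] = (test_embedding, test_labels)
    for kernel in ("linear", "rbf"):
        for split, (emb, lab) in splits.items():
            report.kappa[f"{kernel}_{split}"] = svm_separability(
                train_embedding, train_labels, emb, lab, kernel=kernel
            )
    for split, (emb, _) in splits.items():
        c, curve = cluster_count(emb, k_max=k_max, seed=seed)
        report.cluster_count[split] = c
        report.silhouette_curve[split] = curve
    return report
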