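"""Evaluation machinery: stratified resampling, confusion matrices with
per-site sensitivity/specificity, cumulative top-n accuracy,
confidence-stratified accuracy, accuracy vs fraction called, and
subgroup Fisher tests.

Accuracy confidence intervals use the Wilson score interval at 95%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.proportion import proportion_confint

from .ensemble import ClassificationResult

__all__ = [
    "stratified_kfold",
    "stratified_split",
    "confusion_stats",
    "cumulative_topn",
    "confidence_stratified_accuracy",
    "accuracy_vs_fraction_called",
    "subgroup_fisher",
    "EvaluationReport",
    "evaluate_results",
]


def stratified_kfold(
    labels: Sequence[str], k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold index partition.

    Per-site proportions are preserved within one sample per fold.
    Raises when any site has fewer than k samples.
    """
    labels = np.asarray(labels, dtype=object)
    counts = pd.Series(labels).value_counts()
    small = counts[counts < k]
    if not small.empty:
        raise ValueError(
            f"sites with fewer than k={k} samples: {sorted(small.index)}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def stratified_split(
    labels: Sequence[str], test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic class-proportional train/test index split."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels, dtype=object)
    idx = np.arange(len(labels))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=labels, random_state=seed
    )
    return np.sort(train), np.sort(test)


# ---------------------------------------------------------------------------


def confusion_stats(
    predicted: Sequence[str], truth: Sequence[str], sites: Sequence[str] | None = None
) -> dict:
    """Confusion matrix with per-site sensitivity and specificity.

    sensitivity(s) = correctly predicted s / actual s;
    specificity(s) = other-site samples not predicted s / actual non-s.
    A site with no actual samples has undefined (None) sensitivity.
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    if sites is None:
        sites = sorted(set(truth) | set(predicted))
    sites = list(sites)
    confusion = pd.DataFrame(0, index=sites, columns=sites, dtype=int)
    for t, p in zip(truth, predicted):
        confusion.loc[t, p] += 1
    total = len(truth)
    per_site = {}
    for s in sites:
        actual = int(confusion.loc[s].sum())
        correct = int(confusion.loc[s, s])
        non_s = total - actual
        pred_s_wrong = int(confusion[s].sum()) - correct
        per_site[s] = {
            "n": actual,
            "sensitivity": None if actual == 0 else correct / actual,
            "specificity": None if non_s == 0 else (non_s - pred_s_wrong) / non_s,
        }
    overall = float(np.trace(confusion.to_numpy())) / total if total else float("nan")
    return {"confusion": confusion, "per_site": per_site, "overall_accuracy": overall}


def cumulative_topn(
    results: Sequence[ClassificationResult],
    truth: Sequence[str],
    train_frequencies: dict[str, int] | None = None,
) -> dict:
    """Cumulative accuracy of the top-n ranked sites, n = 1..K.

    Also returns the accuracy of two baselines: sites ranked by their
    (training) frequency, and the uniform-random expectation n/K.
    """
    if len(results) != len(truth):
        raise ValueError("results and truth lengths differ")
    sites = [s for s, _ in results[0].ranked_sites]
    K = len(sites)
    n_samples = len(results)
    model_curve = []
    for n in range(1, K + 1):
        hits = sum(
            1
            for r, t in zip(results, truth)
            if t in {s for s, _ in r.ranked_sites[:n]}
        )
        model_curve.append(hits / n_samples)
    if train_frequencies is None:
        train_frequencies = dict(pd.Series(list(truth)).value_counts())
    freq_rank = sorted(sites, key=lambda s: (-train_frequencies.get(s, 0), s))
    freq_curve = [
        sum(1 for t in truth if t in freq_rank[:n]) / n_samples
        for n in range(1, K + 1)
    ]
    random_curve = [n / K for n in range(1, K + 1)]
    return {
        "sites": sites,
        "model": model_curve,
        "by_frequency": freq_curve,
        "random": random_curve,
        "frequency_source": "training" if train_frequencies else "test",
    }


def wilson_ci(correct: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(correct, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def confidence_stratified_accuracy(
    results: Sequence[ClassificationResult],
    truth: Sequence[str],
    bin_width: float = 0.1,
) -> list[dict]:
    """Accuracy by confidence-score bin with 95% Wilson intervals.

    Bins cover [0, 1] with the given width; the last bin is closed at 1.
    Empty bins are reported with n = 0.
    """
    edges = np.arange(0, 1 + bin_width / 2, bin_width)
    if edges[-1] < 1:
        edges = np.append(edges, 1.0)
    conf = np.array([r.confidence for r in results])
    correct = np.array(
        [r.predicted_site == t for r, t in zip(results, truth)], dtype=bool
    )
    bins = []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        mask = (conf >= lo) & ((conf < hi) if i < len(edges) - 2 else (conf <= hi))
        n = int(mask.sum())
        k = int(correct[mask].sum())
        bins.append(
            {
                "lo": float(lo),
                "hi": float(hi),
                "n": n,
                "accuracy": None if n == 0 else k / n,
                "ci": None if n == 0 else wilson_ci(k, n),
            }
        )
    return bins


def accuracy_vs_fraction_called(
    results: Sequence[ClassificationResult],
    truth: Sequence[str],
    target_accuracy: float = 0.95,
) -> dict:
    """Accuracy over the most-confident fraction of samples.

    Samples are ordered by confidence descending (ties keep stable
    input order); the curve entry at fraction f = i/n is the accuracy
    over the i most confident samples. ``fraction_at_target`` is the
    largest fraction whose prefix accuracy still meets the target
    (0 when even the single most confident sample fails it).
    """
    n = len(results)
    if n != len(truth):
        raise ValueError("results and truth lengths differ")
    conf = np.array([r.confidence for r in results])
    order = np.argsort(-conf, kind="stable")
    correct = np.array(
        [results[i].predicted_site == truth[i] for i in order], dtype=float
    )
    cum_acc = np.cumsum(correct) / np.arange(1, n + 1)
    curve = []
    for i in range(n):
        k = int(cum_acc[i] * (i + 1) + 0.5)
        lo, hi = wilson_ci(k, i + 1)
        curve.append(
            {
                "fraction": (i + 1) / n,
                "accuracy": float(cum_acc[i]),
                "ci": (lo, hi),
            }
        )
    qualifying = np.flatnonzero(cum_acc >= target_accuracy)
    fraction_at_target = float((qualifying[-1] + 1) / n) if qualifying.size else 0.0
    return {
        "curve": curve,
        "target_accuracy": target_accuracy,
        "fraction_at_target": fraction_at_target,
    }


def subgroup_fisher(
    correct: Sequence[bool], in_group: Sequence[bool]
) -> tuple[float, float, float]:
    """Compare accuracy inside vs outside a subgroup.

    Builds the 2x2 (correct/incorrect x in/out) table and returns
    (accuracy_in, accuracy_out, two-sided Fisher exact p).
    """
    correct = np.asarray(correct, dtype=bool)
    in_group = np.asarray(in_group, dtype=bool)
    if correct.shape != in_group.shape:
        raise ValueError("length mismatch")
    n_in, n_out = int(in_group.sum()), int((~in_group).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError("both subgroup and complement must be non-empty")
    a = int((correct & in_group).sum())
    b = int((correct & ~in_group).sum())
    table = [[a, b], [n_in - a, n_out - b]]
    _, p = fisher_exact(table, alternative="two-sided")
    return a / n_in, b / n_out, float(p)


# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Bundle of every evaluation output for one result set."""

    overall_accuracy: float
    confusion: pd.DataFrame
    per_site: dict
    topn_curve: dict
    confidence_bins: list[dict]
    called_fraction: dict
    n_samples: int
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "overall_accuracy": self.overall_accuracy,
            "n_samples": self.n_samples,
            "confusion": {
                "sites": list(self.confusion.index),
                "counts": self.confusion.to_numpy().tolist(),
            },
            "per_site": self.per_site,
            "topn_curve": self.topn_curve,
            "confidence_bins": self.confidence_bins,
            "called_fraction": {
                "target_accuracy": self.called_fraction["target_accuracy"],
                "fraction_at_target": self.called_fraction["fraction_at_target"],
                "curve": self.called_fraction["curve"],
            },
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=1)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(self.to_json())
        self.confusion.to_csv(out_dir / "confusion.tsv", sep="\t")
        pd.DataFrame(self.per_site).T.to_csv(out_dir / "per_site.tsv", sep="\t")


def evaluate_results(
    results: Sequence[ClassificationResult],
    truth: Sequence[str],
    train_frequencies: dict[str, int] | None = None,
    bin_width: float = 0.1,
    target_accuracy: float = 0.95,
    metadata: dict | None = None,
) -> EvaluationReport:
    truth = list(truth)
    predicted = [r.predicted_site for r in results]
    cs = confusion_stats(predicted, truth)
    return EvaluationReport(
        overall_accuracy=cs["overall_accuracy"],
        confusion=cs["confusion"],
        per_site=cs["per_site"],
        topn_curve=cumulative_topn(results, truth, train_frequencies),
        confidence_bins=confidence_stratified_accuracy(results, truth, bin_width),
        called_fraction=accuracy_vs_fraction_called(results, truth, target_accuracy),
        n_samples=len(truth),
        metadata=metadata or {},
    )
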