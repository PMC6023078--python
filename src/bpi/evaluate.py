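"""Evaluation machinery: confusion matrices, per-subject accuracy,
cross-subject aggregation with outlier-set omission, and the ED-vs-DTW
comparison.

The study design this mirrors: each subject contributes one live set of 5
repetitions per class (4 classes -> 20 live patterns).  A confusion matrix
is built per subject; accuracy is the percentage of correct classifications
out of the evaluated live patterns.  Sets flagged as outliers (subjects
unable to recall their chosen pattern — human judgment recorded as
metadata, never auto-detected) are omitted at the set level before
aggregation.  Aggregate accuracy is reported both as the mean of
per-subject percentages and as the pooled trace/total, since "average rate"
is ambiguous between the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "ConfusionMatrix",
    "SubjectScore",
    "MetricComparison",
    "confusion_matrix",
    "subject_accuracy",
    "aggregate_subjects",
    "compare_metrics",
    "plot_comparison",
]


@dataclass
class ConfusionMatrix:
    """True-class x predicted-class counts."""

    counts: np.ndarray  # (n_classes, n_classes) non-negative ints
    class_ids: List[int]
    n_omitted_sets: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_ids)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if np.any(self.counts < 0) or self.n_omitted_sets < 0:
            raise ValueError("counts and n_omitted_sets must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.class_ids, name="true"),
            columns=pd.Index(self.class_ids, name="predicted"),
        )


@dataclass
class SubjectScore:
    subject_id: int
    percent_correct: float
    per_class_correct: Dict[int, int]
    metric_name: str


def confusion_matrix(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    class_ids: Sequence[int],
    n_omitted_sets: int = 0,
) -> ConfusionMatrix:
    """Count table ``counts[t][p] = #{i : true_i = t, pred_i = p}``."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label sequences must have equal length")
    class_ids = list(class_ids)
    unknown = set(true_labels.tolist()) | set(predicted_labels.tolist())
    unknown -= set(class_ids)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} outside class_ids {class_ids}")
    counts = _sk_confusion_matrix(true_labels, predicted_labels, labels=class_ids)
    return ConfusionMatrix(counts, class_ids, n_omitted_sets)


def subject_accuracy(
    cm: ConfusionMatrix, subject_id: int = 0, metric_name: str = ""
) -> SubjectScore:
    """Percent correct = 100 * trace / total evaluated live patterns."""
    if cm.total == 0:
        raise ValueError("empty evaluation: confusion matrix has no counts")
    per_class = {cid: int(cm.counts[k, k]) for k, cid in enumerate(cm.class_ids)}
    return SubjectScore(
        subject_id=subject_id,
        percent_correct=100.0 * cm.n_correct / cm.total,
        per_class_correct=per_class,
        metric_name=metric_name,
    )


def per_class_rates(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class success/error percentages (rows sum to 100 each)."""
    rows = []
    for k, cid in enumerate(cm.class_ids):
        row_sum = int(cm.counts[k].sum())
        correct = int(cm.counts[k, k])
        success = 100.0 * correct / row_sum if row_sum else np.nan
        rows.append(
            {
                "class_id": cid,
                "n_evaluated": row_sum,
                "n_correct": correct,
                "success_pct": success,
                "error_pct": 100.0 - success if row_sum else np.nan,
            }
        )
    return pd.DataFrame(rows)


def aggregate_subjects(
    cms: Sequence[ConfusionMatrix],
    scores: Optional[Sequence[SubjectScore]] = None,
) -> Tuple[ConfusionMatrix, Dict]:
    """Element-wise sum of per-subject confusion matrices plus a summary.

    Outlier omission has already happened per subject (flagged sets never
    enter their subject's matrix); ``n_omitted_sets`` accumulates here.
    Summary reports both the mean of per-subject percentages and the pooled
    trace/total percentage.
    """
    if len(cms) == 0:
        raise ValueError("no subjects to aggregate")
    class_ids = cms[0].class_ids
    for cm in cms[1:]:
        if cm.class_ids != class_ids:
            raise ValueError(
                f"incompatible subjects: class ids {cm.class_ids} != {class_ids}"
            )
    total_counts = np.sum([cm.counts for cm in cms], axis=0)
    n_omitted = int(sum(cm.n_omitted_sets for cm in cms))
    cumulative = ConfusionMatrix(total_counts, class_ids, n_omitted)
    summary = {
        "n_subjects": len(cms),
        "n_evaluated": cumulative.total,
        "n_omitted_sets": n_omitted,
        "pooled_percent_correct": 100.0 * cumulative.n_correct / cumulative.total,
        "per_class": per_class_rates(cumulative),
    }
    if scores is not None:
        summary["mean_percent_correct"] = float(
            np.mean([s.percent_correct for s in scores])
        )
    return cumulative, summary


@dataclass
class MetricComparison:
    """Paired ED/DTW evaluation of the same datasets."""

    per_class: pd.DataFrame  # one row per class per metric
    mean_accuracy: Dict[str, float]  # mean of per-subject percentages
    pooled_accuracy: Dict[str, float]  # cumulative trace/total
    cumulative: Dict[str, ConfusionMatrix]
    subject_scores: Dict[str, List[SubjectScore]]
    n_omitted_sets: int = 0


def evaluate_subject_predictions(
    true_by_class: Mapping[int, Sequence[int]],
    pred_by_class: Mapping[int, Sequence[int]],
    class_ids: Sequence[int],
    outlier_flags: Optional[Mapping[int, bool]] = None,
    omit_flagged: bool = True,
) -> ConfusionMatrix:
    """Build one subject's confusion matrix, omitting flagged live sets
    (all repetitions of a flagged class) as whole units."""
    outlier_flags = outlier_flags or {}
    true_all: List[int] = []
    pred_all: List[int] = []
    n_omitted = 0
    for cid in class_ids:
        if cid not in true_by_class:
            continue
        if omit_flagged and outlier_flags.get(cid, False):
            n_omitted += 1
            continue
        true_all.extend(true_by_class[cid])
        pred_all.extend(pred_by_class[cid])
    return confusion_matrix(true_all, pred_all, class_ids, n_omitted)


def compare_metrics(
    datasets: Iterable,
    config=None,
    metrics: Sequence[str] = ("ed", "dtw"),
    omit_flagged: bool = True,
) -> MetricComparison:
    """Run the full pipeline under each metric on identical inputs.

    ``datasets`` is an iterable of :class:`bpi.synth.SubjectDataset` (a
    generator is fine: recordings are processed to envelopes subject by
    subject and then discarded).  Envelopes are computed once and shared by
    both metrics, so the comparison is paired exactly.
    """
    from .pipeline import PipelineConfig, process_samples  # deferred: avoids cycle
    from .classify import BreathPatternClassifier

    config = config or PipelineConfig()
    cms: Dict[str, List[ConfusionMatrix]] = {m: [] for m in metrics}
    scores: Dict[str, List[SubjectScore]] = {m: [] for m in metrics}
    n_subjects = 0
    class_ids: Optional[List[int]] = None

    for ds in datasets:
        n_subjects += 1
        class_ids = ds.class_ids
        train_X, train_y = [], []
        for cid in class_ids:
            for rec in ds.train_recordings[cid]:
                train_X.append(process_samples(rec, config))
                train_y.append(cid)
        live_env: Dict[int, List[np.ndarray]] = {}
        for cid in class_ids:
            live_env[cid] = [
                process_samples(rec, config) for rec in ds.live_recordings[cid]
            ]
        train_X = np.stack(train_X)
        train_y = np.asarray(train_y)
        for m in metrics:
            clf = BreathPatternClassifier(metric=m, band_width=config.band_width)
            clf.fit(train_X, train_y)
            true_by_class = {cid: [cid] * len(live_env[cid]) for cid in class_ids}
            pred_by_class = {
                cid: clf.predict(np.stack(live_env[cid])).tolist() for cid in class_ids
            }
            cm = evaluate_subject_predictions(
                true_by_class, pred_by_class, class_ids, ds.outlier_flags, omit_flagged
            )
            cms[m].append(cm)
            scores[m].append(subject_accuracy(cm, ds.subject_id, m.upper()))

    if n_subjects == 0:
        raise ValueError("no datasets supplied")

    rows = []
    cumulative: Dict[str, ConfusionMatrix] = {}
    mean_acc: Dict[str, float] = {}
    pooled_acc: Dict[str, float] = {}
    for m in metrics:
        cum, summary = aggregate_subjects(cms[m], scores[m])
        cumulative[m] = cum
        mean_acc[m] = summary["mean_percent_correct"]
        pooled_acc[m] = summary["pooled_percent_correct"]
        pc = summary["per_class"].copy()
        pc.insert(0, "metric", m.upper())
        rows.append(pc)
    per_class = pd.concat(rows, ignore_index=True)
    return MetricComparison(
        per_class=per_class,
        mean_accuracy=mean_acc,
        pooled_accuracy=pooled_acc,
        cumulative=cumulative,
        subject_scores=scores,
        n_omitted_sets=int(sum(cm.n_omitted_sets for cm in cumulative.values())),
    )


def plot_comparison(comparison: MetricComparison, path=None):
    """Grouped bar chart of per-class success rates for ED vs DTW."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = comparison.per_class
    classes = sorted(df["class_id"].unique())
    metrics = list(dict.fromkeys(df["metric"]))
    width = 0.8 / len(metrics)
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, m in enumerate(metrics):
        sub = df[df["metric"] == m].set_index("class_id")
        vals = [sub.loc[c, "success_pct"] for c in classes]
        ax.bar(np.arange(len(classes)) + k * width, vals, width, label=m)
    ax.set_xticks(np.arange(len(classes)) + width / 2)
    ax.set_xticklabels([f"class {c}" for c in classes])
    ax.set_ylabel("classification success [%]")
    ax.set_ylim(0, 105)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
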