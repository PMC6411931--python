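"""AUC / AUPRC metrics and the replicated-negatives benchmark harness.

``roc_auc`` equals the Mann-Whitney statistic (ties credited 0.5);
``pr_auc`` is the non-interpolated step-rule area under the
precision-recall curve with tied scores processed as one group (the
``average_precision`` convention).  Both delegate to scikit-learn; their
test suite cross-checks them against brute-force enumeration oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

if TYPE_CHECKING:  # pragma: no cover
    from berbp.models import BindingModel


@dataclass(frozen=True)
class EvalResult:
    model_id: str
    dataset_id: str
    replicate: int
    auc: float
    auprc: float
    n_pos: int
    n_neg: int


@dataclass
class BenchmarkDataset:
    """Positive features plus a pool to draw negative replicates from."""

    dataset_id: str
    X_pos: np.ndarray
    neg_pool: np.ndarray
    standardized: bool = False


def _check_binary(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int), scores


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """P(score_pos > score_neg) + 0.5 * P(tie)."""
    labels, scores = _check_binary(np.asarray(labels), np.asarray(scores))
    return float(roc_auc_score(labels, scores))


def pr_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Step-rule area under the precision-recall curve (no interpolation)."""
    labels, scores = _check_binary(np.asarray(labels), np.asarray(scores))
    return float(average_precision_score(labels, scores))


def run_benchmark(
    models: Sequence["BindingModel"],
    datasets: Sequence[BenchmarkDataset],
    n_negative_replicates: int = 5,
    seed: int = 0,
    n_neg: int | None = None,
) -> tuple[list[EvalResult], pd.DataFrame]:
    """Evaluate each model on each dataset over replicated negative draws.

    Each replicate pairs the full positive set with a fresh seeded sample
    from the negative pool (without replacement when the pool is large
    enough; the sample size defaults to the positive count).  Returns the
    per-replicate results plus a mean/sd summary table.
    """
    from berbp.models import StandardizationError

    results: list[EvalResult] = []
    for model in models:
        for ds in datasets:
            if ds.standardized != model.standardized:
                raise StandardizationError(
                    f"dataset {ds.dataset_id!r} and model {model.model_id!r} "
                    "disagree on feature standardization"
                )
            n_pos = ds.X_pos.shape[0]
            want = n_neg if n_neg is not None else n_pos
            pos_scores = model.forest.vote_fractions(ds.X_pos)
            for rep in range(n_negative_replicates):
                rng = np.random.RandomState((seed, rep))
                replace = want > ds.neg_pool.shape[0]
                pick = rng.choice(ds.neg_pool.shape[0], size=want, replace=replace)
                neg_scores = model.forest.vote_fractions(ds.neg_pool[pick])
                labels = np.concatenate([np.ones(n_pos, int), np.zeros(want, int)])
                scores = np.concatenate([pos_scores, neg_scores])
                results.append(
                    EvalResult(
                        model_id=model.model_id,
                        dataset_id=ds.dataset_id,
                        replicate=rep,
                        auc=roc_auc(labels, scores),
                        auprc=pr_auc(labels, scores),
                        n_pos=n_pos,
                        n_neg=want,
                    )
                )
    table = pd.DataFrame([r.__dict__ for r in results])
    summary = (
        table.groupby(["model_id", "dataset_id"], sort=False)[["auc", "auprc"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    return results, summary


def write_eval_tsv(
    results: Sequence[EvalResult], summary: pd.DataFrame, path: str | Path
) -> None:
    """Write per-replicate rows followed by '# summary' mean/sd rows."""
    table = pd.DataFrame([r.__dict__ for r in results])
    with open(path, "w") as fh:
        table.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        fh.write("# summary\n")
        summary.to_csv(fh, sep="\t", index=False, float_format="%.6f")
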