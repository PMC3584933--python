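"""CAFA-style evaluation of GO-term predictions.

Precision and recall are computed on *propagated* term sets: both the
predicted and the true GO terms of a target are expanded with all their
ancestors up to the namespace root before comparison, so predicting a
correct-but-general ancestor earns partial credit. For one target,

    P = |prop(pred) ∩ prop(true)| / |prop(pred)|
    R = |prop(pred) ∩ prop(true)| / |prop(true)|

and curve points are means over targets.

Two selection regimes generate curves:

* **top-n** (n = 1..20): predictions are grouped by identical
  confidence; all terms in the n highest-scoring groups are selected,
  so a tie group enters or leaves as a whole and the selected count can
  exceed n. Fractional (average) ranks are available for reporting.
* **threshold sweep** (t = 0..1 step 0.01): predictions with
  confidence ≥ t are selected. The break-even point is the grid point
  where precision and recall are closest (larger t wins ties).

Semantic-similarity curves replace exact-match overlap with the DAG
path-overlap score: each selected predicted term is scored against its
best-matching true term; the *average* curve means over predicted terms
then over targets, the *best* curve takes the per-target maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import AnnotationMap, Prediction
from .go_dag import GoDag, propagate, semantic_similarity, term_depth
from .predict import PredictionSet

__all__ = [
    "PrPoint",
    "tied_average_ranks",
    "top_n_select",
    "pr_single_target",
    "pr_curve_topn",
    "pr_curve_threshold",
    "break_even",
    "similarity_scores",
    "average_depth",
    "write_curve_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_N_RANGE = range(1, 21)
DEFAULT_T_GRID = tuple(round(0.01 * i, 2) for i in range(101))


@dataclass(frozen=True)
class PrPoint:
    """One point of a precision-recall curve.

    ``selector`` is n in top-n mode or t in threshold mode;
    ``n_targets`` counts the targets contributing to the averages.
    """

    selector: float
    precision: float
    recall: float
    n_targets: int


def tied_average_ranks(scores: Sequence[float]) -> list[float]:
    """Fractional (average) ranks of scores in descending order.

    Tied scores share the mean of the ranks they occupy, e.g.
    (0.9, 0.8, 0.8) → (1, 2.5, 2.5). Ranks always sum to n(n+1)/2.
    """
    if len(scores) == 0:
        return []
    return list(rankdata([-s for s in scores], method="average"))


def top_n_select(predictions: Sequence[Prediction], n: int) -> set[str]:
    """GO terms in the n highest-confidence tie groups.

    ``predictions`` must be sorted by confidence descending. Whole tie
    groups are taken, so the selection may exceed n terms; if there are
    fewer than n groups, everything is selected.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out: set[str] = set()
    groups_seen = 0
    prev_conf: float | None = None
    for p in predictions:
        if prev_conf is None or p.confidence != prev_conf:
            groups_seen += 1
            if groups_seen > n:
                break
            prev_conf = p.confidence
        out.add(p.go_term)
    return out


def pr_single_target(
    predicted_terms: set[str], true_terms: set[str], dag: GoDag
) -> tuple[float, float]:
    """Propagated precision and recall for one target.

    An empty predicted set yields (0, 0); an empty true set raises (the
    target should have been excluded upstream).
    """
    if not true_terms:
        raise ValueError("target has no true GO terms")
    if not predicted_terms:
        return 0.0, 0.0
    pred = propagate(dag, predicted_terms)
    true = propagate(dag, true_terms)
    correct = len(pred & true)
    return correct / len(pred), correct / len(true)


def _evaluable(
    predictions: PredictionSet, truth: AnnotationMap
) -> list[str]:
    targets = []
    for targ, true_terms in truth.items():
        if not true_terms:
            logger.warning("%s: empty truth set, excluded from averages", targ)
            continue
        targets.append(targ)
    return sorted(targets)


def pr_curve_topn(
    predictions: PredictionSet,
    truth: AnnotationMap,
    dag: GoDag,
    n_range: Iterable[int] = DEFAULT_N_RANGE,
    *,
    count_empty: bool = True,
) -> list[PrPoint]:
    """Average precision-recall over targets for each top-n cut.

    Targets without selected predictions contribute (0, 0) by default
    (``count_empty=False`` drops them from the averages instead).
    """
    targets = _evaluable(predictions, truth)
    if not targets:
        raise ValueError("no evaluable targets (empty truth table)")
    points = []
    for n in n_range:
        ps, rs = [], []
        for targ in targets:
            entry = predictions.entries.get(targ, [])
            selected = top_n_select(entry, n) if entry else set()
            if not selected and not count_empty:
                continue
            p, r = pr_single_target(selected, truth[targ], dag)
            ps.append(p)
            rs.append(r)
        points.append(
            PrPoint(float(n), float(np.mean(ps)) if ps else 0.0,
                    float(np.mean(rs)) if rs else 0.0, len(ps))
        )
    return points


def pr_curve_threshold(
    predictions: PredictionSet,
    truth: AnnotationMap,
    dag: GoDag,
    t_grid: Iterable[float] = DEFAULT_T_GRID,
    *,
    inclusive: bool = True,
    count_empty: bool = True,
) -> list[PrPoint]:
    """Average precision-recall for each confidence threshold t.

    Selection keeps predictions with confidence ≥ t (``inclusive=False``
    switches to strict >, dropping confidence-1.0 terms at t = 1).
    """
    targets = _evaluable(predictions, truth)
    if not targets:
        raise ValueError("no evaluable targets (empty truth table)")
    points = []
    for t in t_grid:
        ps, rs = [], []
        for targ in targets:
            entry = predictions.entries.get(targ, [])
            if inclusive:
                selected = {p.go_term for p in entry if p.confidence >= t}
            else:
                selected = {p.go_term for p in entry if p.confidence > t}
            if not selected and not count_empty:
                continue
            p, r = pr_single_target(selected, truth[targ], dag)
            ps.append(p)
            rs.append(r)
        points.append(
            PrPoint(float(t), float(np.mean(ps)) if ps else 0.0,
                    float(np.mean(rs)) if rs else 0.0, len(ps))
        )
    return points


def break_even(curve: Sequence[PrPoint]) -> tuple[float, float, float, float]:
    """Grid point where precision and recall are closest.

    Returns (t, precision, recall, (P+R)/2). Ties on |P − R| go to the
    larger selector; no interpolation between grid points. Points where
    both precision and recall are exactly 0 (thresholds above every
    confidence, where the equality is vacuous) are ignored unless the
    whole curve is zero.
    """
    if not curve:
        raise ValueError("empty curve")
    candidates = [pt for pt in curve if (pt.precision, pt.recall) != (0.0, 0.0)]
    if not candidates:
        candidates = list(curve)
    best = min(candidates,
               key=lambda pt: (abs(pt.precision - pt.recall), -pt.selector))
    return (best.selector, best.precision, best.recall,
            (best.precision + best.recall) / 2.0)


def similarity_scores(
    predictions: PredictionSet,
    truth: AnnotationMap,
    dag: GoDag,
    k_range: Iterable[int] = DEFAULT_N_RANGE,
) -> tuple[list[tuple[int, float]], list[tuple[int, float]]]:
    """Semantic-similarity curves over top-k selections.

    For each k and target, every selected predicted term is scored as
    its maximum path-overlap similarity to any true term. The *average*
    curve means those per-term scores within a target and then over
    targets; the *best* curve averages the per-target maximum. Targets
    with no selected predictions contribute 0 to both.
    """
    targets = _evaluable(predictions, truth)
    avg_curve, best_curve = [], []
    for k in k_range:
        avgs, bests = [], []
        for targ in targets:
            entry = predictions.entries.get(targ, [])
            selected = top_n_select(entry, k) if entry else set()
            if not selected:
                avgs.append(0.0)
                bests.append(0.0)
                continue
            per_term = [
                max(semantic_similarity(dag, g, t) for t in truth[targ])
                for g in sorted(selected)
            ]
            avgs.append(float(np.mean(per_term)))
            bests.append(float(np.max(per_term)))
        avg_curve.append((k, float(np.mean(avgs)) if avgs else 0.0))
        best_curve.append((k, float(np.mean(bests)) if bests else 0.0))
    return avg_curve, best_curve


def average_depth(
    predicted_terms: set[str], dag: GoDag, convention: str = "shortest"
) -> float:
    """Mean node-count depth of a term set (root depth = 1)."""
    if not predicted_terms:
        raise ValueError("empty term set")
    return float(
        np.mean([term_depth(dag, t, convention) for t in predicted_terms])
    )


def write_curve_tsv(curve: Sequence[PrPoint], stream: IO[str]) -> None:
    """Write a curve as TSV (selector, precision, recall, n_targets)."""
    stream.write("selector\tprecision\trecall\tn_targets\n")
    for pt in curve:
        stream.write(
            f"{pt.selector:g}\t{pt.precision:.6f}\t{pt.recall:.6f}\t{pt.n_targets}\n"
        )


def plot_curve(curves: Mapping[str, Sequence[PrPoint]], path: str) -> None:
    """Optional matplotlib plot of one or more PR curves (recall vs precision)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.plot([p.recall for p in curve], [p.precision for p in curve],
                marker=".", label=label)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
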