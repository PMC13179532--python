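"""Cluster-to-direction labelling and validation statistics.

The three fitted clusters are interpreted as reactions to the left, to the
right, or "centre" (no decision): the centre cluster is the one whose mean
is nearest the origin, and the two lateral clusters are mapped to left/right
so as to maximise agreement with the speaker side over the training trials.
Per feature set and data split the module builds 3 (predicted class) x 2
(speaker side) contingency tables and derives:

* the correct-decision rate ("specificity" in the study's usage): the
  fraction of non-centre decisions whose direction matches the speaker side;
* an exact one-sided binomial test of that fraction against guessing at 50%;
* the decision rate (fraction of trials with a non-centre prediction);
* cross-feature-set averages and head/gaze decision combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .em import MixtureModel3, responsibilities

CLASSES = ("left", "centre", "right")
SIDES = ("left", "right")


@dataclass(frozen=True)
class ClusterLabelling:
    """Bijective map cluster index -> {left, centre, right}."""

    mapping: tuple[str, str, str]   # class of cluster 0, 1, 2
    decision_axis: int              # feature axis encoding left/right

    def cluster_of(self, cls: str) -> int:
        return self.mapping.index(cls)


@dataclass
class DirectionTable:
    """3x2 contingency counts: predicted class (rows) x speaker side (cols)."""

    counts: np.ndarray              # (3, 2) ints, rows ordered as CLASSES
    split: str
    feature_set: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts, int)
        if self.counts.shape != (3, 2) or (self.counts < 0).any():
            raise ValueError("counts must be a nonnegative 3x2 table")

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    @property
    def n_decisions(self) -> int:
        """Trials with a non-centre (left or right) prediction."""
        return int(self.counts.sum() - self.counts[CLASSES.index("centre")].sum())

    @property
    def n_correct(self) -> int:
        """Non-centre predictions matching the speaker side."""
        return int(self.counts[CLASSES.index("left"), SIDES.index("left")]
                   + self.counts[CLASSES.index("right"), SIDES.index("right")])


class LabellingError(ValueError):
    """Cluster geometry does not admit an unambiguous labelling."""


def label_clusters(model: MixtureModel3, X_train: np.ndarray,
                   sides_train) -> ClusterLabelling:
    """Assign {left, centre, right} to the three clusters.

    Centre = smallest-norm mean (ties within 1e-9 are an error).  The
    decision axis is the feature axis along which the two lateral means
    differ most.  The lateral clusters take whichever left/right mapping
    agrees best with the speaker sides of the training trials they claim;
    exact ties fall back to the sign convention (negative coordinate on the
    decision axis -> left).
    """
    norms = np.linalg.norm(model.means, axis=1)
    order = np.argsort(norms)
    if abs(norms[order[0]] - norms[order[1]]) < 1e-9:
        raise LabellingError("two clusters tie for the centre role")
    centre = int(order[0])
    a, b = (int(i) for i in range(3) if i != centre)
    axis = int(np.argmax(np.abs(model.means[a] - model.means[b])))

    sides = np.asarray(sides_train)
    assign = np.argmax(responsibilities(np.asarray(X_train, float), model), axis=1)

    def agreement(left_cluster: int, right_cluster: int) -> int:
        return int(np.sum((assign == left_cluster) & (sides == "left"))
                   + np.sum((assign == right_cluster) & (sides == "right")))

    ag_ab = agreement(a, b)   # a=left, b=right
    ag_ba = agreement(b, a)
    if ag_ab > ag_ba:
        left, right = a, b
    elif ag_ba > ag_ab:
        left, right = b, a
    else:
        left, right = (a, b) if model.means[a, axis] < model.means[b, axis] else (b, a)
    mapping = [""] * 3
    mapping[centre] = "centre"
    mapping[left] = "left"
    mapping[right] = "right"
    return ClusterLabelling(mapping=tuple(mapping), decision_axis=axis)


def predict(model: MixtureModel3, labelling: ClusterLabelling,
            points: np.ndarray) -> np.ndarray:
    """Class of the argmax-responsibility cluster for each point."""
    X = np.atleast_2d(np.asarray(points, float))
    assign = np.argmax(responsibilities(X, model), axis=1)
    return np.asarray([labelling.mapping[k] for k in assign])


def contingency(predictions, sides, split: str, feature_set: str) -> DirectionTable:
    predictions = list(predictions)
    sides = list(sides)
    if len(predictions) != len(sides):
        raise ValueError("predictions and sides differ in length")
    counts = np.zeros((3, 2), int)
    for p, s in zip(predictions, sides):
        counts[CLASSES.index(p), SIDES.index(s)] += 1
    return DirectionTable(counts=counts, split=split, feature_set=feature_set)


def specificity(table: DirectionTable) -> float | None:
    """Correct-decision rate; None when no non-centre decision was made."""
    if table.n_decisions == 0:
        return None
    return table.n_correct / table.n_decisions


def binomial_p_one_sided(k_correct: int, n_decisions: int,
                         p0: float = 0.5) -> float:
    """Exact upper-tail binomial probability P(X >= k | n, p0)."""
    if not (isinstance(k_correct, (int, np.integer))
            and isinstance(n_decisions, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n_decisions < 1 or not 0 <= k_correct <= n_decisions:
        raise ValueError(f"invalid k={k_correct}, n={n_decisions}")
    return float(stats.binom.sf(k_correct - 1, n_decisions, p0))


def average_correct_rate(tables) -> int | None:
    """Unweighted mean specificity across feature sets, as a whole percent.

    Tables with no decisions are excluded with a warning; None if all are
    undefined.
    """
    vals = []
    for t in tables:
        s = specificity(t)
        if s is None:
            warnings.warn(f"feature set {t.feature_set!r} ({t.split}) made no "
                          "decisions; excluded from the average")
        else:
            vals.append(s)
    if not vals:
        return None
    return int(round(100.0 * float(np.mean(vals))))


def combine_decisions(pred_head, pred_gaze, conflict_policy: str = "gaze"
                      ) -> tuple[np.ndarray, dict]:
    """Merge head-movement and gaze predictions trial by trial.

    If exactly one source decides (non-centre), its decision is used; if both
    agree, the shared class; if they conflict, the ``conflict_policy`` source
    ("gaze" or "head") wins and the conflict is counted.
    """
    if conflict_policy not in ("gaze", "head"):
        raise ValueError("conflict_policy must be 'gaze' or 'head'")
    ph = np.asarray(pred_head)
    pg = np.asarray(pred_gaze)
    if ph.shape != pg.shape:
        raise ValueError("prediction lists differ in length")
    combined = []
    n_both = n_agree = n_conflict = 0
    for h, g in zip(ph, pg):
        if h == "centre" and g == "centre":
            combined.append("centre")
        elif h == "centre":
            combined.append(g)
        elif g == "centre":
            combined.append(h)
        else:
            n_both += 1
            if h == g:
                n_agree += 1
                combined.append(h)
            else:
                n_conflict += 1
                combined.append(g if conflict_policy == "gaze" else h)
    combined = np.asarray(combined)
    stats_d = {
        "n_decisions_head": int(np.sum(ph != "centre")),
        "n_decisions_gaze": int(np.sum(pg != "centre")),
        "n_decisions_combined": int(np.sum(combined != "centre")),
        "n_both": n_both,
        "n_agree": n_agree,
        "n_conflict": n_conflict,
    }
    return combined, stats_d


def table_report(table: DirectionTable) -> dict:
    """Per-table statistics block (rounded as in the written report:
    percentages to the nearest integer, p to 3 significant figures)."""
    s = specificity(table)
    rep = {
        "split": table.split,
        "feature_set": table.feature_set,
        "counts": table.counts.tolist(),
        "n_trials": table.n_trials,
        "n_decisions": table.n_decisions,
        "n_correct": table.n_correct,
        "decision_rate": (table.n_decisions / table.n_trials
                          if table.n_trials else None),
        "specificity": s,
        "specificity_pct": None if s is None else int(round(100 * s)),
        "p_one_sided": None,
    }
    if table.n_decisions > 0:
        p = binomial_p_one_sided(table.n_correct, table.n_decisions)
        rep["p_one_sided"] = float(f"{p:.3g}")
    return rep
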