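"""Three-class score thresholding and binary confusion metrics.

Scores are banded into likely_benign / ambiguous / likely_pathogenic with the
published cutoffs 0.340 and 0.564 (benign strictly below the lower cutoff,
pathogenic at or above the upper one; the score 0.5637 is therefore still
ambiguous).  Against binary clinical labels the three-way prediction is
reduced to a confusion table under one of two policies:

* ``ambiguous_as_error`` (default): an ambiguous call on a pathogenic-labeled
  variant is a false negative, on a benign-labeled variant a false positive;
* ``ambiguous_excluded``: ambiguous calls are removed before counting and
  tallied separately.

PPV, TPR, F1 and MCC come from the confusion table; aucROC is rank-based
with midrank tie handling on the raw scores.  Zero-denominator metrics
return 0 and are flagged as degenerate instead of raising, so sparse subsets
do not abort batch runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .io import ClinicalLabel, ScoreClass


@dataclass(frozen=True)
class ThresholdScheme:
    """Cutoffs delimiting the three score bands."""

    benign_cutoff: float = 0.340
    pathogenic_cutoff: float = 0.564

    def __post_init__(self) -> None:
        if not 0.0 < self.benign_cutoff < self.pathogenic_cutoff < 1.0:
            raise ValueError(
                "require 0 < benign_cutoff < pathogenic_cutoff < 1, got "
                f"{self.benign_cutoff}/{self.pathogenic_cutoff}"
            )


DEFAULT_SCHEME = ThresholdScheme()


def classify_score(
    score: float, scheme: ThresholdScheme = DEFAULT_SCHEME
) -> ScoreClass:
    """Band a score: benign < benign_cutoff <= ambiguous < pathogenic_cutoff <= pathogenic."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score < scheme.benign_cutoff:
        return ScoreClass.LIKELY_BENIGN
    if score < scheme.pathogenic_cutoff:
        return ScoreClass.AMBIGUOUS
    return ScoreClass.LIKELY_PATHOGENIC


class AmbiguousPolicy(str, Enum):
    AS_ERROR = "ambiguous_as_error"
    EXCLUDED = "ambiguous_excluded"


@dataclass
class ConfusionTable:
    """Binary confusion counts plus the ambiguous tallies kept aside."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_ambig_on_pathogenic_label: int = 0
    n_ambig_on_benign_label: int = 0
    policy: AmbiguousPolicy = AmbiguousPolicy.AS_ERROR

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn",
                     "n_ambig_on_pathogenic_label", "n_ambig_on_benign_label"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_total(self) -> int:
        if self.policy is AmbiguousPolicy.EXCLUDED:
            return (self.n_evaluated + self.n_ambig_on_pathogenic_label
                    + self.n_ambig_on_benign_label)
        return self.n_evaluated


def build_confusion(
    pairs: Iterable[tuple[ClinicalLabel, ScoreClass]],
    policy: AmbiguousPolicy = AmbiguousPolicy.AS_ERROR,
) -> ConfusionTable:
    """Tally (clinical label, three-way prediction) pairs under a policy."""
    ct = ConfusionTable(policy=policy)
    for label, predicted in pairs:
        if label is ClinicalLabel.PATHOGENIC:
            if predicted is ScoreClass.LIKELY_PATHOGENIC:
                ct.tp += 1
            elif predicted is ScoreClass.AMBIGUOUS:
                if policy is AmbiguousPolicy.EXCLUDED:
                    ct.n_ambig_on_pathogenic_label += 1
                else:
                    ct.fn += 1
            else:
                ct.fn += 1
        else:
            if predicted is ScoreClass.LIKELY_BENIGN:
                ct.tn += 1
            elif predicted is ScoreClass.AMBIGUOUS:
                if policy is AmbiguousPolicy.EXCLUDED:
                    ct.n_ambig_on_benign_label += 1
                else:
                    ct.fp += 1
            else:
                ct.fp += 1
    return ct


@dataclass(frozen=True)
class MetricsValues:
    """Point metrics from a confusion table.

    ``degenerate`` names the metrics whose denominator vanished; those are
    reported as 0 by convention.
    """

    ppv: float
    tpr: float
    f1: float
    mcc: float
    degenerate: frozenset[str] = frozenset()


def compute_metrics(ct: ConfusionTable) -> MetricsValues:
    """PPV = TP/(TP+FP), TPR = TP/(TP+FN), F1 harmonic mean, MCC from the
    standard four-term formula.  Any zero denominator flags the metric."""
    tp, fp, tn, fn = ct.tp, ct.fp, ct.tn, ct.fn
    degenerate: set[str] = set()

    if tp + fp == 0:
        ppv = 0.0
        degenerate.add("ppv")
    else:
        ppv = tp / (tp + fp)
    if tp + fn == 0:
        tpr = 0.0
        degenerate.add("tpr")
    else:
        tpr = tp / (tp + fn)
    if ppv + tpr == 0:
        f1 = 0.0
        degenerate.add("f1")
    else:
        f1 = 2 * ppv * tpr / (ppv + tpr)

    denom_sq = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        mcc = 0.0
        degenerate.add("mcc")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom_sq)
    return MetricsValues(ppv, tpr, f1, mcc, frozenset(degenerate))


def _as_positive(label) -> bool:
    if isinstance(label, ClinicalLabel):
        return label is ClinicalLabel.PATHOGENIC
    if isinstance(label, str):
        return ClinicalLabel(label) is ClinicalLabel.PATHOGENIC
    return bool(label)


def auc_roc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based ROC AUC with midrank tie handling; pathogenic is positive.

    Equals P(score_pathogenic > score_benign) + 1/2 P(equal).  Raises on
    single-class input, where the AUC is undefined.
    """
    y = np.asarray([_as_positive(l) for l in labels], dtype=bool)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "AUC undefined: input contains a single class "
            f"({n_pos} pathogenic, {n_neg} benign)"
        )
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """One benchmark row: metrics plus length-normalized mutation frequencies."""

    set_name: str
    n_proteins: int
    n_mutations: int
    n_evaluated: int
    ppv: float
    tpr: float
    f1: float
    auc_roc: float
    mcc: float
    f_cv_benign: float
    f_cv_pathogenic: float
    f_am_benign: float
    f_am_pathogenic: float
    degenerate: frozenset[str] = field(default_factory=frozenset)

    #: Column order used by the TSV report writer.
    COLUMNS = (
        "set", "n_protein", "n_mutation", "n_evaluated",
        "PPV", "TPR", "F1", "aucROC", "MCC",
        "f_CV_benign", "f_CV_pathogenic", "f_AM_benign", "f_AM_pathogenic",
        "degenerate",
    )

    def to_row(self) -> list[str]:
        return [
            self.set_name,
            str(self.n_proteins),
            str(self.n_mutations),
            str(self.n_evaluated),
            f"{self.ppv:.3f}",
            f"{self.tpr:.3f}",
            f"{self.f1:.3f}",
            f"{self.auc_roc:.3f}",
            f"{self.mcc:.3f}",
            f"{self.f_cv_benign:.3f}",
            f"{self.f_cv_pathogenic:.3f}",
            f"{self.f_am_benign:.3f}",
            f"{self.f_am_pathogenic:.3f}",
            ",".join(sorted(self.degenerate)),
        ]
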