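"""Median-rank consensus over multiple binding-prediction methods.

Raw scores from different predictors live on incompatible scales, so
each method's scores are first converted to percentile ranks within
the evaluated peptide set (rank 1 = best after orientation, divided by
n, average ranks on ties).  The consensus score of a peptide is the
median of its per-method percentile ranks; lower is better.  The
combination is invariant to monotone rescaling of any member's raw
scores and to the order in which methods are listed.

Two refinements from the benchmarking study are provided: a
leave-one-out table quantifying each method's contribution to the
consensus (removing a weak member can *improve* the consensus), and a
best-subset consensus that restricts the members to a configured
primary list with per-allele fallback substitution for methods that
are unavailable for some molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ValidationError
from .evaluation import roc_auc

logger = logging.getLogger(__name__)


@dataclass
class MethodScores:
    """One method's raw scores over a fixed peptide list."""

    method: str
    scores: np.ndarray
    orientation: str = "lower-is-better"
    available: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValidationError("scores must be a 1-D array")


def percentile_rank(scores, orientation: str = "lower-is-better") -> np.ndarray:
    """Percentile ranks in (0, 1]: rank among the set (1 = best) over n.

    Ties get average ranks; the result is invariant under strictly
    monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 1:
        raise ValidationError("need at least one score")
    if orientation == "lower-is-better":
        keyed = scores
    elif orientation == "higher-is-better":
        keyed = -scores
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    return stats.rankdata(keyed, method="average") / scores.size


def _usable(method_scores: list[MethodScores]) -> list[MethodScores]:
    usable = []
    for m in method_scores:
        if not m.available:
            logger.info("method %s unavailable for this allele: excluded", m.method)
            continue
        usable.append(m)
    return usable


def median_rank_consensus(method_scores: list[MethodScores]) -> np.ndarray:
    """Median of per-method percentile ranks; lower = better.

    Requires at least two available methods covering the same peptide
    list; unavailable methods are excluded with a log entry.  For an
    even method count the consensus is the mean of the two central
    ranks.  Permutation-invariant in method order.
    """
    usable = _usable(method_scores)
    if len(usable) < 2:
        raise ValidationError(
            f"consensus needs at least 2 available methods, got {len(usable)}"
        )
    n = usable[0].scores.size
    if any(m.scores.size != n for m in usable):
        raise ValidationError("all methods must score the same peptide list")
    ranks = np.stack([percentile_rank(m.scores, m.orientation) for m in usable])
    return np.median(ranks, axis=0)


def leave_one_out_consensus(method_scores: list[MethodScores], labels) -> pd.DataFrame:
    """Consensus AUC with each method removed, next to the full consensus.

    Rows: ``full`` plus one per removed method.  A method whose removal
    raises the AUC is hurting the consensus.
    """
    usable = _usable(method_scores)
    if len(usable) < 3:
        raise ValidationError("leave-one-out needs at least 3 available methods")
    labels = np.asarray(labels, dtype=bool)
    rows = [
        {
            "removed": "none",
            "n_methods": len(usable),
            "auc": roc_auc(median_rank_consensus(usable), labels).auc,
        }
    ]
    for m in usable:
        rest = [x for x in usable if x is not m]
        rows.append(
            {
                "removed": m.method,
                "n_methods": len(rest),
                "auc": roc_auc(median_rank_consensus(rest), labels).auc,
            }
        )
    return pd.DataFrame(rows)


def subset_consensus(
    method_scores: list[MethodScores],
    primary: list[str],
    fallback: list[str] | None = None,
    allele: str = "?",
) -> np.ndarray:
    """Consensus over a configured method subset with availability fallback.

    The members are the ``primary`` methods; any primary that is
    unavailable (or absent) for this allele is replaced by the next
    available ``fallback`` method not already in use.  Raises if no
    valid substitution leaves at least two members.
    """
    fallback = fallback or []
    by_name = {m.method: m for m in method_scores}
    chosen: list[MethodScores] = []
    used: set[str] = set()
    fallback_pool = [
        name for name in fallback
        if name in by_name and by_name[name].available
    ]
    for name in primary:
        m = by_name.get(name)
        if m is not None and m.available:
            chosen.append(m)
            used.add(name)
            continue
        substitute = next((f for f in fallback_pool if f not in used), None)
        if substitute is None:
            logger.warning(
                "allele %s: no fallback available to replace method %s", allele, name
            )
            continue
        chosen.append(by_name[substitute])
        used.add(substitute)
    if len(chosen) < 2:
        raise ValidationError(
            f"allele {allele}: subset consensus has {len(chosen)} usable method(s); need >= 2"
        )
    return median_rank_consensus(chosen)
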