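"""F-score feature ranking and quartile-pruned candidate subsets.

Per-class binary models are built on a subset of the feature space
chosen by filter selection: features are ranked by F-score (between-
class squared mean deviations over pooled within-class variances), the
ranking is cut at the quartile fractions 25/50/75/100%, the extreme
cuts are discarded (too few features recognize poorly; the full set is
slow and noisy), and the surviving candidates are compared by
cross-validated MCC with a sensitivity/specificity/size tie-break.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

DEFAULT_FRACTIONS = (0.25, 0.50, 0.75, 1.00)
DEFAULT_ELIGIBLE = (0.50, 0.75)


def f_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Fisher-style score of one feature for a binary split.

    ``F = [(m+ - m)^2 + (m- - m)^2] / [var+ + var-]`` with sample
    (n-1) variances.  Conventions: 0/0 -> 0; positive numerator over a
    zero denominator (a perfectly class-constant separator) -> +inf.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = values[labels], values[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 samples")
    m, mp, mn = values.mean(), pos.mean(), neg.mean()
    num = (mp - m) ** 2 + (mn - m) ** 2
    den = pos.var(ddof=1) + neg.var(ddof=1)
    if den == 0.0:
        return 0.0 if num == 0.0 else math.inf
    return float(num / den)


@dataclass
class FeatureRanking:
    """F-scores per 1-based feature index plus the descending order."""

    scores: dict[int, float]
    order: list[int]

    def __len__(self) -> int:
        return len(self.order)


def rank_features(matrix: np.ndarray, labels: np.ndarray) -> FeatureRanking:
    """Rank all columns by F-score, ties broken by ascending index."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 features")
    scores = {j + 1: f_score(matrix[:, j], labels) for j in range(matrix.shape[1])}
    order = sorted(scores, key=lambda j: (-scores[j], j))
    return FeatureRanking(scores, order)


@dataclass
class CandidateSubset:
    """A prefix of the ranking: the top ceil(fraction * d) features."""

    fraction: float
    indices: list[int]  # 1-based, in ranking order
    eligible: bool

    def __len__(self) -> int:
        return len(self.indices)


def candidate_subsets(
    ranking: FeatureRanking,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    eligible: tuple[float, ...] = DEFAULT_ELIGIBLE,
) -> list[CandidateSubset]:
    """Nested prefix subsets at the quartile fractions.

    Subset sizes are ``ceil(f * d)``.  Fractions in ``eligible`` are
    flagged as candidates for model selection; the rest (by default the
    25% and 100% cuts) are built but flagged discarded.
    """
    if not ranking.order:
        raise ValueError("empty ranking")
    d = len(ranking.order)
    out = []
    for f in fractions:
        k = math.ceil(f * d)
        out.append(CandidateSubset(f, ranking.order[:k], f in eligible))
    return out


def select_best(candidates: list[CandidateSubset], cv_reports: list) -> CandidateSubset:
    """Pick the eligible candidate with the best cross-validated report.

    Reports must expose ``mcc``, ``sn`` and ``sp``.  Order of
    preference: higher MCC, then higher Sn, then higher Sp, then the
    smaller subset.  NaN metrics sort below every finite value.  With
    no eligible candidate, all candidates compete (logged warning).
    """
    if len(candidates) != len(cv_reports):
        raise ValueError("one report per candidate required")
    pool = [(c, r) for c, r in zip(candidates, cv_reports) if c.eligible]
    if not pool:
        log.warning("no eligible candidates; falling back to the full candidate list")
        pool = list(zip(candidates, cv_reports))

    def key(item):
        c, r = item

        def safe(x):
            return -math.inf if x is None or (isinstance(x, float) and math.isnan(x)) else x

        return (safe(r.mcc), safe(r.sn), safe(r.sp), -len(c))

    return max(pool, key=key)[0]


def export_ranking(ranking: FeatureRanking, feature_ids: list[str], path, top: int | None = None) -> None:
    """Write a (rank, feature id, F-score) TSV, best first."""
    order = ranking.order[:top] if top else ranking.order
    with open(path, "w") as fh:
        fh.write("rank\tfeature\tf_score\n")
        for rank, j in enumerate(order, start=1):
            fh.write(f"{rank}\t{feature_ids[j - 1]}\t{ranking.scores[j]:.6g}\n")
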