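"""Dataset curation: length/unknown filters, redundancy clustering, folds.

The curation pipeline mirrors standard practice for building oligomer
training sets from structural databases: drop fragments shorter than 30
residues, drop sequences with three or more unknown residues, then
remove redundancy with greedy identity clustering at a per-class
threshold (60% by default; 90% for the sparse pentamer / octamer /
decamer / dodecamer classes so those classes keep enough members to be
statistically useful).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict

import numpy as np
from Bio import Align

from .records import OligomerLabel, ProteinRecord

log = logging.getLogger(__name__)

#: Per-class identity thresholds for redundancy removal.  Classes absent
#: from the map use the ``"default"`` entry.
DEFAULT_IDENTITY_THRESHOLDS: dict[str, float] = {
    "default": 0.6,
    "homo:5": 0.9, "homo:8": 0.9, "homo:10": 0.9, "homo:12": 0.9,
    "hetero:5": 0.9, "hetero:8": 0.9, "hetero:10": 0.9, "hetero:12": 0.9,
}


def filter_min_length(records: list[ProteinRecord], min_len: int = 30) -> list[ProteinRecord]:
    """Keep records whose sequence length is >= ``min_len`` (order kept)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in records if len(r) >= min_len]


def filter_unknown(records: list[ProteinRecord], max_unknown: int = 2) -> list[ProteinRecord]:
    """Keep records with at most ``max_unknown`` unknown ('X') residues."""
    if max_unknown < 0:
        raise ValueError("max_unknown must be >= 0")
    return [r for r in records if r.n_unknown <= max_unknown]


def filter_label_consistent(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Drop every record whose id maps to more than one distinct label.

    A generic consistency filter for datasets where the same chain can
    appear under several oligomeric states.
    """
    seen: dict[str, set] = defaultdict(set)
    for r in records:
        seen[r.id].add(r.label)
    good = {i for i, ls in seen.items() if len(ls) == 1}
    return [r for r in records if r.id in good]


def _aligner() -> Align.PairwiseAligner:
    # Free gaps + unit match score: the optimal global score counts the
    # maximum number of identically aligned positions.
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = 0.0
    a.extend_gap_score = 0.0
    return a


_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identically aligned positions over the shorter length.

    Identity is the maximum number of matched identical residues over
    all global alignments (gaps unpenalized), divided by the length of
    the shorter sequence — the denominator convention of greedy
    redundancy-clustering tools.  Symmetric; in [0, 1].
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    matches = _ALIGNER.score(a, b)
    return float(matches) / min(len(a), len(b))


def cluster_redundancy(records: list[ProteinRecord], threshold: float) -> list[ProteinRecord]:
    """Greedy longest-first redundancy clustering; returns representatives.

    Records are visited in order of decreasing length (ties broken by
    ascending id).  A record joins the first existing representative
    with ``pairwise_identity >= threshold``; otherwise it founds a new
    cluster.  Deterministic; representatives are returned in founding
    order.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[ProteinRecord] = []
    for rec in ordered:
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence) >= threshold:
                break
        else:
            reps.append(rec)
    return reps


def cluster_by_class(
    records: list[ProteinRecord],
    thresholds: dict[str, float] | None = None,
) -> list[ProteinRecord]:
    """Run :func:`cluster_redundancy` separately within each label class.

    ``thresholds`` maps label strings to identity thresholds, with a
    ``"default"`` fallback (see :data:`DEFAULT_IDENTITY_THRESHOLDS`).
    Input order among representatives is preserved.
    """
    thresholds = thresholds or DEFAULT_IDENTITY_THRESHOLDS
    default = thresholds.get("default", 0.6)
    by_class: dict[OligomerLabel, list[ProteinRecord]] = defaultdict(list)
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.id!r} has no label; cannot cluster per class")
        by_class[r.label].append(r)
    keep_ids: set[str] = set()
    for label, members in by_class.items():
        t = thresholds.get(str(label), default)
        keep_ids.update(r.id for r in cluster_redundancy(members, t))
    return [r for r in records if r.id in keep_ids]


def assign_folds(records: list[ProteinRecord], k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment: per class, fold sizes differ by <= 1.

    Members of each class are shuffled (seeded) and dealt round-robin
    from a random starting fold, so no single fold systematically takes
    the remainder records of every class.  Returns an int array aligned
    with ``records``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = []
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.id!r} is unlabelled; folds are stratified by label")
        labels.append(str(r.label))
    return assign_folds_labels(labels, k=k, seed=seed)


def assign_folds_labels(labels: list[str], k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment over a plain label list (see assign_folds)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=np.int64)
    by_class: dict[str, list[int]] = defaultdict(list)
    for i, lab in enumerate(labels):
        by_class[lab].append(i)
    for lab in sorted(by_class):
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        start = int(rng.integers(k))
        for j, i in enumerate(idx):
            folds[i] = (start + j) % k
    return folds


def curate(
    records: list[ProteinRecord],
    min_len: int = 30,
    max_unknown: int = 2,
    thresholds: dict[str, float] | None = None,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Full curation pipeline; returns (survivors, per-stage removal counts)."""
    report = {"input": len(records)}
    step = filter_min_length(records, min_len)
    report["removed_short"] = len(records) - len(step)
    step2 = filter_unknown(step, max_unknown)
    report["removed_unknown"] = len(step) - len(step2)
    if all(r.label is not None for r in step2) and step2:
        step3 = cluster_by_class(step2, thresholds)
    else:
        # unlabelled input: cluster globally at the default threshold
        t = (thresholds or DEFAULT_IDENTITY_THRESHOLDS).get("default", 0.6)
        reps = {r.id for r in cluster_redundancy(step2, t)}
        step3 = [r for r in step2 if r.id in reps]
    report["removed_redundant"] = len(step2) - len(step3)
    report["output"] = len(step3)
    return step3, report


def class_counts(records: list[ProteinRecord]) -> dict[str, int]:
    return dict(Counter(str(r.label) for r in records))
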