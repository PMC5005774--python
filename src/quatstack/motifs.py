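"""Block / domain motif databases and ungapped PSSM scanning.

A *block* is a short, gapless, highly conserved segment of a multiple
alignment.  Each motif carries a position-specific scoring matrix
(PSSM) of log-odds scores against a uniform background, built from its
aligned segments, plus a hit threshold.  A sequence *hits* a motif when
the best ungapped window score reaches the threshold; downstream
encoders only use the hit/no-hit bit.

Hit thresholds are calibrated empirically: the threshold is a high
quantile (default 0.999) of best-window scores over random decoy
sequences, which pins the per-motif false-hit rate without any external
significance machinery.  Externally computed hit lists can be injected
instead (see :mod:`quatstack.features`).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import AA20, AA_INDEX

#: Finite floor for log-odds of zero-count cells at pseudocount 0 (bits).
SCORE_FLOOR = -30.0

#: Sentinel returned by scan for sequences shorter than the motif.
NO_HIT_SCORE = -math.inf


class BlockParseError(ValueError):
    pass


def build_pssm(segments: list[str], pseudocount: float = 1.0) -> np.ndarray:
    """Log-odds PSSM from equal-length aligned segments.

    ``entry[j][a] = log2(((count(a at j) + c*q) / (n + c)) / q)`` with a
    uniform background ``q = 1/20`` and pseudocount ``c``.  With
    ``c == 0``, zero-count cells are floored at :data:`SCORE_FLOOR`
    rather than -inf so every entry stays finite.
    """
    if not segments:
        raise ValueError("need at least one segment")
    width = len(segments[0])
    if any(len(s) != width for s in segments):
        raise ValueError("segments must have equal lengths")
    counts = np.zeros((width, 20))
    for seg in segments:
        for j, ch in enumerate(seg):
            if ch not in AA_INDEX:
                raise ValueError(
                    f"residue {ch!r} not a standard amino acid (blocks are "
                    "conserved regions; 'X' is not allowed)"
                )
            counts[j, AA_INDEX[ch]] += 1
    n = len(segments)
    q = 1.0 / 20.0
    prob = (counts + pseudocount * q) / (n + pseudocount)
    with np.errstate(divide="ignore"):
        pssm = np.log2(prob / q)
    return np.maximum(pssm, SCORE_FLOOR)


@dataclass
class BlockMotif:
    """An ungapped motif: id, PSSM and hit threshold."""

    block_id: str
    pssm: np.ndarray  # width x 20 log-odds, all finite
    hit_threshold: float = 0.0
    segments: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.pssm = np.asarray(self.pssm, dtype=float)
        if self.pssm.ndim != 2 or self.pssm.shape[1] != 20 or self.pssm.shape[0] < 2:
            raise ValueError(f"motif {self.block_id!r}: PSSM must be width>=2 x 20")
        if not np.all(np.isfinite(self.pssm)):
            raise ValueError(f"motif {self.block_id!r}: PSSM entries must be finite")
        if self.hit_threshold > float(self.pssm.max(axis=1).sum()) + 1e-9:
            raise ValueError(
                f"motif {self.block_id!r}: threshold exceeds the maximum "
                "attainable window score"
            )

    @property
    def width(self) -> int:
        return int(self.pssm.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(AA20[a] for a in self.pssm.argmax(axis=1))

    @classmethod
    def from_segments(
        cls,
        block_id: str,
        segments: list[str],
        hit_threshold: float | None = None,
        pseudocount: float = 1.0,
    ) -> "BlockMotif":
        pssm = build_pssm(segments, pseudocount)
        if hit_threshold is None:
            hit_threshold = 0.0
        return cls(block_id, pssm, hit_threshold, list(segments))


# Domain models share the block machinery: only the feature-space name
# and the provenance of the threshold (an E-value-like significance
# cutoff for real domain databases) differ.
DomainModel = BlockMotif


@dataclass
class BlockDatabase:
    """Ordered motif collection; order fixes feature indices 1..|motifs|."""

    motifs: list[BlockMotif]
    name: str = "blocks"

    def __post_init__(self) -> None:
        ids = [m.block_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"database {self.name!r}: duplicate motif ids")
        self._index = {m.block_id: i for i, m in enumerate(self.motifs)}

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def __contains__(self, block_id: str) -> bool:
        return block_id in self._index

    def index_of(self, block_id: str) -> int:
        """0-based position of a motif in the database order."""
        return self._index[block_id]

    @property
    def ids(self) -> list[str]:
        return [m.block_id for m in self.motifs]

    def digest(self) -> str:
        """Stable content hash over ids, PSSMs and thresholds."""
        h = hashlib.sha256()
        for m in self.motifs:
            h.update(m.block_id.encode())
            h.update(np.ascontiguousarray(m.pssm).tobytes())
            h.update(repr(round(m.hit_threshold, 12)).encode())
        return h.hexdigest()


DomainDatabase = BlockDatabase


def _encode(sequence: str) -> np.ndarray:
    """Residues to PSSM column indices; unknown ('X') becomes -1."""
    return np.array([AA_INDEX.get(ch, -1) for ch in sequence], dtype=np.int64)


def scan(sequence: str, motif: BlockMotif) -> tuple[float, int]:
    """Best ungapped window score and its 0-based offset.

    Unknown residues score 0 at any motif position.  Sequences shorter
    than the motif return ``(-inf, -1)`` — no hit, not an error.  The
    first offset achieving the maximum wins ties.
    """
    w = motif.width
    n = len(sequence) - w + 1
    if n <= 0:
        return (NO_HIT_SCORE, -1)
    idx = _encode(sequence)
    scores = np.zeros(n)
    for j in range(w):
        col = idx[j : j + n]
        known = col >= 0
        scores[known] += motif.pssm[j, col[known]]
    best = int(np.argmax(scores))
    return (float(scores[best]), best)


def calibrate_threshold(
    motif: BlockMotif,
    n_decoys: int = 1000,
    quantile: float = 0.999,
    seed: int = 0,
) -> float:
    """Empirical decoy quantile of best-window scores.

    Decoys are uniform-residue sequences of length 5x the motif width.
    The returned threshold caps the per-decoy false-hit rate at roughly
    ``1 - quantile``.
    """
    if n_decoys < 100:
        raise ValueError("n_decoys must be >= 100")
    rng = np.random.default_rng(seed)
    w = motif.width
    best = np.empty(n_decoys)
    for i in range(n_decoys):
        decoy = "".join(AA20[c] for c in rng.integers(20, size=5 * w))
        best[i], _ = scan(decoy, motif)
    return float(np.quantile(best, quantile, method="higher"))


def find_hits(sequence: str, db: BlockDatabase) -> set[str]:
    """Ids of motifs whose best window score reaches their threshold."""
    if len(db) == 0:
        raise ValueError("empty motif database")
    hits = set()
    for motif in db:
        score, _ = scan(sequence, motif)
        if score >= motif.hit_threshold:
            hits.add(motif.block_id)
    return hits


def parse_block_db(
    path: str | Path,
    name: str | None = None,
    calibrate_missing: bool = True,
    seed: int = 0,
) -> BlockDatabase:
    """Parse the simplified aligned-segment dialect.

    Per block: ``ID <block_id>``, one or more equal-length segment
    lines, an optional ``TH <threshold>``, and a ``//`` terminator.
    Blocks without ``TH`` get a calibrated threshold (seeded).
    """
    path = Path(path)
    motifs: list[BlockMotif] = []
    block_id: str | None = None
    segments: list[str] = []
    threshold: float | None = None

    def flush() -> None:
        nonlocal block_id, segments, threshold
        if block_id is None:
            return
        if not segments:
            raise BlockParseError(f"{path}: block {block_id!r} has no segments")
        if len({len(s) for s in segments}) != 1:
            raise BlockParseError(
                f"{path}: block {block_id!r}: segments have unequal lengths"
            )
        try:
            motif = BlockMotif.from_segments(block_id, segments, threshold)
        except ValueError as exc:
            raise BlockParseError(f"{path}: block {block_id!r}: {exc}") from exc
        if threshold is None and calibrate_missing:
            motif.hit_threshold = calibrate_threshold(motif, seed=seed)
        motifs.append(motif)
        block_id, segments, threshold = None, [], None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("ID "):
                if block_id is not None:
                    raise BlockParseError(
                        f"{path}: line {lineno}: block {block_id!r} not terminated"
                    )
                block_id = line[3:].strip()
            elif line.startswith("TH "):
                threshold = float(line[3:])
            elif line == "//":
                flush()
            else:
                if block_id is None:
                    raise BlockParseError(
                        f"{path}: line {lineno}: segment outside a block"
                    )
                segments.append(line)
    if block_id is not None:
        raise BlockParseError(f"{path}: block {block_id!r} not terminated")
    return BlockDatabase(motifs, name=name or path.stem)


def write_block_db(db: BlockDatabase, path: str | Path) -> None:
    """Write a database back to the aligned-segment dialect (with TH)."""
    with open(path, "w") as fh:
        for m in db:
            if not m.segments:
                raise ValueError(
                    f"motif {m.block_id!r} has no stored segments; cannot serialize"
                )
            fh.write(f"ID {m.block_id}\n")
            for seg in m.segments:
                fh.write(seg + "\n")
            fh.write(f"TH {m.hit_threshold!r}\n//\n")
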