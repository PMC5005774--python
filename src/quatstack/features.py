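"""The three feature encodings and their sparse interchange format.

* **block** — binary vector over a block database: bit i is set iff the
  sequence hits block i.
* **fund** — the same construction over a functional-domain database.
* **pseasa** — pseudo-amino-acid composition computed separately on the
  solvent-exposed and buried subsequences of the chain and
  concatenated.  Interaction interfaces are enriched in exposed
  residues, so splitting by accessibility lets the encoding see the
  surface and the core with separate composition/order statistics.

Block and domain bits are stored sparsely in the classic
``label idx:val`` one-record-per-line format; PseASA vectors are dense
but use the same container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifs import BlockDatabase, find_hits
from .records import AA20, AA_INDEX, ProteinRecord

log = logging.getLogger(__name__)

# Canonical per-residue property tables of the classic pseudo-amino-acid
# composition encoding (raw values; standardized at use):
# hydrophobicity, hydrophilicity, side-chain mass, indexed by AA20 order
# A C D E F G H I K L M N P Q R S T V W Y.
HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _standardize(table: dict[str, float]) -> np.ndarray:
    v = np.array([table[a] for a in AA20], dtype=float)
    return (v - v.mean()) / v.std()


@dataclass
class PseASAParams:
    """Parameters of the pseudo-amino-acid composition encoding.

    ``lam`` is the maximum sequence-order correlation rank (how far
    apart two residues may be and still contribute a correlation
    factor); ``w`` weights the correlation factors against plain
    composition.  Property tables are standardized to mean 0, SD 1 over
    the 20 residues before use.
    """

    lam: int = 10
    w: float = 0.05
    properties: list[np.ndarray] = field(default_factory=lambda: [
        _standardize(HYDROPHOBICITY),
        _standardize(HYDROPHILICITY),
        _standardize(SIDE_CHAIN_MASS),
    ])

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.w <= 0:
            raise ValueError("w must be > 0")
        for p in self.properties:
            p = np.asarray(p, dtype=float)
            if p.shape != (20,):
                raise ValueError("each property table needs exactly 20 entries")
            if abs(p.mean()) > 1e-9 or abs(p.std() - 1.0) > 1e-9:
                raise ValueError("property tables must be standardized (mean 0, SD 1)")


@dataclass
class FeatureVector:
    """A named-space feature vector with sparse 1-based entries."""

    space_name: str  # block | fund | pseasa
    dimension: int
    entries: dict[int, float]

    def __post_init__(self) -> None:
        for i in self.entries:
            if not (1 <= i <= self.dimension):
                raise ValueError(
                    f"index {i} outside [1, {self.dimension}] in {self.space_name}"
                )

    def to_dense(self) -> np.ndarray:
        v = np.zeros(self.dimension)
        for i, x in self.entries.items():
            v[i - 1] = x
        return v

    @classmethod
    def from_dense(cls, space_name: str, values: np.ndarray) -> "FeatureVector":
        entries = {i + 1: float(x) for i, x in enumerate(values) if x != 0.0}
        return cls(space_name, len(values), entries)


def encode_block(record: ProteinRecord, db: BlockDatabase) -> FeatureVector:
    """Binary block-composition vector: bit i set iff block i hits."""
    hits = find_hits(record.sequence, db)
    entries = {db.index_of(h) + 1: 1.0 for h in hits}
    return FeatureVector("block", len(db), entries)


def encode_fund(record: ProteinRecord, db: BlockDatabase) -> FeatureVector:
    """Binary functional-domain-composition vector (all-zero is legal:
    a chain may match no known domain at all)."""
    hits = find_hits(record.sequence, db)
    entries = {db.index_of(h) + 1: 1.0 for h in hits}
    return FeatureVector("fund", len(db), entries)


def encode_from_hits(
    record_id: str,
    hits_by_record: dict[str, set[str]],
    db: BlockDatabase,
    space_name: str = "block",
) -> FeatureVector:
    """Encode from a precomputed hit list instead of scanning."""
    hits = hits_by_record.get(record_id, set())
    entries = {db.index_of(h) + 1: 1.0 for h in hits if h in db}
    return FeatureVector(space_name, len(db), entries)


def load_precomputed_hits(
    path: str | Path, db: BlockDatabase | None = None
) -> dict[str, set[str]]:
    """Read a (record id, motif id) TSV of externally computed hits.

    Motif ids absent from ``db`` (when given) are dropped with a logged
    warning tallying how many pairs were ignored.
    """
    hits: dict[str, set[str]] = {}
    ignored = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            rec_id, motif_id = parts
            if db is not None and motif_id not in db:
                ignored += 1
                continue
            hits.setdefault(rec_id, set()).add(motif_id)
    if ignored:
        log.warning("%s: ignored %d hit pairs with motif ids absent from the database",
                    path, ignored)
    return hits


def split_accessibility(record: ProteinRecord) -> tuple[str, str]:
    """Split a chain into its exposed and buried subsequences.

    The discontinuous exposed residues are concatenated in original
    order into one string, the buried residues into another; the two
    lengths sum to the sequence length.
    """
    if record.accessibility is None:
        raise ValueError(
            f"record {record.id!r} has no accessibility labels; provide a "
            "(record id, E/B string) TSV sidecar"
        )
    exposed = "".join(c for c, a in zip(record.sequence, record.accessibility) if a == "E")
    buried = "".join(c for c, a in zip(record.sequence, record.accessibility) if a == "B")
    return exposed, buried


def pseaac(sequence: str, params: PseASAParams) -> np.ndarray:
    """Pseudo-amino-acid composition of one sequence, length ``20 + lam``.

    With residue frequencies ``f_u`` and sequence-order correlation
    factors ``theta_j = mean_i Theta(R_i, R_{i+j})`` — ``Theta`` the
    mean squared difference of the standardized property values of the
    two residues — the components are::

        p_u      = f_u / (sum f + w * sum theta)        u = 1..20
        p_{20+j} = w * theta_j / (sum f + w * sum theta)  j = 1..lam

    so the vector sums to 1.  Unknown residues are dropped before
    encoding.  If the (X-free) sequence is shorter than ``lam + 1`` the
    correlation rank is degraded to ``len - 1`` with a logged warning;
    the output keeps dimension ``20 + lam`` with zeros for the
    unreachable ranks.
    """
    seq = sequence.replace("X", "")
    if not seq:
        raise ValueError("sequence has no standard residues to encode")
    lam = params.lam
    L = len(seq)
    eff_lam = lam
    if L < lam + 1:
        eff_lam = L - 1
        log.warning(
            "sequence of length %d shorter than lam+1=%d; degrading lam to %d",
            L, lam + 1, eff_lam,
        )
    idx = np.array([AA_INDEX[c] for c in seq])
    freqs = np.bincount(idx, minlength=20).astype(float) / L

    props = np.stack(params.properties)  # n_props x 20
    vals = props[:, idx]  # n_props x L
    theta = np.zeros(lam)
    for j in range(1, eff_lam + 1):
        diff = vals[:, : L - j] - vals[:, j:]
        theta[j - 1] = float(np.mean(diff**2))

    denom = freqs.sum() + params.w * theta.sum()
    out = np.empty(20 + lam)
    out[:20] = freqs / denom
    out[20:] = params.w * theta / denom
    return out


def encode_pseasa(record: ProteinRecord, params: PseASAParams | None = None) -> FeatureVector:
    """Accessibility-split pseudo-amino-acid composition.

    Concatenates ``pseaac(exposed)`` and ``pseaac(buried)``; an empty
    side contributes a zero block, so the dimension is always
    ``2 * (20 + lam)``.
    """
    params = params or PseASAParams()
    exposed, buried = split_accessibility(record)
    d = 20 + params.lam
    vec = np.zeros(2 * d)
    if exposed.replace("X", ""):
        vec[:d] = pseaac(exposed, params)
    if buried.replace("X", ""):
        vec[d:] = pseaac(buried, params)
    return FeatureVector("pseasa", 2 * d, {
        i + 1: float(x) for i, x in enumerate(vec) if x != 0.0
    })


class SparseParseError(ValueError):
    pass


def write_sparse(
    path: str | Path,
    vectors: list[FeatureVector],
    labels: list[str],
) -> None:
    """Write ``label idx:val`` lines with ascending 1-based indices."""
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal lengths")
    with open(path, "w") as fh:
        for lab, vec in zip(labels, vectors):
            parts = [str(lab)]
            for i in sorted(vec.entries):
                x = vec.entries[i]
                parts.append(f"{i}:{int(x) if x == int(x) else repr(x)}")
            fh.write(" ".join(parts) + "\n")


def read_sparse(
    path: str | Path,
    space_name: str = "block",
    dimension: int | None = None,
) -> tuple[list[str], list[FeatureVector]]:
    """Read the sparse format back; rejects non-ascending indices.

    If ``dimension`` is not given, the largest index seen is used.
    """
    labels: list[str] = []
    raw: list[dict[int, float]] = []
    max_idx = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            labels.append(parts[0])
            entries: dict[int, float] = {}
            prev = 0
            for tok in parts[1:]:
                try:
                    i_str, x_str = tok.split(":")
                    i, x = int(i_str), float(x_str)
                except ValueError as exc:
                    raise SparseParseError(
                        f"{path}: line {lineno}: bad token {tok!r}"
                    ) from exc
                if i <= prev:
                    raise SparseParseError(
                        f"{path}: line {lineno}: indices not strictly ascending"
                    )
                prev = i
                entries[i] = x
            max_idx = max(max_idx, prev)
            raw.append(entries)
    dim = dimension if dimension is not None else max_idx
    return labels, [FeatureVector(space_name, dim, e) for e in raw]


def encode_features(
    records: list[ProteinRecord],
    block_db: BlockDatabase | None = None,
    domain_db: BlockDatabase | None = None,
    pseasa_params: PseASAParams | None = None,
    feature_types: tuple[str, ...] = ("block", "fund"),
    block_hits: dict[str, set[str]] | None = None,
    fund_hits: dict[str, set[str]] | None = None,
) -> dict[str, np.ndarray]:
    """Encode records into dense per-type matrices for the stack.

    Precomputed hit maps, when given, replace scanning for the
    corresponding space (so real external search output can be
    injected).
    """
    out: dict[str, np.ndarray] = {}
    for t in feature_types:
        if t == "block":
            if block_db is None:
                raise ValueError("block features requested but no block database given")
            if block_hits is not None:
                vecs = [encode_from_hits(r.id, block_hits, block_db, "block") for r in records]
            else:
                vecs = [encode_block(r, block_db) for r in records]
        elif t == "fund":
            if domain_db is None:
                raise ValueError("fund features requested but no domain database given")
            if fund_hits is not None:
                vecs = [encode_from_hits(r.id, fund_hits, domain_db, "fund") for r in records]
            else:
                vecs = [encode_fund(r, domain_db) for r in records]
        elif t == "pseasa":
            vecs = [encode_pseasa(r, pseasa_params) for r in records]
        else:
            raise ValueError(f"unknown feature type {t!r}")
        out[t] = feature_matrix(vecs)
    return out


def feature_matrix(vectors: list[FeatureVector]) -> np.ndarray:
    """Stack feature vectors of one space into a dense (n, d) matrix."""
    if not vectors:
        raise ValueError("no vectors to stack")
    dims = {v.dimension for v in vectors}
    if len(dims) != 1:
        raise ValueError(f"inconsistent dimensions: {sorted(dims)}")
    return np.stack([v.to_dense() for v in vectors])
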