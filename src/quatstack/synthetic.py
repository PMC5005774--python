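"""Seeded synthetic fixtures with the statistical structure the method assumes.

The generator fabricates what the external motif/domain databases and
the accessibility predictor would otherwise provide: a block database
of conserved ungapped motifs, a domain database of the same shape, and
labelled protein records in which each class's motifs are planted into
otherwise random background sequence.  Class identity is therefore
carried by sparse binary motif presence — exactly the discriminative
structure the block / domain encoders are built to capture — which
makes every pipeline stage testable offline and with known ground
truth.

Defaults define the reference study conditions: 6 oligomer classes,
60 records per class, 2 private blocks + 2 private domains per class,
planting probability 0.9, background length uniform on [80, 300],
uniform residue composition, and random exposed/buried labels
(probability 0.5 exposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifs import BlockDatabase, BlockMotif, calibrate_threshold, write_block_db
from .records import AA20, OligomerLabel, ProteinRecord
from . import seqio

DEFAULT_CLASSES = ("monomer", "homo:2", "homo:3", "homo:4", "hetero:2", "hetero:3")


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic fixture set."""

    n_blocks: int = 12
    n_domains: int = 12
    motif_width: tuple[int, int] = (8, 12)  # inclusive range
    classes: tuple[str, ...] = DEFAULT_CLASSES
    motifs_per_class: int = 2
    records_per_class: int = 60
    embed_prob: float = 0.9
    length_range: tuple[int, int] = (80, 300)  # inclusive
    exposed_prob: float = 0.5
    segment_count: int = 5
    mutation_rate: float = 0.1
    seed: int = 7
    class_motif_map: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.embed_prob <= 1.0):
            raise ValueError("embed_prob must be in [0, 1]")
        for c in self.classes:
            OligomerLabel.parse(c)  # validates

    def resolved_motif_map(self) -> dict[str, tuple[list[str], list[str]]]:
        """Per class: (planted block ids, planted domain ids)."""
        need = self.motifs_per_class * len(self.classes)
        if not self.class_motif_map and (self.n_blocks < need or self.n_domains < need):
            raise ValueError(
                f"need >= {need} blocks and domains for "
                f"{len(self.classes)} classes x {self.motifs_per_class} motifs"
            )
        if self.class_motif_map:
            for cls in self.classes:
                if cls not in self.class_motif_map:
                    raise ValueError(f"class {cls!r} has no motifs in class_motif_map")
            return self.class_motif_map
        m = self.motifs_per_class
        return {
            cls: (
                [_block_id(i * m + j) for j in range(m)],
                [_domain_id(i * m + j) for j in range(m)],
            )
            for i, cls in enumerate(self.classes)
        }


def _block_id(i: int) -> str:
    return f"BLK{i + 1:03d}"


def _domain_id(i: int) -> str:
    return f"DOM{i + 1:03d}"


def _random_motif(rng: np.random.Generator, motif_id: str, spec: GeneratorSpec) -> BlockMotif:
    lo, hi = spec.motif_width
    w = int(rng.integers(lo, hi + 1))
    consensus = rng.integers(20, size=w)
    segments = []
    for _ in range(spec.segment_count):
        seg = consensus.copy()
        for j in range(w):
            if rng.random() < spec.mutation_rate:
                seg[j] = (seg[j] + 1 + rng.integers(19)) % 20
        segments.append("".join(AA20[a] for a in seg))
    motif = BlockMotif.from_segments(motif_id, segments)
    motif.hit_threshold = calibrate_threshold(
        motif, seed=int(rng.integers(2**31))
    )
    return motif


def generate_block_db(spec: GeneratorSpec) -> BlockDatabase:
    """Seeded block database: mutated-consensus motifs with calibrated thresholds."""
    if spec.n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(spec.seed)
    motifs = [_random_motif(rng, _block_id(i), spec) for i in range(spec.n_blocks)]
    return BlockDatabase(motifs, name="synthetic-blocks")


def generate_domain_db(spec: GeneratorSpec) -> BlockDatabase:
    """Seeded domain database (offset seed stream so it differs from blocks)."""
    if spec.n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    rng = np.random.default_rng(spec.seed + 500009)
    motifs = [_random_motif(rng, _domain_id(i), spec) for i in range(spec.n_domains)]
    return BlockDatabase(motifs, name="synthetic-domains")


@dataclass
class PlantedMotif:
    motif_id: str
    position: int  # 0-based start in the record sequence


@dataclass
class GroundTruth:
    """Exact provenance of every planted motif, keyed by record id."""

    label: dict[str, str] = field(default_factory=dict)
    planted: dict[str, list[PlantedMotif]] = field(default_factory=dict)

    def planted_ids(self, record_id: str) -> set[str]:
        return {p.motif_id for p in self.planted.get(record_id, [])}


def _place_nonoverlapping(
    rng: np.random.Generator, length: int, widths: list[int]
) -> list[int]:
    """Random non-overlapping start offsets; retries, then gives up on
    the colliding motif (rare at the default length/width ratios)."""
    placed: list[tuple[int, int]] = []
    starts = []
    for w in widths:
        ok = -1
        for _ in range(100):
            s = int(rng.integers(length - w + 1))
            if all(s + w <= a or s >= a + ww for a, ww in placed):
                ok = s
                break
        starts.append(ok)
        if ok >= 0:
            placed.append((ok, w))
    return starts


def generate_dataset(
    spec: GeneratorSpec,
    block_db: BlockDatabase,
    domain_db: BlockDatabase,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Labelled records with planted class motifs and accessibility labels.

    Per record: a uniform-residue background of random length, each
    class block/domain consensus planted with probability
    ``embed_prob`` at a random non-overlapping position, and random
    exposed/buried labels.
    """
    motif_map = spec.resolved_motif_map()
    by_id = {m.block_id: m for m in list(block_db) + list(domain_db)}
    for cls, (bids, dids) in motif_map.items():
        for mid in bids + dids:
            if mid not in by_id:
                raise ValueError(f"class {cls!r}: motif {mid!r} not in the databases")
    rng = np.random.default_rng(spec.seed + 900007)
    records: list[ProteinRecord] = []
    truth = GroundTruth()
    lo, hi = spec.length_range
    for ci, cls in enumerate(spec.classes):
        bids, dids = motif_map[cls]
        for j in range(spec.records_per_class):
            rec_id = f"rec_c{ci}_{j:03d}"
            length = int(rng.integers(lo, hi + 1))
            seq = rng.integers(20, size=length)
            to_plant = [mid for mid in bids + dids if rng.random() < spec.embed_prob]
            widths = [by_id[m].width for m in to_plant]
            starts = _place_nonoverlapping(rng, length, widths)
            planted = []
            for mid, s in zip(to_plant, starts):
                if s < 0:
                    continue
                cons = by_id[mid].consensus
                seq[s : s + len(cons)] = [AA20.index(ch) for ch in cons]
                planted.append(PlantedMotif(mid, s))
            acc = "".join(
                "E" if rng.random() < spec.exposed_prob else "B" for _ in range(length)
            )
            records.append(
                ProteinRecord(
                    rec_id,
                    "".join(AA20[a] for a in seq),
                    OligomerLabel.parse(cls),
                    acc,
                )
            )
            truth.label[rec_id] = cls
            truth.planted[rec_id] = planted
    return records, truth


def generate_all(spec: GeneratorSpec):
    """Convenience: (block_db, domain_db, records, ground_truth)."""
    block_db = generate_block_db(spec)
    domain_db = generate_domain_db(spec)
    records, truth = generate_dataset(spec, block_db, domain_db)
    return block_db, domain_db, records, truth


def write_fixture_set(spec: GeneratorSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit all fixture files; byte-identical for identical spec + seed.

    Writes the block and domain databases, FASTA, label TSV,
    accessibility TSV, ground-truth TSV and a spec manifest.
    """
    import json
    from dataclasses import asdict

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    block_db, domain_db, records, truth = generate_all(spec)
    paths = {
        "blocks": outdir / "blocks.txt",
        "domains": outdir / "domains.txt",
        "fasta": outdir / "sequences.fasta",
        "labels": outdir / "labels.tsv",
        "accessibility": outdir / "accessibility.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "manifest": outdir / "generator_spec.json",
    }
    write_block_db(block_db, paths["blocks"])
    write_block_db(domain_db, paths["domains"])
    seqio.write_fasta(records, paths["fasta"])
    seqio.write_labels(records, paths["labels"])
    seqio.write_accessibility(records, paths["accessibility"])
    with open(paths["ground_truth"], "w") as fh:
        fh.write("record\tlabel\tmotif\tposition\n")
        for r in records:
            for p in truth.planted[r.id]:
                fh.write(f"{r.id}\t{truth.label[r.id]}\t{p.motif_id}\t{p.position}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
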