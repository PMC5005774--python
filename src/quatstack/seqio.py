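"""FASTA and sidecar-TSV input/output.

Sequences travel as FASTA; class labels and per-residue accessibility
(exposed/buried) travel as two-column TSV sidecars keyed by record id.
On read, sequences are normalized: lowercase residues are uppercased and
ambiguity or rare-residue codes (B, Z, J, U, O, ``*``) become ``X``.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AA20, UNKNOWN_CODES, OligomerLabel, ProteinRecord


class FastaParseError(ValueError):
    pass


def normalize_sequence(raw: str) -> str:
    """Uppercase and map non-standard residue codes to 'X'."""
    out = []
    for ch in raw.upper():
        if ch in AA20:
            out.append(ch)
        elif ch in UNKNOWN_CODES or ch == "X":
            out.append("X")
        else:
            raise FastaParseError(f"invalid residue character {ch!r}")
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read FASTA into normalized :class:`ProteinRecord` objects.

    Order is preserved.  A file whose first non-blank line is not a
    header is rejected with the offending line number.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first header"
            )
        break
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=normalize_sequence(str(rec.seq))))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_labels(path: str | Path) -> dict[str, OligomerLabel]:
    """Read a 2-column TSV (record id, label like ``homo:4``)."""
    labels: dict[str, OligomerLabel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            labels[parts[0]] = OligomerLabel.parse(parts[1])
    return labels


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.label is None:
                raise ValueError(f"record {r.id!r} has no label")
            fh.write(f"{r.id}\t{r.label}\n")


def read_accessibility(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (record id, E/B string)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_accessibility(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.accessibility is None:
                raise ValueError(f"record {r.id!r} has no accessibility labels")
            fh.write(f"{r.id}\t{r.accessibility}\n")


def attach_labels(records: list[ProteinRecord], labels: dict[str, OligomerLabel]) -> list[ProteinRecord]:
    """Return records with labels attached; ids without a label error out."""
    out = []
    for r in records:
        if r.id not in labels:
            raise KeyError(f"no label for record {r.id!r}")
        out.append(ProteinRecord(r.id, r.sequence, labels[r.id], r.accessibility))
    return out


def attach_accessibility(records: list[ProteinRecord], acc: dict[str, str]) -> list[ProteinRecord]:
    out = []
    for r in records:
        if r.id not in acc:
            raise KeyError(f"no accessibility labels for record {r.id!r}")
        out.append(ProteinRecord(r.id, r.sequence, r.label, acc[r.id]))
    return out
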