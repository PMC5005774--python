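"""Core domain types: protein records and oligomeric-state labels.

A quaternary-structure *attribute* is the pair (assembly kind, subunit
count): a protein chain is either a monomer, part of a homooligomer
(identical subunits) or part of a heterooligomer (at least two distinct
subunit types).  Subunit counts are restricted to the stoichiometries
with enough structural data to learn from — 2, 3, 4, 5, 6, 8, 10 and 12
— giving 17 valid labels in total (1 monomer + 2 x 8 oligomer classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: The 20 standard amino acids, alphabetical one-letter codes.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA20)}

#: Residue codes normalized to 'X' (ambiguity codes and rare residues).
UNKNOWN_CODES = set("BZJUO*")

#: Subunit counts accepted for homo-/heterooligomers.
OLIGOMER_SUBUNITS = (2, 3, 4, 5, 6, 8, 10, 12)

ASSEMBLIES = ("monomer", "homo", "hetero")


@dataclass(frozen=True, order=True)
class OligomerLabel:
    """One of the 17 quaternary-structure attributes.

    ``monomer`` always has ``subunits == 1``; ``homo`` and ``hetero``
    require a subunit count in :data:`OLIGOMER_SUBUNITS`.  The canonical
    string form is ``"monomer"``, ``"homo:4"``, ``"hetero:2"``, ...
    """

    assembly: str
    subunits: int = 1

    def __post_init__(self) -> None:
        if self.assembly not in ASSEMBLIES:
            raise ValueError(f"unknown assembly kind: {self.assembly!r}")
        if self.assembly == "monomer":
            if self.subunits != 1:
                raise ValueError("monomer implies exactly 1 subunit")
        elif self.subunits not in OLIGOMER_SUBUNITS:
            raise ValueError(
                f"subunit count {self.subunits} not in {OLIGOMER_SUBUNITS}"
            )

    @classmethod
    def parse(cls, text: str) -> "OligomerLabel":
        text = text.strip()
        if text == "monomer":
            return cls("monomer", 1)
        try:
            assembly, n = text.split(":")
            return cls(assembly, int(n))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cannot parse oligomer label {text!r}") from exc

    def __str__(self) -> str:
        if self.assembly == "monomer":
            return "monomer"
        return f"{self.assembly}:{self.subunits}"

    @classmethod
    def all_labels(cls) -> list["OligomerLabel"]:
        """The full 17-label space, in a fixed canonical order."""
        labels = [cls("monomer", 1)]
        for assembly in ("homo", "hetero"):
            labels.extend(cls(assembly, n) for n in OLIGOMER_SUBUNITS)
        return labels


@dataclass
class ProteinRecord:
    """A protein chain: id, sequence, optional label and accessibility.

    ``sequence`` is over the 20-residue alphabet plus ``X`` for unknown;
    ``accessibility`` (if present) is a same-length string over
    ``E`` (solvent-exposed) / ``B`` (buried).
    """

    id: str
    sequence: str
    label: Optional[OligomerLabel] = None
    accessibility: Optional[str] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AA20) - {"X"}
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues {sorted(bad)} outside alphabet"
            )
        if self.accessibility is not None:
            if len(self.accessibility) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: accessibility length "
                    f"{len(self.accessibility)} != sequence length "
                    f"{len(self.sequence)}"
                )
            bad = set(self.accessibility) - {"E", "B"}
            if bad:
                raise ValueError(
                    f"record {self.id!r}: accessibility codes {sorted(bad)} "
                    "not in {'E','B'}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_unknown(self) -> int:
        return self.sequence.count("X")
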