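"""Shared domain types: amino-acid alphabet, reference sequence, variants.

Position numbering is 1-based on the mature monomer; the catalytic
N-terminal proline is position 1 and is excluded from mutagenesis, so
collection members live on positions 2..62.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

from Bio import SeqIO

#: Canonical one-letter amino-acid alphabet, alphabetical order.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: First and last mutagenised positions of the mature monomer.
FIRST_POSITION = 2
LAST_POSITION = 62

#: Number of mutagenised positions (Ile-2 .. Arg-62).
N_POSITIONS = LAST_POSITION - FIRST_POSITION + 1  # 61

#: Possible substitutions per position (19 non-wild-type residues).
SUBSTITUTIONS_PER_POSITION = 19


class ReferenceSequence:
    """62-residue wild-type monomer sequence with 1-based indexing."""

    LENGTH = 62

    def __init__(self, residues: str):
        residues = str(residues).strip().upper()
        if len(residues) != self.LENGTH:
            raise ValueError(
                f"reference sequence must have {self.LENGTH} residues, "
                f"got {len(residues)}"
            )
        bad = set(residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
        self.residues = residues

    def __getitem__(self, position: int) -> str:
        """Residue at 1-based ``position``."""
        if not 1 <= position <= self.LENGTH:
            raise IndexError(f"position {position} outside 1..{self.LENGTH}")
        return self.residues[position - 1]

    def __len__(self) -> int:
        return self.LENGTH

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferenceSequence) and self.residues == other.residues

    def __repr__(self) -> str:
        return f"ReferenceSequence({self.residues!r})"


def load_reference(path=None) -> ReferenceSequence:
    """Load the wild-type sequence from FASTA.

    With no argument, the packaged 4-OT monomer sequence is used.  All
    position logic downstream keys off whatever sequence is supplied here,
    so an alternative protein only needs a replacement FASTA.
    """
    if path is None:
        ref = resources.files("mutscape").joinpath("data/4ot.fasta")
        with ref.open() as handle:
            record = next(SeqIO.parse(handle, "fasta"))
    else:
        record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceSequence(str(record.seq))


@dataclasses.dataclass(frozen=True, order=True)
class Variant:
    """One amino-acid substitution: ``wt_aa`` at ``position`` becomes ``mut_aa``."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self):
        if self.wt_aa not in AMINO_ACIDS or self.mut_aa not in AMINO_ACIDS:
            raise ValueError(f"invalid residue in {self.wt_aa}/{self.mut_aa}")
        if self.mut_aa == self.wt_aa:
            raise ValueError(f"substitution at {self.position} is wild-type-to-wild-type")

    @property
    def variant_id(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @classmethod
    def from_id(cls, variant_id: str) -> "Variant":
        wt, mut = variant_id[0], variant_id[-1]
        return cls(position=int(variant_id[1:-1]), wt_aa=wt, mut_aa=mut)

    def validate_against(self, reference: ReferenceSequence) -> None:
        if not FIRST_POSITION <= self.position <= LAST_POSITION:
            raise ValueError(
                f"position {self.position} outside collection range "
                f"{FIRST_POSITION}..{LAST_POSITION}"
            )
        if reference[self.position] != self.wt_aa:
            raise ValueError(
                f"wild-type residue mismatch at {self.position}: variant says "
                f"{self.wt_aa}, reference has {reference[self.position]}"
            )
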