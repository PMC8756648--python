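"""Core domain types shared across the toolkit.

A *signal peptide* here is the N-terminal extension of a secreted protein,
recorded up to (and excluding) the signal peptidase I cleavage site, together
with up to two residues retained downstream of the cut — the convention used
when fusing a signal peptide to a heterologous cargo protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

#: The 20 standard amino acids, one-letter uppercase.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes tolerated only in permissive mode, where
#: they count as neither charged nor hydrophobic.
AMBIGUOUS_AA = frozenset("XUBZ")


class AlphabetError(ValueError):
    """A sequence contains a character outside the accepted amino-acid alphabet."""


class FormatError(ValueError):
    """A record or table cell does not match the expected textual format."""


def validate_peptide(seq: str, *, allow_ambiguous: bool = False, context: str = "") -> str:
    """Validate an amino-acid string, returning it uppercased.

    Raises :class:`AlphabetError` naming the first offending character and its
    1-based position.
    """
    if not isinstance(seq, str):
        raise AlphabetError(f"{context}: expected a string, got {type(seq).__name__}")
    up = seq.upper()
    allowed = STANDARD_AA | AMBIGUOUS_AA if allow_ambiguous else STANDARD_AA
    for i, ch in enumerate(up, start=1):
        if ch not in allowed:
            where = f" in {context}" if context else ""
            raise AlphabetError(
                f"non-amino-acid character {ch!r} at position {i}{where}"
            )
    return up


@dataclass
class SignalPeptideRecord:
    """One predicted Sec/SPI signal peptide.

    ``sp_seq`` ends at the residue immediately before the cleavage site, so
    the cut bond sits between ``len(sp_seq)`` and the first ``downstream``
    residue (1-based coordinates).
    """

    id: str
    sp_seq: str
    downstream: str = ""
    annotation: str = ""
    strain_id: str = ""

    def __post_init__(self) -> None:
        if not self.sp_seq:
            raise FormatError(f"record {self.id!r}: empty signal-peptide sequence")
        self.sp_seq = validate_peptide(self.sp_seq, context=f"record {self.id!r}")
        self.downstream = validate_peptide(
            self.downstream, context=f"record {self.id!r} downstream"
        )
        if len(self.downstream) > 2:
            raise FormatError(
                f"record {self.id!r}: downstream {self.downstream!r} longer than 2 residues"
            )
        if self.sp_seq[0] != "M":
            warnings.warn(
                f"record {self.id!r} does not start with Met; "
                "expected for peptides taken from a CDS start",
                stacklevel=2,
            )

    @property
    def cleavage_position(self) -> int:
        """1-based position of the last signal-peptide residue."""
        return len(self.sp_seq)


@dataclass
class StrainPeptideSet:
    """The set of predicted signal-peptide sequences of one strain."""

    strain_id: str
    peptides: frozenset[str] = field(default_factory=frozenset)
    accession: str = ""

    def __post_init__(self) -> None:
        cleaned = frozenset(
            validate_peptide(p, context=f"strain {self.strain_id!r}") for p in self.peptides
        )
        self.peptides = cleaned

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, seq: str) -> bool:
        return seq.upper() in self.peptides
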