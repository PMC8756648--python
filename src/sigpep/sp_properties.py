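"""Per-peptide sequence properties of Sec signal peptides.

The quantities follow the operational definitions used in genome-wide
screens of lactobacilli signal peptides:

* **N-domain** — from the initial Met up to the last positively charged
  residue (K or R) of the peptide.
* **Net charge** — over the N-domain, with K/R = +1 and D/E = -1 ("signed"
  mode) or counting K/R only ("positive_count" mode).
* **Hydrophobicity** — percent of residues in {G, A, V, L, I, M, F, W, P},
  rounded half-up to an integer.
* **Ala-X-Ala motif** — alanine at positions -3 and -1 relative to the
  cleavage site, the canonical signal peptidase I recognition pattern.

A transmembrane-helix flag can be attached from an external prediction; it
is never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

from ._rounding import round_half_up
from .records import AMBIGUOUS_AA, SignalPeptideRecord, validate_peptide

HYDROPHOBIC = frozenset("GAVLIMFWP")
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

CHARGE_MODES = ("signed", "positive_count")


@dataclass
class PropertyRecord:
    """Computed properties of one signal peptide (one table row)."""

    id: str
    sequence: str
    downstream: str
    length: int
    n_domain_end: int
    net_charge: int
    hydrophobicity_pct: int
    axa_motif: bool
    tm_helix: bool | None = None  # externally supplied; None = unknown
    annotation: str = ""


def n_domain(sp_seq: str, *, allow_ambiguous: bool = False) -> int:
    """1-based index of the last K/R in ``sp_seq``; 1 if there is none.

    The no-K/R fallback keeps the N-domain non-empty (the initial residue
    alone), preserving ``1 <= n_domain_end <= length``.
    """
    seq = validate_peptide(sp_seq, allow_ambiguous=allow_ambiguous, context="n_domain")
    if not seq:
        raise ValueError("n_domain of empty sequence")
    last = 0
    for i, ch in enumerate(seq, start=1):
        if ch in POSITIVE:
            last = i
    return last or 1


def net_charge(
    sp_seq: str, *, mode: str = "signed", allow_ambiguous: bool = False
) -> int:
    """Net charge of the N-domain.

    ``mode='signed'`` applies K/R = +1, D/E = -1; ``mode='positive_count'``
    counts K/R only. Ambiguous codes (permissive mode) contribute zero.
    """
    if mode not in CHARGE_MODES:
        raise ValueError(f"unknown charge mode {mode!r}; expected one of {CHARGE_MODES}")
    seq = validate_peptide(sp_seq, allow_ambiguous=allow_ambiguous, context="net_charge")
    nd = n_domain(seq, allow_ambiguous=allow_ambiguous)
    region = seq[:nd]
    pos = sum(ch in POSITIVE for ch in region)
    if mode == "positive_count":
        return pos
    return pos - sum(ch in NEGATIVE for ch in region)


def hydrophobicity(sp_seq: str, *, allow_ambiguous: bool = False) -> int:
    """Percent hydrophobic residues, rounded half-up to an integer."""
    seq = validate_peptide(sp_seq, allow_ambiguous=allow_ambiguous, context="hydrophobicity")
    if not seq:
        raise ValueError("hydrophobicity of empty sequence")
    count = sum(ch in HYDROPHOBIC for ch in seq)
    return round_half_up(Fraction(100 * count, len(seq)))


def hydrophilicity(sp_seq: str, *, allow_ambiguous: bool = False) -> int:
    """Percent non-hydrophobic residues (complement of the same count)."""
    seq = validate_peptide(sp_seq, allow_ambiguous=allow_ambiguous, context="hydrophilicity")
    if not seq:
        raise ValueError("hydrophilicity of empty sequence")
    count = len(seq) - sum(ch in HYDROPHOBIC for ch in seq)
    # Ambiguous codes count as neither: subtract them from the complement too.
    count -= sum(ch in AMBIGUOUS_AA for ch in seq)
    return round_half_up(Fraction(100 * count, len(seq)))


def axa_motif(sp_seq: str, *, allow_ambiguous: bool = False) -> bool:
    """True iff positions -3 and -1 of the signal peptide are both alanine."""
    seq = validate_peptide(sp_seq, allow_ambiguous=allow_ambiguous, context="axa_motif")
    if len(seq) < 3:
        raise ValueError(f"Ala-X-Ala motif undefined for length {len(seq)} < 3")
    return seq[-1] == "A" and seq[-3] == "A"


def property_table(
    records: Iterable[SignalPeptideRecord],
    helix_flags: Mapping[str, bool] | None = None,
    *,
    charge_mode: str = "signed",
    allow_ambiguous: bool = False,
) -> list[PropertyRecord]:
    """Compute one :class:`PropertyRecord` per input record.

    ``helix_flags`` maps record id to an externally predicted
    transmembrane-helix flag; ids without a flag get ``tm_helix=None``.
    Duplicate record ids are an error (the table is keyed by id).
    """
    recs = list(records)
    seen: dict[str, int] = {}
    for r in recs:
        seen[r.id] = seen.get(r.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate record ids: {', '.join(dups)}")

    out: list[PropertyRecord] = []
    for r in recs:
        out.append(
            PropertyRecord(
                id=r.id,
                sequence=r.sp_seq,
                downstream=r.downstream,
                length=len(r.sp_seq),
                n_domain_end=n_domain(r.sp_seq, allow_ambiguous=allow_ambiguous),
                net_charge=net_charge(
                    r.sp_seq, mode=charge_mode, allow_ambiguous=allow_ambiguous
                ),
                hydrophobicity_pct=hydrophobicity(r.sp_seq, allow_ambiguous=allow_ambiguous),
                axa_motif=axa_motif(r.sp_seq, allow_ambiguous=allow_ambiguous),
                tm_helix=None if helix_flags is None else helix_flags.get(r.id),
                annotation=r.annotation,
            )
        )
    return out
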