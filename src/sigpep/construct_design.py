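"""In-silico design of signal-peptide::protease fusion constructs.

A library fragment is assembled, in order, from: a 20 nt upstream overlap
(homologous to the linearized vector's right end), the Shine–Dalgarno
ribosome binding site (AGGAGG by default), a spacer, the signal-peptide CDS,
the six nucleotides encoding the two residues retained downstream of the
cleavage site, the mature-protein CDS ending in a stop codon, and a 20 nt
downstream overlap (homologous to the vector's left end). Promoter and
terminator are vector-resident context, not fragment parts. Fragments are
merged into the vector by overlap (Gibson-style) assembly, each homology arm
represented once in the resulting circle.

Signal-peptide DNA is taken from the source gene — no back-translation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .records import SignalPeptideRecord

DEFAULT_RBS = "AGGAGG"
DEFAULT_SPACER = "AATTAAA"  # 7 nt between SD sequence and start codon
OVERLAP = 20

STOPS = {"TAA", "TAG", "TGA"}
_DNA = set("ACGT")


class AssemblyError(ValueError):
    """Overlap homology check failed."""


def _check_dna(seq: str, name: str) -> str:
    up = seq.upper()
    bad = set(up) - _DNA
    if bad:
        raise ValueError(f"{name}: non-ACGT characters {sorted(bad)}")
    return up


def _codons(seq: str) -> list[str]:
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


@dataclass
class VectorSpec:
    """A linearized vector whose terminal 20-mers are the assembly landing sites."""

    sequence: str
    name: str = "vector"

    def __post_init__(self) -> None:
        self.sequence = _check_dna(self.sequence, self.name)
        if len(self.sequence) < 2 * OVERLAP:
            raise ValueError(f"{self.name}: shorter than two {OVERLAP} nt overlaps")
        for label, mer in (("left", self.left_overlap), ("right", self.right_overlap)):
            if self.sequence.count(mer) != 1:
                raise AssemblyError(
                    f"{self.name}: {label} terminal {OVERLAP}-mer {mer} is not "
                    "unique within the vector"
                )

    @property
    def left_overlap(self) -> str:
        return self.sequence[:OVERLAP]

    @property
    def right_overlap(self) -> str:
        return self.sequence[-OVERLAP:]


@dataclass
class FusionConstruct:
    """An ordered-parts library fragment ready for overlap assembly."""

    sp_id: str
    upstream_overlap: str
    rbs: str
    spacer: str
    sp_cds: str
    retained_codons: str
    mature_cds: str
    downstream_overlap: str
    source: SignalPeptideRecord | None = field(default=None, repr=False)

    @property
    def orf(self) -> str:
        return self.sp_cds + self.retained_codons + self.mature_cds

    @property
    def fragment(self) -> str:
        return (
            self.upstream_overlap + self.rbs + self.spacer
            + self.orf + self.downstream_overlap
        )

    @property
    def parts(self) -> list[tuple[str, str]]:
        return [
            ("overlap_L", self.upstream_overlap),
            ("RBS", self.rbs),
            ("spacer", self.spacer),
            ("sp_cds", self.sp_cds),
            ("retained", self.retained_codons),
            ("mature_cds", self.mature_cds),
            ("overlap_R", self.downstream_overlap),
        ]

    def translation(self) -> str:
        """Amino-acid sequence of the ORF, stop codon stripped."""
        return str(Seq(self.orf).translate())[:-1]

    def to_seqrecord(self) -> SeqRecord:
        """Annotated linear record of the fragment (1-based inclusive features)."""
        rec = SeqRecord(
            Seq(self.fragment),
            id=f"{self.sp_id}_fusion",
            description=f"signal peptide {self.sp_id} fusion fragment",
            annotations={"molecule_type": "DNA", "topology": "linear"},
        )
        pos = 0
        for label, seq in self.parts:
            if not seq:
                continue
            rec.features.append(
                SeqFeature(
                    FeatureLocation(pos, pos + len(seq)),
                    type="misc_feature",
                    qualifiers={"label": [label]},
                )
            )
            pos += len(seq)
        return rec


def extract_sp_cds(gene_cds: str, cleavage_residue: int) -> tuple[str, str]:
    """Slice the signal-peptide CDS and the two retained codons from a gene.

    ``cleavage_residue`` (k) is the 1-based index of the last signal-peptide
    residue; the cut lies between residues k and k+1. Returns
    ``(first 3k nt, the following 6 nt)``.
    """
    gene = _check_dna(gene_cds, "gene_cds")
    if len(gene) % 3:
        raise ValueError(f"gene length {len(gene)} is not a multiple of 3")
    if not gene.startswith("ATG"):
        raise ValueError("gene does not start with ATG")
    k = cleavage_residue
    if k < 1 or 3 * (k + 2) > len(gene):
        raise IndexError(
            f"cleavage residue {k} out of range for a {len(gene) // 3}-codon gene "
            "(two retained codons must remain)"
        )
    return gene[: 3 * k], gene[3 * k: 3 * k + 6]


def build_fusion(
    sp: SignalPeptideRecord,
    sp_cds: str,
    retained_codons: str,
    mature_cds: str,
    vector: VectorSpec,
    *,
    spacer: str = DEFAULT_SPACER,
    rbs: str = DEFAULT_RBS,
) -> FusionConstruct:
    """Assemble one library fragment, verifying DNA/peptide consistency.

    The translations of ``sp_cds`` and ``retained_codons`` must equal the
    record's signal peptide and downstream residues — the guard against
    cross-contamination between library members — and ``mature_cds`` must be
    in frame with exactly one, terminal, stop codon.
    """
    sp_cds = _check_dna(sp_cds, "sp_cds")
    retained_codons = _check_dna(retained_codons, "retained_codons")
    mature_cds = _check_dna(mature_cds, "mature_cds")
    spacer = _check_dna(spacer, "spacer") if spacer else ""
    rbs = _check_dna(rbs, "rbs")

    if len(sp_cds) % 3:
        raise ValueError("sp_cds length not a multiple of 3")
    if not sp_cds.startswith("ATG"):
        raise ValueError("sp_cds does not start with ATG")
    if len(retained_codons) != 6:
        raise ValueError("retained_codons must be exactly two codons (6 nt)")
    if len(mature_cds) % 3:
        raise ValueError("mature_cds length not a multiple of 3")

    sp_aa = str(Seq(sp_cds).translate())
    if "*" in sp_aa:
        raise ValueError("sp_cds contains an in-frame stop codon")
    if sp_aa != sp.sp_seq:
        raise ValueError(
            f"sp_cds translates to {sp_aa!r}, record {sp.id!r} expects {sp.sp_seq!r}"
        )
    ret_aa = str(Seq(retained_codons).translate())
    if ret_aa != sp.downstream:
        raise ValueError(
            f"retained codons translate to {ret_aa!r}, record {sp.id!r} "
            f"expects {sp.downstream!r}"
        )
    mature_codons = _codons(mature_cds)
    if mature_codons[-1] not in STOPS:
        raise ValueError("mature_cds lacks a terminal stop codon")
    if any(c in STOPS for c in mature_codons[:-1]):
        raise ValueError("mature_cds contains an internal stop codon")
    if not spacer:
        warnings.warn("empty spacer: RBS directly abuts the start codon", stacklevel=2)

    return FusionConstruct(
        sp_id=sp.id,
        upstream_overlap=vector.right_overlap,
        rbs=rbs,
        spacer=spacer,
        sp_cds=sp_cds,
        retained_codons=retained_codons,
        mature_cds=mature_cds,
        downstream_overlap=vector.left_overlap,
        source=sp,
    )


def assemble(construct: FusionConstruct | str, vector: VectorSpec) -> SeqRecord:
    """Merge a fragment into the vector by its two 20 nt homology arms.

    The fragment must start with the vector's right terminal 20-mer and end
    with its left terminal 20-mer; each overlap appears once in the circular
    product, so ``len(circle) == len(vector) + len(fragment) − 40``.
    """
    fragment = construct.fragment if isinstance(construct, FusionConstruct) else _check_dna(construct, "fragment")
    if len(fragment) < 2 * OVERLAP:
        raise AssemblyError("fragment shorter than its two overlaps")
    for label, got, want in (
        ("upstream", fragment[:OVERLAP], vector.right_overlap),
        ("downstream", fragment[-OVERLAP:], vector.left_overlap),
    ):
        if got != want:
            at = next(i for i, (a, b) in enumerate(zip(got, want)) if a != b)
            raise AssemblyError(
                f"{label} overlap mismatch at offset {at}: fragment has "
                f"{got[at]!r}, vector has {want[at]!r}"
            )
    circle = vector.sequence + fragment[OVERLAP:-OVERLAP]
    name = construct.sp_id if isinstance(construct, FusionConstruct) else "insert"
    rec = SeqRecord(
        Seq(circle),
        id=f"{vector.name}_{name}",
        description=f"circular assembly of {name} into {vector.name}",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    rec.features.append(
        SeqFeature(
            FeatureLocation(0, len(vector.sequence)),
            type="misc_feature",
            qualifiers={"label": ["vector"]},
        )
    )
    if isinstance(construct, FusionConstruct):
        pos = len(vector.sequence) - OVERLAP
        for label, seq in construct.parts:
            if not seq:
                continue
            end = pos + len(seq)
            if label == "overlap_R":
                end = min(end, len(circle))
            rec.features.append(
                SeqFeature(
                    FeatureLocation(pos % len(circle), end),
                    type="misc_feature",
                    qualifiers={"label": [label]},
                )
            )
            pos += len(seq)
    return rec


def build_library(
    entries: Iterable[tuple[SignalPeptideRecord, str]],
    mature_cds: str,
    vector: VectorSpec,
    *,
    spacer: str = DEFAULT_SPACER,
    rbs: str = DEFAULT_RBS,
) -> list[FusionConstruct]:
    """Build one fusion per (record, source gene CDS) pair.

    Each gene CDS is sliced at the record's cleavage position to obtain the
    signal-peptide CDS and retained codons, then fused to the shared mature
    CDS.
    """
    out = []
    for sp, gene in entries:
        sp_cds, retained = extract_sp_cds(gene, sp.cleavage_position)
        out.append(
            build_fusion(
                sp, sp_cds, retained, mature_cds, vector, spacer=spacer, rbs=rbs
            )
        )
    return out
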