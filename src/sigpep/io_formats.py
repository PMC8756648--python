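"""Readers and writers for every external representation the pipeline touches.

Formats handled:

* arrow-notation peptide cells, ``MQLLK...LA↓AS`` (``|`` accepted as ASCII
  dialect for the arrow);
* FASTA of signal peptides, with the downstream residues and provenance
  encoded in the description so a plain FASTA reader still gets the sequence;
* cleavage-site prediction tables — the tab-separated summary a signal-peptide
  predictor emits (classification column plus a ``CS pos:`` column) or a
  minimal three-column TSV (id, class, cut_after);
* per-strain peptide FASTA files;
* TSV property tables and helix-flag files.

All text I/O is UTF-8 with Unix newlines.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    FormatError,
    SignalPeptideRecord,
    StrainPeptideSet,
    validate_peptide,
)
from .sp_properties import PropertyRecord

ARROW = "↓"
_ARROW_RE = re.compile(rf"[{ARROW}|]")

#: Classification label marking a general-secretion, signal peptidase I peptide.
SEC_SPI = "SP(SEC/SPI)"

PROPERTY_COLUMNS = [
    "id",
    "sequence",
    "downstream",
    "length",
    "n_domain_end",
    "net_charge",
    "hydrophobicity_pct",
    "axa_motif",
    "tm_helix",
    "annotation",
]


# ---------------------------------------------------------------------------
# arrow notation
# ---------------------------------------------------------------------------

def parse_arrow_notation(
    text: str,
    *,
    id: str = "",
    annotation: str = "",
    strain_id: str = "",
    allow_ambiguous: bool = False,
) -> SignalPeptideRecord:
    """Parse one arrow-notation cell, e.g. ``"MQLLK...SGLA↓AS"``.

    The cell holds the signal peptide, the cleavage arrow (``↓`` or ``|``)
    and the residues retained downstream of the cut. More than two downstream
    residues are truncated to two with a warning (two are retained when
    building fusions).
    """
    parts = _ARROW_RE.split(text.strip())
    if len(parts) != 2:
        n = len(parts) - 1
        raise FormatError(
            f"expected exactly one cleavage arrow in {text!r}, found {n}"
        )
    sp_seq, downstream = parts
    sp_seq = validate_peptide(sp_seq, allow_ambiguous=allow_ambiguous, context=id or text)
    downstream = validate_peptide(
        downstream, allow_ambiguous=allow_ambiguous, context=f"{id or text} downstream"
    )
    if len(downstream) > 2:
        warnings.warn(
            f"{id or text}: truncating downstream {downstream!r} to two residues",
            stacklevel=2,
        )
        downstream = downstream[:2]
    return SignalPeptideRecord(
        id=id, sp_seq=sp_seq, downstream=downstream,
        annotation=annotation, strain_id=strain_id,
    )


def format_arrow_notation(record: SignalPeptideRecord, *, ascii_arrow: bool = False) -> str:
    """Inverse of :func:`parse_arrow_notation` for valid records."""
    arrow = "|" if ascii_arrow else ARROW
    return f"{record.sp_seq}{arrow}{record.downstream}"


# ---------------------------------------------------------------------------
# record FASTA dialect
# ---------------------------------------------------------------------------

def write_records_fasta(records: Iterable[SignalPeptideRecord], path: str | Path) -> None:
    """Write records as FASTA: ``>id strain=<s> downstream=<xy> function=<text>``."""
    seqs = []
    for r in records:
        desc = f"strain={r.strain_id} downstream={r.downstream} function={r.annotation}"
        seqs.append(SeqRecord(Seq(r.sp_seq), id=r.id, description=desc))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_records_fasta(path: str | Path, *, allow_ambiguous: bool = False) -> list[SignalPeptideRecord]:
    """Read the FASTA dialect written by :func:`write_records_fasta`."""
    out: list[SignalPeptideRecord] = []
    for seq in SeqIO.parse(str(path), "fasta"):
        desc = seq.description[len(seq.id):].strip() if seq.description.startswith(seq.id) else seq.description
        fields = dict(re.findall(r"(strain|downstream|function)=((?:(?!\s\w+=).)*)", desc))
        out.append(
            SignalPeptideRecord(
                id=seq.id,
                sp_seq=validate_peptide(str(seq.seq), allow_ambiguous=allow_ambiguous, context=seq.id),
                downstream=fields.get("downstream", "").strip(),
                annotation=fields.get("function", "").strip(),
                strain_id=fields.get("strain", "").strip(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# cleavage-site prediction tables
# ---------------------------------------------------------------------------

_CS_POS_RE = re.compile(r"CS pos:\s*(\d+)-(\d+)")


def _parse_prediction_rows(path: str | Path) -> list[tuple[str, str, int | None]]:
    """Yield (protein id, classification, cut_after) from either dialect."""
    rows: list[tuple[str, str, int | None]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"unparseable prediction row: {line!r}")
            pid, klass = parts[0], parts[1]
            cut: int | None = None
            m = _CS_POS_RE.search(line)
            if m:
                cut = int(m.group(1))
            elif len(parts) >= 3 and parts[2].strip():
                try:
                    cut = int(parts[2])
                except ValueError:
                    cut = None
            rows.append((pid, klass, cut))
    return rows


def parse_prediction_table(
    proteome: str | Path | Iterable[SeqRecord],
    predictions: str | Path,
    *,
    strain_id: str = "",
    allow_ambiguous: bool = False,
) -> tuple[list[SignalPeptideRecord], int]:
    """Extract signal-peptide records from a proteome plus a prediction table.

    For each row classified Sec/SPI with cleavage site "between k and k+1",
    emits a record with ``sp_seq`` = residues 1..k of the protein and
    ``downstream`` = residues k+1..k+2 (or fewer at the protein end).
    Returns ``(records, n_skipped)`` where ``n_skipped`` counts non-signal rows.
    """
    if isinstance(proteome, (str, Path)):
        proteins = {s.id: str(s.seq) for s in SeqIO.parse(str(proteome), "fasta")}
    else:
        proteins = {s.id: str(s.seq) for s in proteome}

    records: list[SignalPeptideRecord] = []
    skipped = 0
    for pid, klass, cut in _parse_prediction_rows(predictions):
        if klass.strip().upper() != SEC_SPI:
            skipped += 1
            continue
        if pid not in proteins:
            raise KeyError(f"predicted protein {pid!r} absent from proteome")
        prot = proteins[pid]
        if cut is None:
            raise FormatError(f"signal-peptide row {pid!r} lacks a cleavage position")
        if cut > len(prot):  # cut == length is legal: nothing downstream remains
            raise IndexError(
                f"{pid!r}: cleavage after residue {cut} but protein has {len(prot)} residues"
            )
        records.append(
            SignalPeptideRecord(
                id=pid,
                sp_seq=validate_peptide(prot[:cut], allow_ambiguous=allow_ambiguous, context=pid),
                downstream=prot[cut:cut + 2],
                strain_id=strain_id,
            )
        )
    return records, skipped


# ---------------------------------------------------------------------------
# strain sets
# ---------------------------------------------------------------------------

def read_strain_sets(
    paths: Sequence[str | Path], *, allow_ambiguous: bool = False
) -> list[StrainPeptideSet]:
    """Read one peptide FASTA per strain; strain_id comes from the file stem.

    Duplicate sequences within a file collapse to one (set semantics); an
    empty file yields an empty set with a warning.
    """
    sets: list[StrainPeptideSet] = []
    for p in paths:
        p = Path(p)
        peptides = set()
        for seq in SeqIO.parse(str(p), "fasta"):
            peptides.add(validate_peptide(str(seq.seq), allow_ambiguous=allow_ambiguous, context=f"{p.name}:{seq.id}"))
        if not peptides:
            warnings.warn(f"strain file {p} contains no sequences", stacklevel=2)
        sets.append(StrainPeptideSet(strain_id=p.stem, peptides=frozenset(peptides)))
    return sets


def write_strain_set(sset: StrainPeptideSet, path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(pep), id=f"{sset.strain_id}_{i:04d}", description="")
        for i, pep in enumerate(sorted(sset.peptides), start=1)
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(seqs, fh, "fasta")


# ---------------------------------------------------------------------------
# property tables and helix flags
# ---------------------------------------------------------------------------

def write_property_table(props: Iterable[PropertyRecord], path: str | Path) -> None:
    """Write a TSV property table with a fixed, documented column order."""
    df = pd.DataFrame(
        [
            {
                "id": p.id,
                "sequence": p.sequence,
                "downstream": p.downstream,
                "length": p.length,
                "n_domain_end": p.n_domain_end,
                "net_charge": p.net_charge,
                "hydrophobicity_pct": p.hydrophobicity_pct,
                "axa_motif": int(p.axa_motif),
                "tm_helix": "" if p.tm_helix is None else int(p.tm_helix),
                "annotation": p.annotation,
            }
            for p in props
        ],
        columns=PROPERTY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_helix_flags(path: str | Path) -> dict[str, bool]:
    """Read a 2-column TSV (id, yes/no) of external transmembrane-helix calls."""
    flags: dict[str, bool] = {}
    truthy = {"yes", "y", "true", "1"}
    falsy = {"no", "n", "false", "0"}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, val = line.split("\t")[:2]
            v = val.strip().lower()
            if v in truthy:
                flags[pid] = True
            elif v in falsy:
                flags[pid] = False
            else:
                raise FormatError(f"helix flag for {pid!r} must be yes/no, got {val!r}")
    return flags


# ---------------------------------------------------------------------------
# packaged screening-table fixture
# ---------------------------------------------------------------------------

def load_screened_peptides() -> tuple[list[SignalPeptideRecord], pd.DataFrame]:
    """Load the packaged table of the 29 screened signal peptides.

    Returns the parsed records plus a DataFrame carrying, per peptide, the
    published length / net charge / hydrophobicity values, the secretion
    group ("with"/"without" protease secretion), the Ala-X-Ala flag and the
    externally predicted transmembrane-helix flag.
    """
    ref = resources.files("sigpep") / "data" / "screened_signal_peptides.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    records = [
        parse_arrow_notation(
            row.sequence, id=row.id, annotation=row.annotation, strain_id=""
        )
        for row in df.itertuples()
    ]
    return records, df
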