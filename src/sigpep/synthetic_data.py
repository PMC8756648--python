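"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and seed and carries its
ground truth alongside the data, so downstream stages can be tested by exact
recovery rather than against external downloads:

* tripartite signal peptides — a charged N-domain (ending in K/R so the
  N-domain boundary is planted exactly), a hydrophobic H-domain drawn from
  {G,A,V,L,I,M,F,W,P}, and a polar C-domain whose −3/−1 positions are forced
  to alanine with probability ``p_axa``;
* strain panels with *constructively* planted pairwise Jaccard similarity
  (shared core + sized private sets, so recovery is exact, not statistical);
* fluorescence plates with planted per-clone effects under multiplicative
  Gaussian noise truncated at zero;
* proteomes plus matching cleavage-site prediction tables for end-to-end
  fixture generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .records import SignalPeptideRecord, StrainPeptideSet
from .screen_analysis import PlateMeasurement

# Residue pools for the three domains. K/R are confined to the N-domain so
# that the planted N-domain boundary is exactly what the property code finds.
N_DOMAIN_POOL = "KRNQSTHMAG"
H_DOMAIN_POOL = "GAVLIMFWP"
C_DOMAIN_POOL = "STNQGHYA"
DOWNSTREAM_POOL = "ADEGHKNQST"


@dataclass
class SpGenParams:
    """Knobs of the tripartite signal-peptide generator."""

    n_min: int = 2            # N-domain residues after the initial Met
    n_max: int = 8
    h_min: int = 10           # hydrophobic core length
    h_max: int = 18
    c_min: int = 4            # polar C-domain length (>= 3 so the motif fits)
    c_max: int = 8
    p_kr: float = 0.4         # K/R enrichment inside the N-domain
    p_axa: float = 0.5        # probability of forcing Ala at -3 and -1
    c_alphabet: str = C_DOMAIN_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_kr, self.p_axa):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_min, self.h_min, self.c_min) < 1 or self.c_min < 3:
            raise ValueError("domain lengths must be >= 1 and C-domain >= 3")


def _one_peptide(rng: np.random.Generator, params: SpGenParams) -> tuple[str, bool]:
    n_len = int(rng.integers(params.n_min, params.n_max + 1))
    h_len = int(rng.integers(params.h_min, params.h_max + 1))
    c_len = int(rng.integers(params.c_min, params.c_max + 1))

    n_dom = [
        "KR"[rng.integers(2)] if rng.random() < params.p_kr
        else N_DOMAIN_POOL[2:][rng.integers(len(N_DOMAIN_POOL) - 2)]
        for _ in range(n_len)
    ]
    n_dom[-1] = "KR"[rng.integers(2)]  # plant the N-domain boundary
    h_dom = [H_DOMAIN_POOL[rng.integers(len(H_DOMAIN_POOL))] for _ in range(h_len)]
    c_dom = [params.c_alphabet[rng.integers(len(params.c_alphabet))] for _ in range(c_len)]
    has_motif = rng.random() < params.p_axa
    if has_motif:
        c_dom[-1] = "A"
        c_dom[-3] = "A"
    return "M" + "".join(n_dom + h_dom + c_dom), has_motif


def gen_signal_peptides(
    params: SpGenParams, n: int, *, id_prefix: str = "SP"
) -> tuple[list[SignalPeptideRecord], dict]:
    """Generate ``n`` records plus realized summary statistics.

    The returned info dict reports the realized Ala-X-Ala fraction and mean
    hydrophobicity, and the planted N-domain end per peptide.
    """
    from .sp_properties import axa_motif, hydrophobicity

    rng = np.random.default_rng(params.seed)
    records: list[SignalPeptideRecord] = []
    planted_n_end: dict[str, int] = {}
    for i in range(n):
        seq, _ = _one_peptide(rng, params)
        ds = "".join(DOWNSTREAM_POOL[rng.integers(len(DOWNSTREAM_POOL))] for _ in range(2))
        pid = f"{id_prefix}_{i + 1:05d}"
        records.append(
            SignalPeptideRecord(id=pid, sp_seq=seq, downstream=ds, annotation="synthetic")
        )
        planted_n_end[pid] = max(
            idx for idx, ch in enumerate(seq, start=1) if ch in "KR"
        )
    info = {
        "motif_fraction": (
            sum(axa_motif(r.sp_seq) for r in records) / n if n else 0.0
        ),
        "mean_hydrophobicity": (
            float(np.mean([hydrophobicity(r.sp_seq) for r in records])) if n else 0.0
        ),
        "planted_n_domain_end": planted_n_end,
    }
    return records, info


# ---------------------------------------------------------------------------
# strain panels with exact planted Jaccard
# ---------------------------------------------------------------------------

@dataclass
class PanelGenParams:
    """Constructive strain-panel generator parameters.

    Every strain holds ``set_size`` peptides: a core shared within its block
    (all strains form one block by default) plus private peptides sized so
    each within-block pair realizes ``target_jaccard`` exactly. Across
    blocks nothing is shared (Jaccard 0).
    """

    n_strains: int = 4
    set_size: int = 30
    target_jaccard: float = 0.5
    blocks: Sequence[Sequence[int]] | None = None  # strain-index groups
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2 or self.set_size < 1:
            raise ValueError("need >= 2 strains and >= 1 peptide per strain")
        if not 0.0 <= self.target_jaccard <= 1.0:
            raise ValueError("target Jaccard must lie in [0, 1]")

    @property
    def core_size(self) -> int:
        """Shared-core size c solving J = c / (2s − c) for set size s.

        Raises if no integer c fits, suggesting the nearest feasible target.
        """
        j = Fraction(self.target_jaccard).limit_denominator(10**6)
        c = 2 * self.set_size * j / (1 + j)
        if c.denominator != 1:
            near = round(c)
            feasible = Fraction(near, 2 * self.set_size - near)
            raise ValueError(
                f"target Jaccard {self.target_jaccard} infeasible for set size "
                f"{self.set_size}; nearest feasible target is {float(feasible):.6g} "
                f"(core of {near})"
            )
        return int(c)


def _unique_peptides(rng: np.random.Generator, params: SpGenParams, n: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq, _ = _one_peptide(rng, params)
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def gen_strain_panel(
    params: PanelGenParams, sp_params: SpGenParams | None = None
) -> list[StrainPeptideSet]:
    """Build a panel whose realized pairwise Jaccard equals the target exactly."""
    sp_params = sp_params or SpGenParams(seed=params.seed)
    rng = np.random.default_rng(params.seed)
    core = params.core_size
    private = params.set_size - core
    blocks = params.blocks or [list(range(params.n_strains))]
    claimed = sorted(i for b in blocks for i in b)
    if claimed != list(range(params.n_strains)):
        raise ValueError("blocks must partition the strain indices exactly once")

    total = len(blocks) * core + params.n_strains * private
    pool = iter(_unique_peptides(rng, sp_params, total))
    sets: list[StrainPeptideSet | None] = [None] * params.n_strains
    for block in blocks:
        block_core = frozenset(next(pool) for _ in range(core))
        for idx in block:
            own = frozenset(next(pool) for _ in range(private))
            sets[idx] = StrainPeptideSet(
                strain_id=f"strain_{idx + 1:02d}", peptides=block_core | own
            )
    return list(sets)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# fluorescence plates
# ---------------------------------------------------------------------------

def gen_plate(
    n_clones: int,
    *,
    control_mean: float = 1000.0,
    cv: float = 0.05,
    effects: Mapping[str, float] | None = None,
    seed: int = 0,
    controls_per_plate: int = 3,
    wells_per_plate: int = 96,
) -> tuple[list[PlateMeasurement], dict[str, float]]:
    """Simulate a plate batch with planted per-clone effects.

    Clone wells read ``control_mean · (1 + effect) · (1 + ε)`` and control
    wells ``control_mean · (1 + ε)``, with ε zero-mean Gaussian of relative
    SD ``cv`` truncated so intensities stay nonnegative. Clones are laid out
    across as many 96-well plates as needed; every plate carries its own
    control wells. Returns the measurements and the planted effect per clone.
    """
    if cv < 0:
        raise ValueError("noise CV must be nonnegative")
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    rng = np.random.default_rng(seed)
    effects = dict(effects or {})

    def noisy(base: float) -> float:
        return max(0.0, base * (1.0 + rng.normal(0.0, cv))) if cv else base

    per_plate = wells_per_plate - controls_per_plate
    measurements: list[PlateMeasurement] = []
    truth: dict[str, float] = {}
    clone_ids = [f"clone_{i + 1:04d}" for i in range(n_clones)]
    rows = "ABCDEFGH"
    for p_start in range(0, n_clones, per_plate):
        plate_id = f"plate_{p_start // per_plate + 1:02d}"
        wells = (f"{r}{c}" for c in range(1, 13) for r in rows)
        for _ in range(controls_per_plate):
            measurements.append(
                PlateMeasurement(plate_id, next(wells), "control", noisy(control_mean), True)
            )
        for clone_id in clone_ids[p_start: p_start + per_plate]:
            effect = float(effects.get(clone_id, 0.0))
            truth[clone_id] = effect
            measurements.append(
                PlateMeasurement(
                    plate_id, next(wells), clone_id,
                    noisy(control_mean * (1.0 + effect)), False,
                )
            )
    return measurements, truth


# ---------------------------------------------------------------------------
# proteomes + prediction tables
# ---------------------------------------------------------------------------

def gen_proteome(
    n_secretory: int,
    n_other: int,
    params: SpGenParams | None = None,
    *,
    mature_len: int = 120,
    downstream: str | None = None,
    id_prefix: str = "PROT",
) -> tuple[list, "object", list[SignalPeptideRecord]]:
    """Generate a proteome FASTA plus a matching cleavage-site table.

    Secretory proteins are a planted signal peptide followed by its two
    downstream residues and a random mature tail; the prediction table has
    one Sec/SPI row per secretory protein (cleavage between k and k+1) and
    an OTHER row per remaining protein. Returns
    ``(SeqRecords, prediction DataFrame, planted records)`` — running the
    prediction-table parser on the pair must recover the planted records
    exactly.
    """
    import pandas as pd
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    params = params or SpGenParams()
    rng = np.random.default_rng(params.seed)
    mature_pool = "ACDEFGHIKLMNPQRSTVWY"

    def tail(n: int) -> str:
        return "".join(mature_pool[rng.integers(len(mature_pool))] for _ in range(n))

    sp_records, _ = gen_signal_peptides(params, n_secretory, id_prefix=id_prefix)
    planted: list[SignalPeptideRecord] = []
    proteins: list[SeqRecord] = []
    rows = []
    for rec in sp_records:
        ds = downstream if downstream is not None else rec.downstream
        rec = SignalPeptideRecord(
            id=rec.id, sp_seq=rec.sp_seq, downstream=ds,
            annotation=rec.annotation, strain_id=rec.strain_id,
        )
        planted.append(rec)
        k = rec.cleavage_position
        protein = rec.sp_seq + rec.downstream + tail(max(0, mature_len - 2))
        proteins.append(SeqRecord(Seq(protein), id=rec.id, description="secretory"))
        rows.append(
            {
                "id": rec.id,
                "prediction": "SP(Sec/SPI)",
                "cut_after": k,
                "cs_note": f"CS pos: {k}-{k + 1}. Pr: 0.97",
            }
        )
    for i in range(n_other):
        pid = f"{id_prefix}_O{i + 1:05d}"
        proteins.append(
            SeqRecord(Seq("M" + tail(mature_len - 1)), id=pid, description="cytoplasmic")
        )
        rows.append({"id": pid, "prediction": "OTHER", "cut_after": "", "cs_note": ""})
    table = pd.DataFrame(rows, columns=["id", "prediction", "cut_after", "cs_note"])
    return proteins, table, planted


# One codon per amino acid, used only to fabricate synthetic source genes.
# Real pipelines take signal-peptide DNA from the genome; this table exists so
# generated peptides come with a consistent in-silico gene to slice.
CODON_BY_AA = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
    "*": "TAA",
}


def synthetic_gene(protein: str, *, stop: bool = True) -> str:
    """Deterministic DNA coding for ``protein`` (synthetic fixture only)."""
    return "".join(CODON_BY_AA[aa] for aa in protein.upper()) + ("TAA" if stop else "")


def gen_source_genes(records: Sequence[SignalPeptideRecord], *, tail_len: int = 30) -> dict[str, str]:
    """A synthetic source-gene CDS per record: SP + downstream + poly-Gly tail.

    Slicing each gene at the record's cleavage position recovers the
    signal-peptide CDS and the two retained codons by construction.
    """
    return {
        r.id: synthetic_gene(r.sp_seq + r.downstream + "G" * tail_len)
        for r in records
    }


def write_prediction_table(table, path: str | Path) -> None:
    """Write the generated prediction table in the minimal TSV dialect."""
    table[["id", "prediction", "cut_after"]].to_csv(
        path, sep="\t", index=False, header=False, lineterminator="\n"
    )


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """JSON sidecar with the planted ground truth of a generated dataset."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
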