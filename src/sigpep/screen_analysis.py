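"""Fluorescence plate-screen analysis for secretion-capacity screening.

A library of signal-peptide::protease clones is grown in 96-well plates and
extracellular protease activity is read out as fluorescence. Each clone's
*relative improvement* is its mean fluorescence over the mean of the control
wells (clones carrying the benchmark signal peptide), minus one. First-round
hits are shortlisted at an inclusive fold-change threshold, deduplicated to
unique signal-peptide sequences after sequencing, and confirmed in a
triplicate second round with a two-sample t test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .group_stats import student_t

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ["plate_id", "well", "clone_id", "fluorescence", "is_control"]


@dataclass
class PlateMeasurement:
    """One well: plate, position, clone and its fluorescence readout."""

    plate_id: str
    well: str
    clone_id: str
    fluorescence: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.fluorescence < 0:
            raise ValueError(
                f"negative fluorescence {self.fluorescence} in well "
                f"{self.plate_id}/{self.well}"
            )


@dataclass
class ScreenResult:
    """Per-clone screening outcome."""

    clone_id: str
    improvement: float          # fractional gain over the control mean
    shortlisted: bool
    sequence: str | None = None  # filled in after sequencing
    wells: list[str] = field(default_factory=list)


def relative_improvement(
    clone_values: Sequence[float], control_values: Sequence[float]
) -> float:
    """(mean(clone) − mean(control)) / mean(control)."""
    if len(clone_values) == 0 or len(control_values) == 0:
        raise ValueError("need at least one clone and one control measurement")
    control_mean = sum(control_values) / len(control_values)
    if control_mean <= 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    clone_mean = sum(clone_values) / len(clone_values)
    return (clone_mean - control_mean) / control_mean


def analyze_plates(
    measurements: Iterable[PlateMeasurement],
    *,
    threshold: float = 0.2,
    per_plate_control: bool = True,
) -> list[ScreenResult]:
    """Compute every clone's improvement and shortlist status.

    Controls are averaged per plate by default (absorbing plate-to-plate
    effects); ``per_plate_control=False`` normalizes every clone against the
    global control mean.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    ms = list(measurements)
    controls: dict[str, list[float]] = {}
    for m in ms:
        if m.is_control:
            controls.setdefault(m.plate_id, []).append(m.fluorescence)
    if not controls:
        raise ValueError("no control wells designated")
    global_controls = [v for vals in controls.values() for v in vals]

    clones: dict[str, list[PlateMeasurement]] = {}
    for m in ms:
        if not m.is_control:
            clones.setdefault(m.clone_id, []).append(m)

    results: list[ScreenResult] = []
    for clone_id in sorted(clones):
        wells = clones[clone_id]
        plates = {w.plate_id for w in wells}
        if per_plate_control:
            missing = plates - controls.keys()
            if missing:
                raise ValueError(
                    f"clone {clone_id!r} measured on plates without controls: "
                    f"{', '.join(sorted(missing))}"
                )
            ctrl = [v for p in sorted(plates) for v in controls[p]]
        else:
            ctrl = global_controls
        imp = relative_improvement([w.fluorescence for w in wells], ctrl)
        results.append(
            ScreenResult(
                clone_id=clone_id,
                improvement=imp,
                shortlisted=imp >= threshold,
                wells=[f"{w.plate_id}/{w.well}" for w in wells],
            )
        )
    return results


def shortlist(results: Iterable[ScreenResult], threshold: float) -> list[ScreenResult]:
    """Clones whose improvement meets the (inclusive) threshold."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return [r for r in results if r.improvement >= threshold]


def dedupe_to_signal_peptides(
    shortlisted: Iterable[ScreenResult],
) -> list[tuple[str, int, list[str]]]:
    """Collapse sequenced clones to unique signal peptides with clone counts.

    Returns ``(sequence, n_clones, clone_ids)`` tuples sorted by count
    descending, then by first clone id. Clones without a sequence are
    excluded with a warning.
    """
    by_seq: dict[str, list[str]] = {}
    for r in shortlisted:
        if r.sequence is None:
            warnings.warn(f"clone {r.clone_id!r} has no sequence; excluded", stacklevel=2)
            continue
        by_seq.setdefault(r.sequence.upper(), []).append(r.clone_id)
    return sorted(
        ((seq, len(ids), sorted(ids)) for seq, ids in by_seq.items()),
        key=lambda t: (-t[1], t[2][0]),
    )


def oversampling(
    n_clones: int, library_size: int, *, target_fold: float = 10.0
) -> tuple[float, bool]:
    """Fold coverage of the library by picked clones, and whether it exceeds
    the target (the screen aims for > 10-fold to cover every member)."""
    if library_size < 1:
        raise ValueError("library size must be at least 1")
    fold = n_clones / library_size
    return fold, fold > target_fold


def confirm_round2(
    candidate: Sequence[float],
    control: Sequence[float],
    *,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> tuple[float, float, bool]:
    """Triplicate confirmation: percent increase, p-value, confirmed flag.

    ``confirmed`` iff the candidate's mean exceeds the control's and the
    two-sided t-test p-value is below ``alpha``. Degenerate zero-variance
    replicates inherit the 0/1 p-value conventions of
    :func:`sigpep.group_stats.student_t`.
    """
    if len(candidate) < 3 or len(control) < 3:
        raise ValueError("second-round confirmation requires triplicates")
    pct = 100.0 * relative_improvement(candidate, control)
    _, p = student_t(candidate, control, equal_var=equal_var)
    return pct, p, (pct > 0 and p < alpha)


# ---------------------------------------------------------------------------
# plate TSV I/O
# ---------------------------------------------------------------------------

def read_plate_tsv(path: str | Path) -> list[PlateMeasurement]:
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "well": str, "clone_id": str})
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {', '.join(sorted(missing))}")
    return [
        PlateMeasurement(
            plate_id=r.plate_id,
            well=r.well,
            clone_id=r.clone_id,
            fluorescence=float(r.fluorescence),
            is_control=bool(int(r.is_control)),
        )
        for r in df.itertuples()
    ]


def write_plate_tsv(measurements: Iterable[PlateMeasurement], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "plate_id": m.plate_id,
                "well": m.well,
                "clone_id": m.clone_id,
                "fluorescence": m.fluorescence,
                "is_control": int(m.is_control),
            }
            for m in measurements
        ],
        columns=PLATE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_results(results: Iterable[ScreenResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "clone_id": r.clone_id,
                "improvement": r.improvement,
                "shortlisted": int(r.shortlisted),
                "sequence": r.sequence or "",
            }
            for r in results
        ],
        columns=["clone_id", "improvement", "shortlisted", "sequence"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
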