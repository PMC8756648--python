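"""Group summaries and two-sample comparisons of signal-peptide properties.

Secreting vs non-secreting peptides are summarized per group (means to one
decimal, motif/helix percentages to whole percent) and compared property by
property with a two-sample t test. The pooled-variance Student's test is the
default; Welch's unequal-variance variant is available via ``equal_var=False``
— on the screened-peptide reference table only the Welch variant reproduces
the published p-values, see the methods note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from ._rounding import mean_half_up, round_half_up
from .sp_properties import PropertyRecord

logger = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    """Per-group averages over per-peptide properties."""

    label: str
    n: int
    mean_length: float
    mean_charge: float
    mean_hydrophobicity: float
    pct_motif: int
    pct_helix: int | None  # None when no member has a known helix flag


@dataclass
class GroupComparison:
    """Two-sided p-values comparing two groups property by property."""

    p_length: float
    p_charge: float
    p_hydrophobicity: float

    def all_above(self, alpha: float = 0.05) -> bool:
        return min(self.p_length, self.p_charge, self.p_hydrophobicity) > alpha


def student_t(
    a: Sequence[float], b: Sequence[float], *, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p-value.

    ``equal_var=True`` is the classical pooled-variance Student's test with
    ``n_a + n_b - 2`` degrees of freedom; ``False`` is Welch's test.
    Degenerate zero-variance input follows the convention p = 1 for equal
    means and p = 0 otherwise (logged, since it signals constant replicates).
    """
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    var_a = stats.tvar(a) if len(set(a)) > 1 else 0.0
    var_b = stats.tvar(b) if len(set(b)) > 1 else 0.0
    if var_a == 0.0 and var_b == 0.0:
        ma, mb = math.fsum(a) / len(a), math.fsum(b) / len(b)
        if math.isclose(ma, mb):
            logger.warning("zero variance in both samples with equal means; p := 1")
            return 0.0, 1.0
        logger.warning("zero variance in both samples with unequal means; p := 0")
        return math.copysign(math.inf, ma - mb), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def _group_members(
    props: Iterable[PropertyRecord], labels: Mapping[str, str]
) -> dict[str, list[PropertyRecord]]:
    groups: dict[str, list[PropertyRecord]] = {}
    for p in props:
        if p.id not in labels:
            raise KeyError(f"record {p.id!r} has no group label")
        groups.setdefault(labels[p.id], []).append(p)
    return groups


def group_summary(
    props: Iterable[PropertyRecord], labels: Mapping[str, str]
) -> dict[str, GroupSummary]:
    """Summarize each labelled group of peptides.

    Means are taken over the per-peptide values as tabulated (the integer
    hydrophobicity percentages, not the raw fractions) and rounded half-up to
    one decimal; motif and helix percentages round to whole percent. The
    helix percentage is computed only over members with a known flag.
    """
    out: dict[str, GroupSummary] = {}
    for label, members in _group_members(props, labels).items():
        n = len(members)
        known_helix = [p for p in members if p.tm_helix is not None]
        pct_helix = (
            round_half_up(100 * sum(p.tm_helix for p in known_helix) / len(known_helix))
            if known_helix
            else None
        )
        out[label] = GroupSummary(
            label=label,
            n=n,
            mean_length=mean_half_up(p.length for p in members),
            mean_charge=mean_half_up(p.net_charge for p in members),
            mean_hydrophobicity=mean_half_up(p.hydrophobicity_pct for p in members),
            pct_motif=round_half_up(100 * sum(p.axa_motif for p in members) / n),
            pct_helix=pct_helix,
        )
    return out


def compare_groups(
    props: Iterable[PropertyRecord],
    labels: Mapping[str, str],
    group_a: str,
    group_b: str,
    *,
    equal_var: bool = True,
) -> GroupComparison:
    """t-test each numeric property between two labelled groups."""
    groups = _group_members(props, labels)
    for g in (group_a, group_b):
        if g not in groups:
            raise KeyError(f"no records labelled {g!r}")
    a, b = groups[group_a], groups[group_b]
    return GroupComparison(
        p_length=student_t([p.length for p in a], [p.length for p in b], equal_var=equal_var)[1],
        p_charge=student_t([p.net_charge for p in a], [p.net_charge for p in b], equal_var=equal_var)[1],
        p_hydrophobicity=student_t(
            [p.hydrophobicity_pct for p in a], [p.hydrophobicity_pct for p in b], equal_var=equal_var
        )[1],
    )
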