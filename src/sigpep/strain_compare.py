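"""Pairwise shared-signal-peptide analysis across a strain panel.

Given each strain's set of predicted signal peptides, this module builds the
shared-count matrix (|A∩B| for every pair), the percent-shared similarity
matrix (the Jaccard index × 100, i.e. shared over total unique-plus-shared
peptides), the presence of query peptides across the panel, summary
statistics over the off-diagonal similarities, and a deterministic
average-linkage clustering order for heatmap export.

"Shared" means exact amino-acid string equality (case-insensitive); an
optional global-identity threshold relaxes the presence query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .records import SignalPeptideRecord, StrainPeptideSet


@dataclass
class SimilarityMatrix:
    """Shared-count and percent-shared (Jaccard × 100) matrices over a panel."""

    strains: list[str]
    shared: np.ndarray   # int, |A ∩ B|; diagonal = set sizes
    percent: np.ndarray  # float, 100·|A∩B|/|A∪B|; diagonal = 100

    def subset(self, strain_ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.strains.index(s) for s in strain_ids]
        return SimilarityMatrix(
            strains=list(strain_ids),
            shared=self.shared[np.ix_(idx, idx)],
            percent=self.percent[np.ix_(idx, idx)],
        )


def _check_panel(sets: Sequence[StrainPeptideSet]) -> None:
    ids = [s.strain_id for s in sets]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate strain ids: {', '.join(dups)}")
    if len(sets) < 2:
        raise ValueError("a panel needs at least two strains")


def shared_counts(sets: Sequence[StrainPeptideSet]) -> np.ndarray:
    """Symmetric matrix of pairwise intersection sizes; diagonal = set sizes."""
    _check_panel(sets)
    n = len(sets)
    m = np.zeros((n, n), dtype=int)
    for i in range(n):
        m[i, i] = len(sets[i])
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = len(sets[i].peptides & sets[j].peptides)
    return m


def percent_shared(sets: Sequence[StrainPeptideSet]) -> SimilarityMatrix:
    """Percent of shared peptides over the union, for every strain pair.

    An empty strain set gets 0 off-diagonal and 100 on the diagonal, with a
    warning (the ratio is undefined; the convention keeps the matrix total).
    """
    _check_panel(sets)
    n = len(sets)
    shared = shared_counts(sets)
    percent = np.full((n, n), 100.0)
    for i, s in enumerate(sets):
        if not s.peptides:
            warnings.warn(f"strain {s.strain_id!r} has an empty peptide set", stacklevel=2)
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i].peptides | sets[j].peptides)
            val = 100.0 * shared[i, j] / union if union else 0.0
            percent[i, j] = percent[j, i] = val
    return SimilarityMatrix(
        strains=[s.strain_id for s in sets], shared=shared, percent=percent
    )


def presence(
    queries: Iterable[SignalPeptideRecord],
    panel: Sequence[StrainPeptideSet],
    *,
    min_identity: float | None = None,
) -> pd.DataFrame:
    """Presence of each query peptide across the panel.

    Returns a DataFrame indexed by query id with one boolean column per
    strain plus ``percent_present`` (share of panel strains containing the
    query, one decimal). By default a peptide is "present" iff an identical
    sequence is in the strain's set; ``min_identity`` (0-1] switches to a
    global-alignment identity threshold.
    """
    if not panel:
        raise ValueError("empty strain panel")
    rows = {}
    for q in queries:
        hits = [_present_in(q.sp_seq, s, min_identity) for s in panel]
        row = {s.strain_id: h for s, h in zip(panel, hits)}
        row["percent_present"] = round_half_up(
            100.0 * sum(hits) / len(panel), 1
        )
        rows[q.id] = row
    cols = [s.strain_id for s in panel] + ["percent_present"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _present_in(seq: str, sset: StrainPeptideSet, min_identity: float | None) -> bool:
    if min_identity is None:
        return seq in sset
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=0,
        open_gap_score=0, extend_gap_score=0,
    )
    for member in sset.peptides:
        score = aligner.score(seq, member)
        if score / max(len(seq), len(member)) >= min_identity:
            return True
    return False


def mean_offdiag(
    similarity: SimilarityMatrix, subset: Sequence[str] | None = None
) -> tuple[float, float]:
    """Mean and sample SD of the upper-triangle off-diagonal percents.

    ``subset`` restricts to the named strains (at least two). With a single
    pair the SD is 0 by convention.
    """
    sim = similarity if subset is None else similarity.subset(subset)
    n = len(sim.strains)
    if n < 2:
        raise ValueError("need at least two strains for off-diagonal statistics")
    vals = sim.percent[np.triu_indices(n, k=1)]
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


def cluster_order(similarity: SimilarityMatrix) -> tuple[list[str], list[tuple]]:
    """Agglomerative average-linkage clustering on distance 100 − percent.

    Ties are broken deterministically: among equally distant cluster pairs
    the one whose (lexicographically sorted) member labels come first is
    merged, and within a merge the lexicographically smaller cluster goes
    left. Returns ``(leaf_order, merges)`` where each merge is
    ``(left_members, right_members, distance)``.

    Implemented directly (rather than through a linkage library) because the
    export contract requires a reproducible order under exact ties.
    """
    n = len(similarity.strains)
    if n < 2:
        raise ValueError("need at least two strains to cluster")
    dist = {
        frozenset((a, b)): 100.0 - similarity.percent[i, j]
        for (i, a), (j, b) in combinations(enumerate(similarity.strains), 2)
    }
    # cluster -> ordered member list; key for tie-breaking is the sorted tuple
    clusters: dict[tuple, list[str]] = {(s,): [s] for s in sorted(similarity.strains)}

    def avg_dist(c1: tuple, c2: tuple) -> float:
        return sum(dist[frozenset((a, b))] for a in c1 for b in c2) / (len(c1) * len(c2))

    merges: list[tuple] = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((avg_dist(k1, k2), k1, k2) for k1, k2 in combinations(keys, 2)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        d, k1, k2 = best
        left, right = clusters.pop(k1), clusters.pop(k2)
        merges.append((list(left), list(right), d))
        clusters[tuple(sorted(k1 + k2))] = left + right
    (leaves,) = clusters.values()
    return leaves, merges


def write_matrix_tsv(similarity: SimilarityMatrix, path: str | Path, *, kind: str = "percent") -> None:
    """Serialize a square matrix as TSV, strain ids as first row and column.

    ``kind='percent'`` writes one-decimal percents, ``'shared'`` the integer
    shared counts.
    """
    if kind == "percent":
        data = np.vectorize(lambda v: round_half_up(v, 1))(similarity.percent)
    elif kind == "shared":
        data = similarity.shared
    else:
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = pd.DataFrame(data, index=similarity.strains, columns=similarity.strains)
    df.to_csv(path, sep="\t", index_label="strain", lineterminator="\n")


def read_matrix_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy()
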