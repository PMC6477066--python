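"""Cosegregation interval mapping from marker genotypes of mutant plants.

Under a recessive model every mutant-phenotype F2 plant is homozygous for
the mutant-parent allele at the causal locus, so markers tightly linked to
it are homozygous mutant-parent (``AA``) in every mutant individual. The
candidate interval is the maximal run of consecutive such cosegregating
markers; its flanks are the first NON-cosegregating markers on either side
(the outer bound — the printed flanking positions of a mapped region are
the markers that exclude the gene, so the gene is guaranteed to lie inside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import GeneModel

__all__ = [
    "CandidateInterval",
    "IntervalMappingResult",
    "select_informative_markers",
    "map_cosegregating_interval",
    "narrow_interval",
    "interval_length_mbp",
    "genes_in_interval",
]

_HOMOZYGOUS = {"AA", "BB"}


class CoordinateError(ValueError):
    """A marker position is incompatible with the interval it should refine."""


class AmbiguousNarrowingError(ValueError):
    """Recombinants do not agree on which flank an extra marker replaces."""


@dataclass(frozen=True)
class CandidateInterval:
    """A candidate region bounded by its first non-cosegregating markers."""

    chrom: str
    left: int
    right: int
    left_marker: Optional[str] = None   # None when bounded by the chromosome end
    right_marker: Optional[str] = None
    n_genes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.left >= self.right:
            raise ValueError(f"degenerate interval ({self.left}, {self.right})")

    @property
    def length_bp(self) -> int:
        return self.right - self.left

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.left <= pos <= self.right


@dataclass
class IntervalMappingResult:
    """Outcome of cosegregation mapping, with per-marker diagnostics.

    ``interval`` is None when no marker cosegregates; ``diagnostics`` then
    still describes the best run found. ``noncoseg`` counts, per marker, the
    mutant individuals whose call broke cosegregation (heterozygous calls
    included — a possible phenotyping error surfaced rather than dropped).
    """

    interval: Optional[CandidateInterval]
    n_mutants_used: int
    run_markers: List[str]
    noncoseg: pd.Series

    @property
    def found(self) -> bool:
        return self.interval is not None


def select_informative_markers(
    parent_mutant: pd.Series,
    parent_wt: pd.Series,
    panel: pd.DataFrame,
) -> pd.DataFrame:
    """Retain markers with distinct homozygous calls in the two parents.

    Markers where either parent is missing or heterozygous are discarded.
    An empty result is returned with a warning rather than an error.
    """
    a = parent_mutant.reindex(panel.index)
    b = parent_wt.reindex(panel.index)
    keep = a.isin(_HOMOZYGOUS) & b.isin(_HOMOZYGOUS) & (a != b)
    if not keep.any():
        warnings.warn("no informative markers between the two parents", stacklevel=2)
    return panel.loc[keep]


def _coseg_mask(table) -> Tuple[pd.Series, pd.Series, pd.Series, int]:
    """Per-marker cosegregation flag over mutant-phenotype individuals."""
    mutants = table.phenotype.index[table.phenotype == "mutant"]
    calls = table.calls.loc[mutants]
    is_aa = calls == "AA"
    known = calls.notna()
    breaking = known & ~is_aa
    coseg = (~breaking).all(axis=0)
    noncoseg = breaking.sum(axis=0)
    breakers = pd.Series(
        {mid: frozenset(breaking.index[breaking[mid]]) for mid in breaking.columns},
        dtype=object,
    )
    return coseg, noncoseg, breakers, len(mutants)


def _runs_with_bridging(
    flags: np.ndarray, breaker_sets: Sequence[frozenset]
) -> List[Tuple[int, int]]:
    """Maximal cosegregating runs, bridging single-individual gaps.

    A gap whose broken markers are all attributable to one and the same
    individual is consistent with a double crossover (or a single genotyping
    error) in that plant; evidence from a single recombinant is not allowed
    to split the candidate region, so such runs are merged.
    """
    runs: List[Tuple[int, int]] = []
    i = 0
    while i < len(flags):
        if not flags[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(flags) and flags[j + 1]:
            j += 1
        runs.append((i, j))
        i = j + 1
    merged = True
    while merged and len(runs) > 1:
        merged = False
        for k in range(len(runs) - 1):
            gap = range(runs[k][1] + 1, runs[k + 1][0])
            union: set = set()
            for g in gap:
                union |= breaker_sets[g]
            if len(union) <= 1:
                runs[k : k + 2] = [(runs[k][0], runs[k + 1][1])]
                merged = True
                break
    return runs


def map_cosegregating_interval(table) -> IntervalMappingResult:
    """Locate the candidate interval from a :class:`GenotypeTable`.

    Only mutant-phenotype rows are used; missing calls are uninformative.
    Gaps broken by a single recombinant individual (a double crossover or an
    isolated genotyping error) do not split the region — see
    :func:`_runs_with_bridging`. Ties between runs with equally many
    cosegregating markers are broken by physical span, then by lowest
    chromosome name and position. Flanks fall back to position 1 and
    the chromosome length (or the outermost marker when lengths are absent).
    """
    if (table.phenotype == "mutant").sum() < 1:
        raise ValueError("at least one mutant-phenotype individual is required")
    coseg, noncoseg, breakers, n_mut = _coseg_mask(table)
    panel = table.panel.loc[table.calls.columns]
    best = None  # key = (n_coseg_markers, span, chrom order, -left_pos)
    for chrom in panel["chrom"].unique():
        ids = panel.index[panel["chrom"] == chrom]
        flags = coseg.loc[ids].to_numpy()
        pos = panel.loc[ids, "pos"].to_numpy()
        breaker_sets = breakers.loc[ids].tolist()
        for i, j in _runs_with_bridging(flags, breaker_sets):
            n_markers = int(flags[i : j + 1].sum())
            span = int(pos[j] - pos[i])
            key = (n_markers, span, _NegStr(chrom), -int(pos[i]))
            if best is None or key > best[0]:
                best = (key, chrom, ids, pos, i, j)
    if best is None:
        return IntervalMappingResult(
            interval=None, n_mutants_used=n_mut, run_markers=[], noncoseg=noncoseg
        )
    _, chrom, ids, pos, i, j = best
    lengths = table.chrom_lengths or {}
    if i > 0:
        left, left_marker = int(pos[i - 1]), ids[i - 1]
    else:
        left, left_marker = 1, None
    if j < len(pos) - 1:
        right, right_marker = int(pos[j + 1]), ids[j + 1]
    else:
        right, right_marker = int(lengths.get(chrom, pos[j])), None
        right = max(right, int(pos[j]) + 1)
    interval = CandidateInterval(
        chrom=chrom, left=left, right=right, left_marker=left_marker, right_marker=right_marker
    )
    return IntervalMappingResult(
        interval=interval,
        n_mutants_used=n_mut,
        run_markers=list(ids[i : j + 1]),
        noncoseg=noncoseg,
    )


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers the lowest name."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def narrow_interval(
    table,
    interval: CandidateInterval,
    marker_id: str,
    pos: int,
    calls: Mapping[str, str],
) -> CandidateInterval:
    """Refine an interval with one additional internal marker.

    The extra marker must lie strictly inside the interval. If it
    cosegregates (every mutant call is ``AA``) the interval is unchanged.
    Otherwise each recombinant mutant individual votes for a side: a
    recombinant carrying a non-``AA`` call at the current right flank places
    the crossover — and hence the marker — on the right of the causal locus,
    and symmetrically for the left; the failing marker then replaces that
    flank. Conflicting votes raise :class:`AmbiguousNarrowingError`.
    """
    if not interval.left < pos < interval.right:
        raise CoordinateError(
            f"marker {marker_id} at {pos} lies outside ({interval.left}, {interval.right})"
        )
    mutants = table.phenotype.index[table.phenotype == "mutant"]
    failing = [
        ind
        for ind in mutants
        if ind in calls and pd.notna(calls[ind]) and calls[ind] != "AA"
    ]
    if not failing:
        return interval

    def flank_breaks(ind: str, marker: Optional[str]) -> Optional[bool]:
        # a flank set by an earlier narrowing is not a table column; its
        # evidence is unavailable, like a chromosome-end flank
        if marker is None or marker not in table.calls.columns:
            return None
        call = table.calls.at[ind, marker]
        return pd.notna(call) and call != "AA"

    votes = {"left": 0, "right": 0}
    for ind in failing:
        broke_left = flank_breaks(ind, interval.left_marker)
        broke_right = flank_breaks(ind, interval.right_marker)
        if broke_right and not broke_left:
            votes["right"] += 1
        elif broke_left and not broke_right:
            votes["left"] += 1
        elif broke_right is None and broke_left is False:
            votes["right"] += 1
        elif broke_left is None and broke_right is False:
            votes["left"] += 1
    if votes["left"] == votes["right"]:
        raise AmbiguousNarrowingError(
            f"marker {marker_id}: recombinants split {votes['left']} left / "
            f"{votes['right']} right"
        )
    if votes["right"] > votes["left"]:
        return replace(interval, right=pos, right_marker=marker_id, n_genes=None)
    return replace(interval, left=pos, left_marker=marker_id, n_genes=None)


def interval_length_mbp(interval: CandidateInterval) -> float:
    """Interval length in Mbp, rounded to one decimal."""
    return round(interval.length_bp / 1e6, 1)


def genes_in_interval(
    interval: CandidateInterval,
    genes: Sequence[GeneModel],
) -> List[GeneModel]:
    """Genes whose span overlaps the closed interval (any overlap counts)."""
    return [
        g
        for g in genes
        if g.chrom == interval.chrom and g.overlaps(interval.left, interval.right)
    ]
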