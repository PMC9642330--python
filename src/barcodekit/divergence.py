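"""Per-species divergence summaries, nearest neighbours and the barcode gap.

For each species the intraspecific mean/min/max distance is computed over
all unordered conspecific pairs with defined distances; single-specimen
species are marked not-calculated.  The nearest neighbour (NN) of a species
is the heterospecific species attaining the minimum pairwise distance to
any of its members.  A species shows a barcode gap when its NN distance
strictly exceeds its maximum intraspecific distance; a species whose NN
distance equals its maximum sits on the 1:1 line of the gap scatter plot
and counts as gap-absent.  Singleton species take max_intra = 0 for the gap
verdict (they still anchor NN distances of other species) and are excluded
from dataset-level intraspecific averages.

Species whose mean intraspecific divergence exceeds 2% are flagged as
candidate species complexes, the conventional ceiling for insect
intraspecific COI variation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesSummary",
    "NNRecord",
    "GapRecord",
    "intraspecific_summary",
    "nearest_neighbor",
    "barcode_gap",
    "flag_high_divergence",
    "dataset_divergence_means",
    "gap_scatter_frame",
]


@dataclass(frozen=True)
class SpeciesSummary:
    """Intraspecific distance summary; fields are NaN when n = 1."""

    species: str
    n: int
    mean_intra: float
    min_intra: float
    max_intra: float

    @property
    def calculated(self) -> bool:
        return not math.isnan(self.mean_intra)


@dataclass(frozen=True)
class NNRecord:
    species: str
    nn_species: str
    nn_distance: float
    tied_species: tuple[str, ...] = ()


@dataclass(frozen=True)
class GapRecord:
    species: str
    max_intra: float
    mean_intra: float
    nn_distance: float
    gap_present: bool


def _groups(matrix: DistanceMatrix, labels: Mapping[str, str]) -> dict[str, list[int]]:
    missing = [i for i in matrix.ids if i not in labels]
    if missing:
        raise ValueError(f"labels missing for ids: {missing}")
    groups: dict[str, list[int]] = {}
    for idx, rid in enumerate(matrix.ids):
        groups.setdefault(labels[rid], []).append(idx)
    return groups


def intraspecific_summary(
    matrix: DistanceMatrix, labels: Mapping[str, str]
) -> list[SpeciesSummary]:
    """Mean/min/max conspecific distance per species, NaN for singletons."""
    out = []
    for sp, idx in _groups(matrix, labels).items():
        n = len(idx)
        if n < 2:
            out.append(SpeciesSummary(sp, n, math.nan, math.nan, math.nan))
            continue
        sub = matrix.data[np.ix_(idx, idx)]
        iu = np.triu_indices(n, k=1)
        vals = sub[iu]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            logger.warning("species %s: all conspecific distances undefined", sp)
            out.append(SpeciesSummary(sp, n, math.nan, math.nan, math.nan))
            continue
        out.append(
            SpeciesSummary(sp, n, float(vals.mean()), float(vals.min()),
                           float(vals.max()))
        )
    return out


def nearest_neighbor(
    matrix: DistanceMatrix, labels: Mapping[str, str]
) -> list[NNRecord]:
    """Minimum heterospecific distance and its species, for every species.

    Ties at the minimum (within float equality) are broken by lexicographic
    species label and reported in full in ``tied_species``.
    """
    groups = _groups(matrix, labels)
    if len(groups) < 2:
        raise ValueError("nearest-neighbour analysis requires at least 2 species")
    out = []
    for sp, idx in groups.items():
        best = math.inf
        per_other: dict[str, float] = {}
        for other, jdx in groups.items():
            if other == sp:
                continue
            block = matrix.data[np.ix_(idx, jdx)]
            if np.all(np.isnan(block)):
                continue
            per_other[other] = float(np.nanmin(block))
            best = min(best, per_other[other])
        if not per_other:
            raise ValueError(f"species {sp}: no defined heterospecific distances")
        ties = tuple(sorted(o for o, d in per_other.items() if d == best))
        out.append(NNRecord(sp, ties[0], best, ties))
    return out


def barcode_gap(
    summaries: Sequence[SpeciesSummary], nn_records: Sequence[NNRecord]
) -> list[GapRecord]:
    """Gap verdict per species: NN distance strictly above max intraspecific.

    Singleton species (not-calculated intraspecific values) are assessed
    with max_intra = 0.
    """
    nn_by_sp = {r.species: r for r in nn_records}
    missing = [s.species for s in summaries if s.species not in nn_by_sp]
    if missing:
        raise ValueError(f"no NN record for species: {missing}")
    out = []
    for s in summaries:
        nn = nn_by_sp[s.species]
        max_intra = 0.0 if math.isnan(s.max_intra) else s.max_intra
        mean_intra = 0.0 if math.isnan(s.mean_intra) else s.mean_intra
        out.append(
            GapRecord(s.species, max_intra, mean_intra, nn.nn_distance,
                      gap_present=nn.nn_distance > max_intra)
        )
    return out


def flag_high_divergence(
    summaries: Sequence[SpeciesSummary], cutoff: float = 0.02
) -> list[str]:
    """Species with mean intraspecific divergence above the cutoff.

    The 2% default marks candidate species complexes (cryptic species).
    """
    return [
        s.species for s in summaries if s.calculated and s.mean_intra > cutoff
    ]


def dataset_divergence_means(summaries: Sequence[SpeciesSummary]) -> dict[str, float]:
    """Dataset-level averages, reported two ways.

    ``mean_of_means`` averages the per-species mean intraspecific distances;
    ``mean_of_maxima`` averages the per-species maxima.  Both are standard
    headline numbers and they differ, so both are emitted.  Singletons are
    excluded.
    """
    means = [s.mean_intra for s in summaries if s.calculated]
    maxima = [s.max_intra for s in summaries if s.calculated]
    if not means:
        raise ValueError("no species with calculated intraspecific distances")
    return {
        "mean_of_means": float(np.mean(means)),
        "mean_of_maxima": float(np.mean(maxima)),
        "min_of_means": float(np.min(means)),
        "max_of_means": float(np.max(means)),
    }


def gap_scatter_frame(gaps: Sequence[GapRecord]) -> pd.DataFrame:
    """Scatter coordinates for the two gap plots.

    One row per species with x-coordinates for both panels (maximum and
    mean intraspecific distance) against the shared y (NN distance); dots
    strictly above the 1:1 line have a gap.
    """
    return pd.DataFrame(
        {
            "species": [g.species for g in gaps],
            "max_intra": [g.max_intra for g in gaps],
            "mean_intra": [g.mean_intra for g in gaps],
            "nn_distance": [g.nn_distance for g in gaps],
            "gap_present": [g.gap_present for g in gaps],
        }
    )
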