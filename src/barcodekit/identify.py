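"""Leave-one-out species identification against a barcode library.

Each sequence in turn queries all the others (no query/reference split) and
is graded under three criteria:

* **Best Match** — the tie set of candidates at the minimum distance (within
  ``tie_epsilon``) is inspected: all conspecific → *correct*, mixed →
  *ambiguous*, all heterospecific → *incorrect*.
* **Best Close Match** — as Best Match, but a query whose closest candidate
  lies beyond the threshold ``t`` is *no_match* instead.
* **All Species Barcodes** — *no_match* beyond ``t``; otherwise *correct*
  only when every conspecific candidate lies within ``t`` and strictly
  closer (beyond ``tie_epsilon``) than every heterospecific candidate;
  *incorrect* when the closest candidate is heterospecific; *ambiguous*
  otherwise (a heterospecific interleaves, or a conspecific exceeds ``t``).

The threshold is either fixed (default 1%, the standard barcode cutoff) or
derived as a nearest-rank percentile (default 95th) of all pooled
intraspecific distances.  Queries from singleton species have no
conspecific candidate and come out *incorrect* under Best Match and
*no_match*/*incorrect* under the gated criteria.  Threshold comparisons use
``distance <= t`` for "within".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .distances import DistanceMatrix, PairwiseDistanceModel
from .seqio import BarcodeDataset

__all__ = [
    "CRITERIA",
    "VERDICTS",
    "IdentificationConfig",
    "IdentificationReport",
    "percentile_threshold",
    "best_match",
    "best_close_match",
    "all_species_barcodes",
    "evaluate_dataset",
    "BestMatchClassifier",
]

CRITERIA = ("best_match", "best_close_match", "all_species_barcodes")
VERDICTS = ("correct", "ambiguous", "incorrect", "no_match")

NO_MATCH_LABEL = ""


@dataclass(frozen=True)
class IdentificationConfig:
    """Threshold and tie-handling settings for the gated criteria.

    ``tie_epsilon`` defaults to exact float ties only; widen it to emulate
    software that rounds distances before comparison.
    """

    threshold: float = 0.01
    threshold_mode: str = "fixed"  # or "intraspecific_percentile"
    percentile: float = 95.0
    model: str = "k2p"
    tie_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")
        if self.tie_epsilon < 0:
            raise ValueError("tie_epsilon must be >= 0")
        if self.threshold_mode not in {"fixed", "intraspecific_percentile"}:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")


@dataclass
class IdentificationReport:
    per_query: pd.DataFrame
    summary: pd.DataFrame  # criterion x verdict, percentages to one decimal
    threshold: float
    model: str

    def percent(self, criterion: str, verdict: str) -> float:
        return float(self.summary.loc[criterion, verdict])


def percentile_threshold(
    matrix: DistanceMatrix, labels: Mapping[str, str], percentile: float = 95.0
) -> float:
    """Nearest-rank percentile of all pooled intraspecific distances.

    With N sorted intraspecific distances the threshold is the value at
    ascending index ceil(percentile/100 · N).
    """
    groups: dict[str, list[int]] = {}
    for idx, rid in enumerate(matrix.ids):
        groups.setdefault(labels[rid], []).append(idx)
    pool: list[float] = []
    for idx in groups.values():
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = matrix.data[idx[a], idx[b]]
                if not math.isnan(d):
                    pool.append(d)
    if not pool:
        raise ValueError("no conspecific pairs: percentile threshold undefined")
    pool.sort()
    rank = math.ceil(percentile / 100.0 * len(pool))
    return pool[max(rank, 1) - 1]


def _candidates(matrix: DistanceMatrix, qidx: int):
    """Leave-one-out candidate indices and distances (defined only)."""
    d = matrix.data[qidx].copy()
    d[qidx] = np.nan
    ok = ~np.isnan(d)
    return np.nonzero(ok)[0], d[ok]


def _tie_set(cand_idx, cand_d, tie_epsilon):
    best = cand_d.min()
    return best, cand_idx[cand_d <= best + tie_epsilon]


def best_match(
    query: str,
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    config: IdentificationConfig = IdentificationConfig(),
) -> str:
    """Best Match verdict for one query (leave-one-out)."""
    qidx = matrix.ids.index(query)
    cand_idx, cand_d = _candidates(matrix, qidx)
    if cand_idx.size == 0:
        return "no_match"
    _, ties = _tie_set(cand_idx, cand_d, config.tie_epsilon)
    truth = labels[query]
    conspecific = [labels[matrix.ids[i]] == truth for i in ties]
    if all(conspecific):
        return "correct"
    if any(conspecific):
        return "ambiguous"
    return "incorrect"


def best_close_match(
    query: str,
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    config: IdentificationConfig = IdentificationConfig(),
) -> str:
    """Best Close Match: Best Match gated by the distance threshold."""
    qidx = matrix.ids.index(query)
    cand_idx, cand_d = _candidates(matrix, qidx)
    if cand_idx.size == 0 or cand_d.min() > config.threshold:
        return "no_match"
    return best_match(query, matrix, labels, config)


def all_species_barcodes(
    query: str,
    matrix: DistanceMatrix,
    labels: Mapping[str, str],
    config: IdentificationConfig = IdentificationConfig(),
) -> str:
    """All Species Barcodes: every conspecific must top the candidate list."""
    qidx = matrix.ids.index(query)
    cand_idx, cand_d = _candidates(matrix, qidx)
    if cand_idx.size == 0 or cand_d.min() > config.threshold:
        return "no_match"
    truth = labels[query]
    is_con = np.array([labels[matrix.ids[i]] == truth for i in cand_idx])
    best = cand_d.min()
    closest_conspecific = bool(
        np.any(is_con & (cand_d <= best + config.tie_epsilon))
    )
    if not closest_conspecific:
        return "incorrect"
    con_d = cand_d[is_con]
    het_d = cand_d[~is_con]
    all_within = bool(np.all(con_d <= config.threshold))
    separated = het_d.size == 0 or bool(
        con_d.max() < het_d.min() - config.tie_epsilon
    )
    if all_within and separated:
        return "correct"
    return "ambiguous"


_CRITERION_FN = {
    "best_match": best_match,
    "best_close_match": best_close_match,
    "all_species_barcodes": all_species_barcodes,
}


def evaluate_dataset(
    dataset: BarcodeDataset,
    config: IdentificationConfig = IdentificationConfig(),
    matrix: DistanceMatrix | None = None,
) -> IdentificationReport:
    """Run all three criteria over every record as query.

    Percentages per criterion are 100·count/N rounded to one decimal; the
    raw counts are recoverable from the per-query table.
    """
    from .distances import distance_matrix

    labels = dataset.species_of()
    if len(set(labels.values())) < 2:
        raise ValueError("identification requires at least 2 species")
    if matrix is None:
        matrix = distance_matrix(dataset, config.model)
    if config.threshold_mode == "intraspecific_percentile":
        t = percentile_threshold(matrix, labels, config.percentile)
        config = IdentificationConfig(
            threshold=t, threshold_mode="fixed", percentile=config.percentile,
            model=config.model, tie_epsilon=config.tie_epsilon,
        )
    rows = []
    index = {rid: i for i, rid in enumerate(matrix.ids)}
    for rid in matrix.ids:
        qidx = index[rid]
        cand_idx, cand_d = _candidates(matrix, qidx)
        if cand_idx.size:
            best_d, ties = _tie_set(cand_idx, cand_d, config.tie_epsilon)
            best_ids = [matrix.ids[i] for i in ties]
        else:
            best_d, best_ids = math.nan, []
        row = dict(
            id=rid, species=labels[rid],
            best_distance=best_d, best_matches=",".join(best_ids),
        )
        for crit in CRITERIA:
            row[crit] = _CRITERION_FN[crit](rid, matrix, labels, config)
        rows.append(row)
    per_query = pd.DataFrame(rows)
    n = len(per_query)
    summary = pd.DataFrame(
        {
            v: [round(100.0 * (per_query[c] == v).sum() / n, 1) for c in CRITERIA]
            for v in VERDICTS
        },
        index=list(CRITERIA),
    )
    return IdentificationReport(
        per_query=per_query, summary=summary,
        threshold=config.threshold, model=config.model,
    )


class BestMatchClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style nearest-barcode species classifier.

    ``fit(X, y)`` stores a reference library of aligned sequences with
    species labels; ``predict(X)`` assigns each query the species of its
    closest reference sequence under the configured distance model,
    returning the empty string for queries whose best hit exceeds the
    threshold (when ``criterion`` is a gated one) or whose tie set mixes
    species.

    Parameters
    ----------
    criterion : {"best_match", "best_close_match"}, default "best_close_match"
        Whether to gate assignments by the distance threshold.
    threshold : float, default 0.01
    model : distance model name, default "k2p"
    tie_epsilon : float, default 1e-12
    """

    def __init__(self, criterion: str = "best_close_match",
                 threshold: float = 0.01, model: str = "k2p",
                 tie_epsilon: float = 1e-12):
        self.criterion = criterion
        self.threshold = threshold
        self.model = model
        self.tie_epsilon = tie_epsilon

    def fit(self, X, y=None):
        if self.criterion not in {"best_match", "best_close_match"}:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if isinstance(X, BarcodeDataset) and y is None:
            y = [r.species for r in X]
        if y is None:
            raise ValueError("y (species labels) is required")
        self._dist = PairwiseDistanceModel(model=self.model).fit(X)
        self.classes_ = np.unique(np.asarray(y, dtype=object))
        self.reference_labels_ = np.asarray(y, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        d = self._dist.transform(X)
        out = np.empty(d.shape[0], dtype=object)
        for i, row in enumerate(d):
            ok = ~np.isnan(row)
            if not ok.any():
                out[i] = NO_MATCH_LABEL
                continue
            best = np.nanmin(row)
            if self.criterion == "best_close_match" and best > self.threshold:
                out[i] = NO_MATCH_LABEL
                continue
            ties = self.reference_labels_[ok & (row <= best + self.tie_epsilon)]
            out[i] = ties[0] if len(set(ties)) == 1 else NO_MATCH_LABEL
        return out
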