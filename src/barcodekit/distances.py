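"""Pairwise site-pattern counts and substitution-model distances.

Distances are computed under pairwise deletion: a site enters a pair's
comparison iff both characters are unambiguous A/C/G/T.  Four models are
supported, all returning substitutions per site on the proportion scale:

* ``p`` — uncorrected proportion of differing comparable sites;
* ``jc69`` — Jukes–Cantor, ``-(3/4)·ln(1 - (4/3)p)``;
* ``k2p`` — Kimura 2-parameter, ``-(1/2)·ln((1-2P-Q)·sqrt(1-2Q))`` with
  ``P = transitions/m`` and ``Q = transversions/m``;
* ``t92`` — Tamura 3-parameter,
  ``-h·ln(1 - P/h - Q) - (1/2)(1-h)·ln(1-2Q)`` with ``h = 2θ(1-θ)`` for GC
  proportion θ (reduces exactly to K2P at θ = 1/2).

Saturated pairs (a logarithm argument ≤ 0) and pairs with no comparable
sites are flagged undefined (NaN) rather than silently zeroed, and are
excluded from every downstream summary with a logged count.  No gamma rate
correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .seqio import AlignmentError, BarcodeDataset, SeqRecord, _CODE

logger = logging.getLogger(__name__)

MODELS = ("p", "jc69", "k2p", "t92")

__all__ = [
    "MODELS",
    "PairwiseCounts",
    "DistanceMatrix",
    "count_site_patterns",
    "pairwise_distance",
    "distance_matrix",
    "PairwiseDistanceModel",
]


class PairwiseCounts(NamedTuple):
    """Comparable sites ``m``, transition and transversion differences."""

    m: int
    ts: int
    tv: int


def _encode(seq: str) -> np.ndarray:
    buf = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[buf]


def count_site_patterns(a: SeqRecord | str, b: SeqRecord | str) -> PairwiseCounts:
    """Count comparable sites, transitions (A↔G, C↔T) and transversions.

    Gap and ambiguity sites are pairwise-deleted.  Raises
    :class:`AlignmentError` on unequal lengths.
    """
    sa = a.seq if isinstance(a, SeqRecord) else a.upper()
    sb = b.seq if isinstance(b, SeqRecord) else b.upper()
    if len(sa) != len(sb):
        raise AlignmentError(
            f"sequences have unequal lengths ({len(sa)} vs {len(sb)})"
        )
    ca, cb = _encode(sa), _encode(sb)
    valid = (ca < 4) & (cb < 4)
    diff = valid & (ca != cb)
    # transitions connect bases of equal code parity (A=0/G=2, C=1/T=3)
    ts = diff & ((ca & 1) == (cb & 1))
    return PairwiseCounts(int(valid.sum()), int(ts.sum()), int(diff.sum() - ts.sum()))


def pairwise_distance(
    counts: PairwiseCounts, model: str = "k2p", gc: float | None = None
) -> float:
    """Evaluate a substitution-model distance from site-pattern counts.

    Returns NaN for undefined entries: zero comparable sites, or a
    saturated pair whose logarithm argument is ≤ 0.

    Parameters
    ----------
    counts : PairwiseCounts
    model : {"p", "jc69", "k2p", "t92"}
    gc : float, optional
        GC proportion θ for the t92 model (required there, ignored
        elsewhere); ``h = 2θ(1-θ)``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    m, ts, tv = counts
    if m == 0:
        return math.nan
    p = (ts + tv) / m
    if model == "p":
        return p
    if model == "jc69":
        arg = 1.0 - 4.0 * p / 3.0
        return -0.75 * math.log(arg) if arg > 0 else math.nan
    P, Q = ts / m, tv / m
    if model == "k2p":
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            return math.nan
        return -0.5 * math.log(a1 * math.sqrt(a2))
    # t92
    if gc is None:
        raise ValueError("t92 requires the GC proportion `gc`")
    h = 2.0 * gc * (1.0 - gc)
    if h <= 0:
        return math.nan
    a1, a2 = 1.0 - P / h - Q, 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        return math.nan
    return -h * math.log(a1) - 0.5 * (1.0 - h) * math.log(a2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined-entry flagging.

    ``data[i, j]`` is the model distance between records ``ids[i]`` and
    ``ids[j]`` on the proportion scale; undefined entries are NaN.
    """

    ids: list[str]
    data: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(self.data), np.nan_to_num(self.data.T)):
            raise ValueError("distance matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.data) < -1e-12:
                raise ValueError("negative distances")
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.data)

    @property
    def n_undefined_pairs(self) -> int:
        n = len(self.ids)
        iu = np.triu_indices(n, k=1)
        return int(np.isnan(self.data[iu]).sum())

    def get(self, a: str, b: str) -> float:
        return float(self.data[self._index[a], self._index[b]])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[i] for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)], self.model)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP format (relaxed names, tab-separated)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for rid, row in zip(self.ids, self.data):
                vals = "\t".join(f"{v:.6f}" for v in row)
                fh.write(f"{rid}\t{vals}\n")

    def condensed(self, fill_undefined: float | None = None) -> np.ndarray:
        """Upper-triangle vector (scipy order); optionally fill NaNs."""
        iu = np.triu_indices(len(self.ids), k=1)
        vec = self.data[iu].copy()
        if fill_undefined is not None:
            vec[np.isnan(vec)] = fill_undefined
        return vec


def _pattern_matrices(codes: np.ndarray):
    """m, ts, tv count matrices for all pairs of encoded sequences."""
    n = codes.shape[0]
    m = np.zeros((n, n), dtype=np.int64)
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    valid = codes < 4
    parity = codes & 1
    for i in range(n):
        v = valid[i] & valid[i + 1:]
        d = v & (codes[i] != codes[i + 1:])
        t = d & (parity[i] == parity[i + 1:])
        m[i, i + 1:] = v.sum(axis=1)
        ts[i, i + 1:] = t.sum(axis=1)
        tv[i, i + 1:] = d.sum(axis=1) - ts[i, i + 1:]
    m += m.T
    ts += ts.T
    tv += tv.T
    np.fill_diagonal(m, codes.shape[1])
    return m, ts, tv


def _distances_from_patterns(
    m: np.ndarray,
    ts: np.ndarray,
    tv: np.ndarray,
    model: str,
    gc: float | None,
    zero_diagonal: bool = True,
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        mf = m.astype(float)
        P = np.where(m > 0, ts / mf, np.nan)
        Q = np.where(m > 0, tv / mf, np.nan)
        p = P + Q
        if model == "p":
            d = p
        elif model == "jc69":
            arg = 1.0 - 4.0 * p / 3.0
            d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.nan)
        elif model == "k2p":
            a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            ok = (a1 > 0) & (a2 > 0)
            d = np.where(
                ok,
                -0.5 * np.log(np.maximum(a1, 1e-300) * np.sqrt(np.maximum(a2, 1e-300))),
                np.nan,
            )
        elif model == "t92":
            if gc is None:
                raise ValueError("t92 requires the GC proportion `gc`")
            h = 2.0 * gc * (1.0 - gc)
            a1, a2 = 1.0 - P / h - Q, 1.0 - 2.0 * Q
            ok = (a1 > 0) & (a2 > 0)
            d = np.where(
                ok,
                -h * np.log(np.maximum(a1, 1e-300))
                - 0.5 * (1.0 - h) * np.log(np.maximum(a2, 1e-300)),
                np.nan,
            )
        else:
            raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if zero_diagonal:
        np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(
    dataset: BarcodeDataset, model: str = "k2p", gc: float | None = None
) -> DistanceMatrix:
    """Full pairwise distance matrix for the dataset under one model.

    Symmetry and a zero diagonal are enforced; per-pair failures become NaN
    flags, never exceptions.  For ``t92`` the GC proportion defaults to the
    dataset's own pooled GC content.
    """
    if len(dataset) < 2:
        raise ValueError("distance matrix requires at least 2 records")
    if model == "t92" and gc is None:
        from .seqio import composition

        gc = composition(dataset).gc_content
    m, ts, tv = _pattern_matrices(dataset.codes())
    d = _distances_from_patterns(m, ts, tv, model, gc)
    dm = DistanceMatrix(dataset.ids, d, model)
    if dm.n_undefined_pairs:
        logger.warning(
            "%d undefined (saturated or incomparable) pairwise distances "
            "excluded from downstream summaries", dm.n_undefined_pairs
        )
    return dm


class PairwiseDistanceModel(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer from aligned sequences to model distances.

    ``fit`` stores reference sequences; ``transform(X)`` returns the
    (len(X), n_reference) distance matrix between new sequences and the
    reference under the configured model.  ``fit_transform(X)`` therefore
    yields the square pairwise matrix of X.

    Parameters
    ----------
    model : {"p", "jc69", "k2p", "t92"}, default "k2p"
    gc : float or None
        GC proportion for t92; estimated from the fitted sequences when None.
    """

    def __init__(self, model: str = "k2p", gc: float | None = None):
        self.model = model
        self.gc = gc

    @staticmethod
    def _as_codes(X) -> tuple[list[str], np.ndarray]:
        if isinstance(X, BarcodeDataset):
            return X.ids, X.codes()
        seqs = [x.seq if isinstance(x, SeqRecord) else str(x).upper() for x in X]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError("sequences have unequal lengths")
        codes = np.stack([_encode(s) for s in seqs])
        ids = [
            x.id if isinstance(x, SeqRecord) else f"seq{i}" for i, x in enumerate(X)
        ]
        return ids, codes

    def fit(self, X, y=None):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        self.reference_ids_, self.reference_codes_ = self._as_codes(X)
        if self.model == "t92" and self.gc is None:
            counts = np.bincount(self.reference_codes_.ravel(), minlength=5)[:4]
            self.gc_ = float((counts[1] + counts[2]) / counts[:4].sum())
        else:
            self.gc_ = self.gc
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "reference_codes_"):
            raise ValueError("PairwiseDistanceModel is not fitted")
        _, codes = self._as_codes(X)
        ref = self.reference_codes_
        if codes.shape[1] != ref.shape[1]:
            raise AlignmentError("query length differs from reference alignment")
        out = np.empty((codes.shape[0], ref.shape[0]))
        valid_r = ref < 4
        parity_r = ref & 1
        for i in range(codes.shape[0]):
            v = (codes[i] < 4) & valid_r
            d = v & (codes[i] != ref)
            t = d & ((codes[i] & 1) == parity_r)
            m = v.sum(axis=1)
            ts = t.sum(axis=1)
            tv = d.sum(axis=1) - ts
            row = _distances_from_patterns(
                m[None, :], ts[None, :], tv[None, :], self.model, self.gc_,
                zero_diagonal=False,
            )[0]
            out[i] = row
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        d = _distances_from_patterns(
            *_pattern_matrices(self.reference_codes_), self.model, self.gc_
        )
        return d
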