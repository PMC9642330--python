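"""Haplotype collapsing, site classification and haplotype diversity.

Two sequences share a haplotype iff their character strings are identical
after uppercase normalisation; gaps and ambiguity codes are compared
literally, so records differing only at an ambiguity code count as
different haplotypes (a deliberate, reproducible convention — the report
also counts how many haplotype merges an ambiguity-tolerant comparison
would produce).

Site classification uses complete deletion: a column is analysed iff every
record carries an unambiguous A/C/G/T there.  Analysed columns are either
monomorphic (one state) or variable; a variable column is
parsimony-informative when at least two states each occur in at least two
records, and a singleton otherwise.

Haplotype diversity is Nei's estimator with the n/(n-1) small-sample
correction,

    Hd = n (1 - Σ p_i²) / (n - 1),

with its sampling standard deviation

    SD = sqrt( (2/(n(n-1))) (2(n-2)(Σp_i³ - (Σp_i²)²) + Σp_i² - (Σp_i²)²) ).

Species represented by a single specimen cannot be assessed and carry a
"not calculated" marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import BarcodeDataset, InputError, SeqRecord, UNAMBIGUOUS

__all__ = [
    "HaplotypeTable",
    "SiteClassification",
    "DiversityEstimate",
    "NotCalculated",
    "collapse_haplotypes",
    "classify_sites",
    "haplotype_diversity",
    "count_ambiguity_mergeable",
    "species_polymorphism_table",
]

#: marker mirroring single-specimen table cells
NOT_CALCULATED = "N/C"


class NotCalculated(ValueError):
    """Raised when a statistic is undefined (fewer than two sequences)."""


@dataclass(frozen=True)
class HaplotypeTable:
    """Haplotype index -> member record ids, in first-seen order."""

    groups: dict[int, list[str]]

    @property
    def h(self) -> int:
        return len(self.groups)

    @property
    def n(self) -> int:
        return sum(len(m) for m in self.groups.values())

    @property
    def counts(self) -> list[int]:
        return [len(m) for m in self.groups.values()]

    @property
    def freqs(self) -> np.ndarray:
        return np.array(self.counts, dtype=float) / self.n


@dataclass(frozen=True)
class SiteClassification:
    analysed_sites: int
    monomorphic: int
    variable: int
    parsimony_informative: int
    singleton: int

    def __post_init__(self) -> None:
        assert self.monomorphic + self.variable == self.analysed_sites
        assert self.parsimony_informative + self.singleton == self.variable


@dataclass(frozen=True)
class DiversityEstimate:
    hd: float
    sd: float


def collapse_haplotypes(seqs: Iterable[SeqRecord]) -> HaplotypeTable:
    """Group records into exact-sequence-identity haplotypes."""
    groups: dict[str, list[str]] = {}
    n = 0
    for rec in seqs:
        groups.setdefault(rec.seq, []).append(rec.id)
        n += 1
    if n == 0:
        raise InputError("cannot collapse haplotypes of an empty collection")
    return HaplotypeTable({i: ids for i, ids in enumerate(groups.values())})


def _iupac_compatible(a: str, b: str) -> bool:
    table = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "GC", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
        "H": "ACT", "V": "ACG", "N": "ACGT", "-": "-",
    }
    return bool(set(table[a]) & set(table[b]))


def count_ambiguity_mergeable(dataset_or_seqs) -> int:
    """Number of haplotype pairs an ambiguity-tolerant match would merge.

    Quantifies how sensitive the exact-match haplotype count is to the
    literal treatment of IUPAC codes: two haplotypes are mergeable when at
    every site their characters are IUPAC-compatible.
    """
    seqs = list(dataset_or_seqs)
    table = collapse_haplotypes(seqs)
    by_id = {r.id: r.seq for r in seqs}
    reps = [by_id[members[0]] for members in table.groups.values()]
    merges = 0
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            if all(_iupac_compatible(a, b) for a, b in zip(reps[i], reps[j])):
                merges += 1
    return merges


def classify_sites(dataset: BarcodeDataset) -> SiteClassification:
    """Classify alignment columns under complete deletion."""
    if len(dataset) < 2:
        raise ValueError("site classification requires at least 2 records")
    codes = dataset.codes()
    analysed = np.all(codes < 4, axis=0)
    if not analysed.any():
        raise ValueError("no analysed sites: every column has a gap/ambiguity")
    cols = codes[:, analysed]
    mono = variable = informative = singleton = 0
    for col in cols.T:
        counts = np.bincount(col, minlength=4)
        states = counts[counts > 0]
        if len(states) == 1:
            mono += 1
        else:
            variable += 1
            if (states >= 2).sum() >= 2:
                informative += 1
            else:
                singleton += 1
    return SiteClassification(
        analysed_sites=int(analysed.sum()),
        monomorphic=mono,
        variable=variable,
        parsimony_informative=informative,
        singleton=singleton,
    )


def haplotype_diversity(table: HaplotypeTable) -> DiversityEstimate:
    """Nei's Hd with small-sample correction, and its standard deviation."""
    n = table.n
    if n < 2:
        raise NotCalculated("haplotype diversity needs at least 2 sequences")
    p = table.freqs
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    hd = n * (1.0 - s2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2
    )
    return DiversityEstimate(hd=hd, sd=math.sqrt(max(var, 0.0)))


def species_polymorphism_table(dataset: BarcodeDataset) -> pd.DataFrame:
    """Per-species n, haplotype count, polymorphic sites and Hd ± SD.

    Haplotypes are collapsed within each species label; polymorphic sites
    are the variable columns of the species' own sub-alignment (complete
    deletion).  Single-specimen species carry the N/C marker.
    """
    rows = []
    for sp in dataset.species:
        members = dataset.by_species(sp)
        n = len(members)
        table = collapse_haplotypes(members)
        if n >= 2:
            sub = BarcodeDataset(members)
            sites = classify_sites(sub)
            div = haplotype_diversity(table)
            rows.append(
                dict(species=sp, n=n, h=table.h,
                     polymorphic_sites=sites.variable,
                     hd=div.hd, hd_sd=div.sd)
            )
        else:
            rows.append(
                dict(species=sp, n=n, h=table.h,
                     polymorphic_sites=np.nan, hd=np.nan, hd_sd=np.nan)
            )
    return pd.DataFrame(rows)
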