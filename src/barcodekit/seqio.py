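"""Reading, validating and summarising species-labelled barcode alignments.

A barcode study starts from an aligned multi-FASTA in which every record
carries a specimen id and a species label in its header.  Two header
conventions are supported:

* ``pipe`` — fields separated by ``|`` as ``id|species|locality`` (the
  convention this package writes);
* ``whitespace`` — GenBank-style headers where the species binomial is the
  2nd and 3rd whitespace-separated token, e.g. ``OL742798 Aedes aegypti ...``.

Input is assumed pre-aligned: all sequences must have identical length, and
no aligner is bundled.  ``U`` is mapped to ``T`` and sequences are
uppercased on load; IUPAC ambiguity codes and gaps are retained in the
sequences but excluded from composition counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "BarcodeDataset",
    "CompositionStats",
    "InputError",
    "AlignmentError",
    "read_fasta",
    "write_fasta",
    "composition",
    "dataset_summary",
]

#: byte codes used throughout the package: A=0, C=1, G=2, T=3, other=4.
#: A/G are even, C/T odd, so transitions are "same parity" differences.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

UNAMBIGUOUS = frozenset("ACGT")
_AMBIGUITY = frozenset("RYSWKMBDHVN")
_ALLOWED = UNAMBIGUOUS | _AMBIGUITY | frozenset("-")


class InputError(ValueError):
    """Malformed input: unparseable header, duplicate id, empty file."""


class AlignmentError(ValueError):
    """Sequences that are not a valid alignment (unequal lengths)."""


@dataclass(frozen=True)
class SeqRecord:
    """One specimen: unique id, species label, optional locality, sequence."""

    id: str
    species: str
    seq: str
    locality: str = ""

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("U", "T")
        object.__setattr__(self, "seq", seq)
        if not seq:
            raise InputError(f"record {self.id!r} has an empty sequence")
        bad = set(seq) - _ALLOWED
        if bad:
            raise InputError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}"
            )
        if not self.id:
            raise InputError("record with empty id")
        if not self.species:
            raise InputError(f"record {self.id!r} has an empty species label")

    @property
    def n_ambiguous(self) -> int:
        return sum(1 for c in self.seq if c not in UNAMBIGUOUS)


class BarcodeDataset:
    """An ordered, validated collection of equal-length barcode records.

    The single input object of the pipeline.  Encodes sequences once into a
    byte matrix (A=0, C=1, G=2, T=3, other=4) shared by all distance and
    site-pattern computations.
    """

    def __init__(self, records: Sequence[SeqRecord]):
        records = list(records)
        if not records:
            raise InputError("dataset must contain at least one record")
        length = len(records[0].seq)
        bad = [r.id for r in records if len(r.seq) != length]
        if bad:
            raise AlignmentError(
                f"unequal sequence lengths: records {bad} differ from "
                f"{records[0].id!r} (length {length})"
            )
        seen: set[str] = set()
        for r in records:
            if r.id in seen:
                raise InputError(f"duplicate record id {r.id!r}")
            seen.add(r.id)
        self.records: list[SeqRecord] = records
        self.length: int = length

    # -- basic introspection -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SeqRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species(self) -> list[str]:
        """Unique species labels in first-seen order."""
        out: list[str] = []
        seen: set[str] = set()
        for r in self.records:
            if r.species not in seen:
                seen.add(r.species)
                out.append(r.species)
        return out

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_of(self) -> dict[str, str]:
        """Mapping id -> species label."""
        return {r.id: r.species for r in self.records}

    def codes(self) -> np.ndarray:
        """(n_records, length) int8 matrix; A=0 C=1 G=2 T=3, other=4."""
        if not hasattr(self, "_codes"):
            buf = np.frombuffer(
                "".join(r.seq for r in self.records).encode("ascii"), dtype=np.uint8
            )
            self._codes = _CODE[buf].reshape(len(self.records), self.length)
        return self._codes

    def subset(self, ids: Iterable[str]) -> "BarcodeDataset":
        wanted = set(ids)
        return BarcodeDataset([r for r in self.records if r.id in wanted])

    def by_species(self, species: str) -> list[SeqRecord]:
        return [r for r in self.records if r.species == species]


@dataclass(frozen=True)
class CompositionStats:
    """Pooled base composition over all unambiguous A/C/G/T characters."""

    freq: Mapping[str, float]
    n_bases: int

    @property
    def at_content(self) -> float:
        return self.freq["A"] + self.freq["T"]

    @property
    def gc_content(self) -> float:
        return self.freq["G"] + self.freq["C"]


_WS_HEADER = re.compile(r"^(\S+)\s+(\S+)\s+(\S+)(?:\s+(.*))?$")


def _parse_header(header: str, scheme: str, lineno: int | None = None):
    where = f" (record {lineno})" if lineno is not None else ""
    if scheme == "pipe" or (scheme == "auto" and "|" in header):
        parts = [p.strip() for p in header.split("|")]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise InputError(
                f"header {header!r}{where} not parseable as id|species|locality"
            )
        locality = parts[2] if len(parts) > 2 else ""
        return parts[0], parts[1], locality
    m = _WS_HEADER.match(header)
    if not m:
        raise InputError(
            f"header {header!r}{where} not parseable as 'id Genus species ...'"
        )
    rid, genus, epithet, rest = m.groups()
    return rid, f"{genus} {epithet}", (rest or "").strip()


def read_fasta(path: str | Path, header_scheme: str = "auto") -> BarcodeDataset:
    """Read an aligned multi-FASTA into a validated :class:`BarcodeDataset`.

    Parameters
    ----------
    path : str or Path
        FASTA file (wrapped or unwrapped lines).
    header_scheme : {"auto", "pipe", "whitespace"}
        How to extract (id, species, locality) from each header.  ``auto``
        uses ``pipe`` when the header contains ``|`` and falls back to the
        whitespace binomial convention otherwise.

    Raises
    ------
    InputError
        Empty file, duplicate ids, or an unparseable header (named with its
        record number).
    AlignmentError
        Unequal sequence lengths, naming the offending ids.
    """
    if header_scheme not in {"auto", "pipe", "whitespace"}:
        raise ValueError(f"unknown header scheme {header_scheme!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description.strip()
        rid, species, locality = _parse_header(header, header_scheme, i)
        records.append(SeqRecord(id=rid, species=species, locality=locality,
                                 seq=str(rec.seq)))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return BarcodeDataset(records)


def write_fasta(dataset: BarcodeDataset, path: str | Path, width: int = 70) -> None:
    """Write the dataset back as ``id|species|locality`` FASTA."""
    with open(path, "w") as fh:
        for r in dataset:
            header = f"{r.id}|{r.species}"
            if r.locality:
                header += f"|{r.locality}"
            fh.write(f">{header}\n")
            for start in range(0, len(r.seq), width):
                fh.write(r.seq[start:start + width] + "\n")


def composition(dataset: BarcodeDataset) -> CompositionStats:
    """Pooled A/C/G/T proportions across all records.

    Gaps and ambiguity codes are excluded from both numerator and
    denominator, matching standard composition reporting.
    """
    codes = dataset.codes()
    counts = np.bincount(codes.ravel(), minlength=5)[:4]
    total = int(counts.sum())
    if total == 0:
        raise ValueError("dataset contains no unambiguous A/C/G/T bases")
    freq = {b: counts[i] / total for i, b in enumerate("ACGT")}
    return CompositionStats(freq=freq, n_bases=total)


def dataset_summary(dataset: BarcodeDataset) -> pd.DataFrame:
    """Per-record summary table: id, species, locality, length, n_ambiguous."""
    return pd.DataFrame(
        {
            "id": [r.id for r in dataset],
            "species": [r.species for r in dataset],
            "locality": [r.locality for r in dataset],
            "length": [len(r.seq) for r in dataset],
            "n_ambiguous": [r.n_ambiguous for r in dataset],
        }
    )
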