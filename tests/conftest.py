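"""Shared fixtures: hand-built datasets and seeded synthetic communities."""

from __future__ import annotations

import numpy as np
import pytest

from barcodekit.seqio import BarcodeDataset, SeqRecord
from barcodekit.synthgen import SynthSpec, generate_community


def make_dataset(by_species: dict[str, list[str]]) -> BarcodeDataset:
    """Build a dataset from {species: [seq, ...]} with generated ids."""
    records = []
    for sp, seqs in by_species.items():
        for k, seq in enumerate(seqs):
            records.append(
                SeqRecord(id=f"{sp}-{k + 1}", species=sp, seq=seq)
            )
    return BarcodeDataset(records)


@pytest.fixture(scope="session")
def clear_community():
    """12 well-separated species, 3 specimens each, no singletons/siblings.

    Intraspecific divergence is far below the 1% threshold and
    interspecific far above, so the barcode gap is unambiguous.
    """
    spec = SynthSpec(
        S=12, n_per_species=3, delta_intra=0.002, delta_inter=0.08,
        sibling_pairs=(), n_singletons=0, seed=0,
    )
    return generate_community(spec)


@pytest.fixture(scope="session")
def sibling_community():
    """10 species incl. one sibling pair at 0.3% and two singletons."""
    spec = SynthSpec(
        S=10, n_per_species=(2, 5), delta_intra=0.002, delta_inter=0.08,
        sibling_pairs=((0, 1, 0.003),), n_singletons=2, seed=0,
    )
    return generate_community(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
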