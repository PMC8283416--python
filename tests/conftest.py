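"""Shared fixtures: toy codon tables and the published RSCU reference table."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cubkit.genetics import AA_TO_CODONS, DEGENERATE_AAS, SYNONYMOUS_CODONS, to_dna
from cubkit.rscu import RSCUVector
from cubkit.sequence_io import CodonCountTable

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def published_rscu() -> pd.DataFrame:
    """Published whole-genome RSCU values (2-decimal print precision) for a
    Hantaan virus strain panel, its clades, and host/reservoir genomes."""
    return pd.read_csv(DATA_DIR / "htnv_host_rscu.tsv", sep="\t")


@pytest.fixture(scope="session")
def published_vectors(published_rscu) -> dict[str, RSCUVector]:
    """The published table's columns as RSCUVector objects (DNA-keyed)."""
    out = {}
    for col in ("overall", "sk", "rus", "ch", "hs", "apo", "nc"):
        values = {
            to_dna(row["codon"]): float(row[col])
            for _, row in published_rscu.iterrows()
        }
        out[col] = RSCUVector(values=values)
    return out


@pytest.fixture
def uniform_counts() -> CodonCountTable:
    """Every synonymous codon of every degenerate amino acid 5 times."""
    return CodonCountTable(
        {c: 5 for aa in DEGENERATE_AAS for c in AA_TO_CODONS[aa]}
    )


@pytest.fixture
def one_codon_per_aa_counts() -> CodonCountTable:
    """Each degenerate amino acid encoded by a single codon, 10 times each."""
    return CodonCountTable({AA_TO_CODONS[aa][0]: 10 for aa in DEGENERATE_AAS})


def random_count_table(rng: np.random.Generator, max_count: int = 20) -> CodonCountTable:
    """A random codon count table over the 59 synonymous codons."""
    return CodonCountTable(
        {c: int(rng.integers(0, max_count + 1)) for c in SYNONYMOUS_CODONS}
    )
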