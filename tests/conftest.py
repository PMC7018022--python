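"""Shared fixtures: small synthetic datasets and table builders."""

import numpy as np
import pandas as pd
import pytest

import codonstab as cs
from codonstab.genetic_code import AMINO_ACIDS, SENSE_CODONS


@pytest.fixture(scope="session")
def small_config():
    return cs.SimulationConfig(n_transcripts=60, seed=11)


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    records, manifest = cs.generate_transcriptome(small_config)
    return records, manifest


@pytest.fixture(scope="session")
def tai_table(small_config):
    """A tAI table derived from synthetic tRNA-seq counts."""
    true_tai, _ = cs.random_feasible_tai(small_config)
    counts = cs.generate_trna_counts(true_tai, small_config)
    return cs.tai_from_counts(counts)


def make_csc_table(values: dict[str, float]) -> pd.DataFrame:
    """CSC-shaped table from explicit per-codon values (tiny p everywhere)."""
    csc = pd.Series(values, dtype=float).reindex(list(SENSE_CODONS))
    return pd.DataFrame(
        {
            "csc": csc,
            "p_value": np.where(csc.notna(), 1e-40, np.nan),
            "ci_low": csc - 0.01,
            "ci_high": csc + 0.01,
            "tier": "ns",
            "genome_wide": csc.notna(),
        },
        index=list(SENSE_CODONS),
    )


def make_aasc_table(
    values: dict[str, float], p_values: dict[str, float] | None = None
) -> pd.DataFrame:
    aasc = pd.Series(values, dtype=float).reindex(list(AMINO_ACIDS))
    p = pd.Series(p_values or {}, dtype=float).reindex(list(AMINO_ACIDS)).fillna(0.5)
    return pd.DataFrame(
        {
            "aasc": aasc,
            "p_value": p,
            "ci_low": aasc - 0.01,
            "ci_high": aasc + 0.01,
            "tier": "ns",
            "genome_wide": False,
        },
        index=list(AMINO_ACIDS),
    )
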