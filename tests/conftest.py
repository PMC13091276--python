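import numpy as np
import pandas as pd
import pytest

from transkingdom.tables import CountTable


@pytest.fixture
def toy_table() -> CountTable:
    """Four samples x five taxa with simple structure."""
    data = pd.DataFrame(
        [[10, 0, 5, 1, 4],
         [8, 2, 0, 0, 10],
         [0, 0, 7, 3, 10],
         [5, 5, 5, 5, 0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["tA", "tB", "tC", "tD", "tE"])
    return CountTable(data)


@pytest.fixture
def toy_taxonomy() -> pd.DataFrame:
    rows = {
        "tA": ["Bacteria", "Bacillota", "c", "o", "fX", "G1"],
        "tB": ["Bacteria", "Bacillota", "c", "o", "fX", "G1"],
        "tC": ["Bacteria", "Bacillota", "c", "o", "fY", "G2"],
        "tD": ["Bacteria", "Bacillota", "c", "o", "fY", "unassigned"],
        "tE": ["Bacteria", "Bacillota", "c", "o", "fZ", "G3"],
    }
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["kingdom", "phylum", "class", "order", "family", "genus"])


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale synthetic cohort reused across tests (session-scoped)."""
    from transkingdom.synth import SynthConfig, generate_cohort
    cfg = SynthConfig(n_bact_taxa=60, n_fungal_taxa=30, seed=11)
    return generate_cohort(cfg)
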