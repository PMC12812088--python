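import numpy as np
import pandas as pd
import pytest

from jumpsieve import ObservationTable, compute_stats


@pytest.fixture
def two_sample_table() -> ObservationTable:
    """One ASV split 90/10 over two samples plus a blank-only singleton."""
    obs = pd.DataFrame(
        {
            "asv_id": ["a1", "a1", "a2"],
            "sample_id": ["s1", "s2", "b1"],
            "reads": [90, 10, 3],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "b1"],
            "is_blank": [False, False, True],
            "group": ["g1", "g1", None],
        }
    )
    return ObservationTable(obs, samples)


def make_table(rows, blanks=(), groups=None) -> ObservationTable:
    """rows: iterable of (asv_id, sample_id, reads)."""
    obs = pd.DataFrame(rows, columns=["asv_id", "sample_id", "reads"])
    sample_ids = sorted(set(obs["sample_id"]) | set(blanks))
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "is_blank": [s in set(blanks) for s in sample_ids],
            "group": [groups.get(s) if groups else None for s in sample_ids],
        }
    )
    return ObservationTable(obs, samples)


@pytest.fixture
def blank_calibration_table() -> ObservationTable:
    """A table whose blank-only singleton reads are {2,3,5,12,400}.

    Also carries blank tag-jump-like observations of abundant ASVs so the
    second-stage thresholds are derivable, and genuine observations in
    real samples.
    """
    rows = []
    # blank-only singleton "sequencing error" ASVs
    for i, reads in enumerate([2, 3, 5, 12, 400]):
        rows.append((f"e{i}", "b1" if i % 2 else "b2", reads))
    # abundant genuine ASVs leaking small read packets into blanks
    for k, leak in enumerate([20, 25, 30, 33, 40, 45, 50, 55, 500, 900]):
        asv = f"g{k}"
        for s in range(6):
            rows.append((asv, f"s{s + 1}", 5000 + 137 * k + 11 * s))
        rows.append((asv, "b1", leak))
    return make_table(rows, blanks=("b1", "b2"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def stats_table(two_sample_table) -> ObservationTable:
    return compute_stats(two_sample_table)
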