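import numpy as np
import pandas as pd
import pytest

from calpcleave import AMINO_ACIDS, DescriptorTable, FeatureMatrix


def make_table(tid: str, seed: int, kind: str = "aaindex") -> DescriptorTable:
    """A deterministic pseudo-random 20-residue scale."""
    rng = np.random.default_rng(seed)
    return DescriptorTable(
        id=tid,
        values={a: float(v) for a, v in zip(AMINO_ACIDS, rng.normal(size=20))},
        kind=kind,
    )


def matrix_from_array(
    X, columns, labels=None, response=None, index=None
) -> FeatureMatrix:
    """Wrap a plain array as a FeatureMatrix with (position, descriptor)
    columns."""
    X = np.asarray(X, dtype=float)
    idx = index if index is not None else [f"w{i}" for i in range(len(X))]
    values = pd.DataFrame(
        X, index=idx, columns=pd.MultiIndex.from_tuples(columns)
    )
    lab = None if labels is None else pd.Series(np.asarray(labels), index=idx)
    resp = None if response is None else pd.Series(
        np.asarray(response, dtype=float), index=idx
    )
    return FeatureMatrix(values=values, labels=lab, response=resp)


@pytest.fixture
def hydrophobicity():
    """A Kyte-Doolittle-like scale used as a planted signal."""
    values = {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    }
    return DescriptorTable(id="HYDRO", values=values, kind="aaindex")


@pytest.fixture
def toy_tables(hydrophobicity):
    return {
        "HYDRO": hydrophobicity,
        "SCALE1": make_table("SCALE1", 11),
        "SCALE2": make_table("SCALE2", 12),
    }
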