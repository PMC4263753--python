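"""Shared fixtures: a small Cq table builder and the published validation
rankings for an 11-gene temperature-stress candidate panel (cold and heat
assays), used to check the consensus arithmetic against printed values."""

import numpy as np
import pandas as pd
import pytest

from refstab import CqTable

GENES_11 = [
    "18SrRNA", "26SrRNA", "GAPDH", "GSA", "HYP1", "H2A",
    "PKS1", "PKS2", "RBCL", "SDR", "TUB",
]

# Per-algorithm competition ranks (ties share the minimal position).
COLD_POSITIONS = {
    "geNorm": {"GAPDH": 1, "GSA": 1, "18SrRNA": 3, "26SrRNA": 4, "TUB": 5,
               "SDR": 6, "H2A": 7, "RBCL": 8, "HYP1": 9, "PKS2": 10, "PKS1": 11},
    "NormFinder": {"TUB": 1, "18SrRNA": 2, "26SrRNA": 3, "GAPDH": 4, "GSA": 5,
                   "SDR": 6, "RBCL": 7, "H2A": 8, "HYP1": 9, "PKS2": 10,
                   "PKS1": 11},
    "BestKeeper": {"RBCL": 1, "TUB": 2, "26SrRNA": 3, "GSA": 4, "HYP1": 5,
                   "GAPDH": 6, "18SrRNA": 7, "SDR": 8, "H2A": 9, "PKS2": 10,
                   "PKS1": 11},
}
HEAT_POSITIONS = {
    "geNorm": {"26SrRNA": 1, "H2A": 1, "GSA": 3, "SDR": 4, "HYP1": 5, "TUB": 6,
               "RBCL": 7, "18SrRNA": 8, "GAPDH": 9, "PKS1": 10, "PKS2": 11},
    "NormFinder": {"TUB": 1, "H2A": 2, "26SrRNA": 3, "RBCL": 4, "18SrRNA": 5,
                   "GSA": 6, "PKS1": 7, "GAPDH": 8, "HYP1": 9, "SDR": 10,
                   "PKS2": 11},
    "BestKeeper": {"26SrRNA": 1, "H2A": 2, "18SrRNA": 3, "TUB": 4, "RBCL": 5,
                   "PKS1": 6, "GSA": 7, "GAPDH": 8, "HYP1": 9, "SDR": 10,
                   "PKS2": 11},
}

# Published consensus geometric means (3 decimals; ≥10 printed at 2).
COLD_GEOMEAN = {
    "TUB": 2.154, "GSA": 2.714, "GAPDH": 2.884, "26SrRNA": 3.302,
    "18SrRNA": 3.476, "RBCL": 3.826, "SDR": 6.604, "HYP1": 7.399,
    "H2A": 7.958, "PKS2": 10.00, "PKS1": 11.00,
}
HEAT_GEOMEAN = {
    "26SrRNA": 1.442, "H2A": 1.587, "TUB": 2.884, "18SrRNA": 4.932,
    "GSA": 5.013, "RBCL": 5.192, "SDR": 7.368, "HYP1": 7.399,
    "PKS1": 7.489, "GAPDH": 8.320, "PKS2": 11.00,
}

COLD_TOP3 = {"TUB", "GSA", "GAPDH"}
HEAT_TOP3 = {"26SrRNA", "H2A", "TUB"}


@pytest.fixture
def published():
    return {
        "cold": (COLD_POSITIONS, COLD_GEOMEAN, COLD_TOP3),
        "heat": (HEAT_POSITIONS, HEAT_GEOMEAN, HEAT_TOP3),
    }


def make_cq_table(values: np.ndarray, genes=None, samples=None,
                  time_h=None, replicate=None) -> CqTable:
    """Build a validated CqTable from a raw array."""
    values = np.asarray(values, dtype=float)
    n_s, n_g = values.shape
    genes = genes or [f"G{j}" for j in range(n_g)]
    samples = samples or [f"s{i}" for i in range(n_s)]
    meta = pd.DataFrame(index=samples)
    if time_h is not None:
        meta["time_h"] = time_h
    if replicate is not None:
        meta["replicate"] = replicate
    return CqTable(pd.DataFrame(values, index=samples, columns=genes), meta)


@pytest.fixture
def cq_builder():
    return make_cq_table
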