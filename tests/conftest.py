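import numpy as np
import pandas as pd
import pytest

from pbnfit.core import BooleanRule, Condition, PBNModel
from pbnfit.data import NormalisedDataset
from pbnfit.synth import SyntheticSpec, generate_random_pbn


@pytest.fixture
def copy_model():
    """Two-node deterministic model: A copies itself, B copies A."""
    return PBNModel([BooleanRule("A", "A"), BooleanRule("B", "A")], p=0.0)


@pytest.fixture
def bernoulli_model():
    """B follows A with weight 0.7 and NOT A with weight 0.3; A clampable."""
    return PBNModel([
        BooleanRule("A", "0", flag="INPUT"),
        BooleanRule("B", "A", weight=0.7, flag="H"),
        BooleanRule("B", "NOT A", weight=0.3, flag="L"),
    ], p=0.0)


@pytest.fixture
def small_model_factory():
    """Random ergodic PBNs of a requested size (seeded)."""
    def make(n_nodes: int, seed: int, p: float = 0.001) -> PBNModel:
        spec = SyntheticSpec(n_nodes=n_nodes, max_parents=min(2, n_nodes - 1),
                             p=p, seed=seed)
        return generate_random_pbn(spec)
    return make


def make_dataset(rows):
    """rows: (condition, molecule, mean, sd[, split])."""
    records = []
    for row in rows:
        condition, molecule, mean, sd = row[:4]
        split = row[4] if len(row) > 4 else "train"
        records.append({"condition": condition, "molecule": molecule,
                        "mean": mean, "sd": sd, "n": 3, "split": split})
    columns = ["condition", "molecule", "mean", "sd", "n", "split"]
    return NormalisedDataset(pd.DataFrame(records, columns=columns))


@pytest.fixture
def dataset_builder():
    return make_dataset
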