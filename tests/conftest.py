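import numpy as np
import pytest

from hetvar.pedigree import UNKNOWN, Pedigree
from hetvar.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def trio_pedigree() -> Pedigree:
    """Sire x dam -> offspring, founders unrelated."""
    return Pedigree(entries=[
        ("O", "S", "D"),
        ("S", UNKNOWN, UNKNOWN),
        ("D", UNKNOWN, UNKNOWN),
    ])


@pytest.fixture(scope="session")
def small_dataset():
    """~400-record simulated dataset shared by design/sampler tests."""
    cfg = SimulationConfig(seed=11, n_records=400, n_sires=20, n_dams=150,
                           n_herds=4)
    records, ped, truth = simulate(cfg)
    return records, ped, truth


def toy_design():
    """Five records on the trio pedigree: one group, varying covariates."""
    from scipy import sparse

    from hetvar.animal_model import Design
    X = sparse.csr_matrix(np.array([
        [1.0, 0.1, -2.0], [1.0, 0.5, 1.0], [1.0, 0.9, 3.0],
        [1.0, 0.2, -1.0], [1.0, 0.7, -1.0]]))
    Z = sparse.csr_matrix(np.array([
        [0, 0, 1.0], [0, 0, 1.0], [0, 1.0, 0], [0, 1.0, 0], [1.0, 0, 0]]))
    y = np.array([2100.0, 2250.0, 2380.0, 2260.0, 2190.0])
    return Design(X=X, Z=Z, y=y, fixed_names=["cg:1", "htz", "age"],
                  animal_order=["S", "D", "O"],
                  record_animals=["O", "O", "D", "D", "S"], subset="ALL")


def random_pedigree(rng: np.random.Generator, n_founders: int,
                    n_offspring: int) -> Pedigree:
    """Random multi-generation pedigree: each offspring picks two distinct
    earlier animals as parents, so inbreeding loops arise naturally."""
    ids = [f"F{i}" for i in range(n_founders)]
    entries = [(i, UNKNOWN, UNKNOWN) for i in ids]
    for k in range(n_offspring):
        s, d = rng.choice(len(ids), size=2, replace=False)
        name = f"X{k}"
        entries.append((name, ids[s], ids[d]))
        ids.append(name)
    return Pedigree(entries=entries)
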