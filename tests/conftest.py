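import numpy as np
import pandas as pd
import pytest

import haplink as hl


def make_matrix(rows: dict, gametes=None) -> hl.HaploidGenotypeMatrix:
    """Build a small matrix from {locus: list of calls}; None = missing."""
    first = next(iter(rows.values()))
    if gametes is None:
        gametes = [f"G{i + 1}" for i in range(len(first))]
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=gametes)
    calls = calls.where(calls.notna(), np.nan)
    return hl.HaploidGenotypeMatrix(calls)


def het_mother(loci, a1="A", a2="B") -> hl.MotherGenotype:
    return hl.MotherGenotype(
        pd.DataFrame({"allele1": a1, "allele2": a2}, index=pd.Index(loci)))


@pytest.fixture(scope="session")
def clean_dataset() -> hl.SimulatedDataset:
    """11-LG, 139-gamete, noiseless dataset shared across tests."""
    cfg = hl.SimulationConfig(n_gametes=139, seed=20)
    return hl.simulate_dataset(n_lgs=11, n_markers=770, config=cfg)


@pytest.fixture(scope="session")
def clean_fit(clean_dataset) -> hl.LinkageMapResults:
    model = hl.LinkageMapper(clean_dataset.matrix, clean_dataset.mother)
    return model.fit(seed=4)
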