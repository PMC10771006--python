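import numpy as np
import pytest

from dbpp import chemprep, synthetic


@pytest.fixture(scope="session")
def fixture_table():
    """The curated ~40-molecule drug / non-drug smoke panel."""
    return synthetic.fixture_molecules()


@pytest.fixture(scope="session")
def std_mols(fixture_table):
    """All fixture molecules, standardized (every one must be accepted)."""
    mols = []
    for _, row in fixture_table.iterrows():
        out = chemprep.standardize(row["smiles"], int(row["label"]), row["name"])
        assert isinstance(out, chemprep.StandardizedMolecule), row["name"]
        mols.append(out)
    return mols


@pytest.fixture(scope="session")
def tiny_panel():
    """A fast 20-endpoint panel fitted on small synthetic endpoint tables."""
    return synthetic.train_synthetic_panel(n=240, effect=3.0, algo="lr", seed=0)


@pytest.fixture(scope="session")
def strong_profiles():
    """Profiles with strong ADMET-block class separation."""
    return synthetic.generate_profiles(
        synthetic.ProfileGeneratorConfig(
            n_per_class=300, admet_effect=np.full(20, 2.0), seed=42
        )
    )


@pytest.fixture(scope="session")
def null_profiles():
    """Profiles with no class separation anywhere."""
    return synthetic.generate_profiles(
        synthetic.ProfileGeneratorConfig(n_per_class=300, seed=43)
    )
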