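import numpy as np
import pandas as pd
import pytest

from microtide.io_core import ClinicalTable, OtuTable, build_micro_set
from microtide.synthetic import preset, simulate_micro


@pytest.fixture(scope="session")
def small_sim():
    """One simulated small cohort (30 libraries, 8 genera, group effect on taxon 3)."""
    return simulate_micro(preset("small", seed=11))


@pytest.fixture(scope="session")
def small_ms(small_sim):
    return build_micro_set({"Genus": small_sim.otu}, small_sim.clinical)


@pytest.fixture()
def toy_otu():
    """Tiny deterministic 3-taxon x 4-library table."""
    return OtuTable(
        name="Genus",
        taxa=["Bacteria/F/A", "Bacteria/F/B", "Bacteria/P/C"],
        libraries=["L1", "L2", "L3", "L4"],
        counts=np.array([[0, 0, 0, 8], [10, 20, 30, 40], [90, 80, 70, 52]]),
    )


@pytest.fixture()
def toy_clinical():
    frame = pd.DataFrame(
        {
            "Group": pd.Categorical(["No", "No", "Yes", "Yes"],
                                    categories=["No", "Yes"]),
            "Age": [60.0, 65.0, 70.0, 75.0],
        },
        index=pd.Index(["L1", "L2", "L3", "L4"], name="Lib"),
    )
    return ClinicalTable(id_column="Lib", frame=frame)


@pytest.fixture()
def toy_ms(toy_otu, toy_clinical):
    return build_micro_set({"Genus": toy_otu}, toy_clinical)


def random_micro_set(rng: np.random.Generator, n_lib=12, n_taxa=6):
    """Random small micro set for property checks."""
    counts = rng.integers(0, 200, size=(n_taxa, n_lib))
    counts[:, counts.sum(axis=0) == 0] += 1  # no empty library
    libs = [f"L{i}" for i in range(n_lib)]
    otu = OtuTable(name="T", taxa=[f"Bacteria/P{i % 3}/g{i}" for i in range(n_taxa)],
                   libraries=libs, counts=counts)
    frame = pd.DataFrame(
        {
            "Group": pd.Categorical(
                np.where(rng.random(n_lib) < 0.5, "No", "Yes"),
                categories=["No", "Yes"]),
            "Age": rng.uniform(40, 90, n_lib),
        },
        index=pd.Index(libs, name="Lib"),
    )
    return build_micro_set({"T": otu}, ClinicalTable("Lib", frame))
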