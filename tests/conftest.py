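import numpy as np
import pandas as pd
import pytest

from rivevol.io_datamodel import FOCAL, NEUTRAL, CatchTable, GenotypePanel
from rivevol.synthetic_data import SimScenario, generate


@pytest.fixture
def tiny_panel() -> GenotypePanel:
    """Three individuals, two neutral loci and one focal locus, fully called."""
    individuals = pd.DataFrame(
        {
            "period": ["1925", "1925", "1987"],
            "sex": ["F", "M", "F"],
            "origin": ["wild", "wild", "hatchery"],
        },
        index=pd.Index(["i1", "i2", "i3"], name="individual_id"),
    )
    calls = pd.DataFrame(
        {
            "snp1": [0.0, 1.0, 2.0],
            "snp2": [1.0, 1.0, 0.0],
            "vgll3": [2.0, 1.0, 0.0],
        },
        index=individuals.index,
    )
    loci = pd.DataFrame(
        {
            "class": [NEUTRAL, NEUTRAL, FOCAL],
            "tracked_allele": ["A", "A", "E"],
        },
        index=pd.Index(["snp1", "snp2", "vgll3"], name="locus_id"),
    )
    return GenotypePanel(individuals, calls, loci)


@pytest.fixture
def tiny_catch() -> CatchTable:
    return CatchTable(
        pd.DataFrame(
            {
                "year": [1950, 1951, 1951],
                "mass_kg": [10.0, 8.0, 12.0],
                "sea_age": [3, 2, 3],
                "smolt_age": [2, 2, 3],
                "sex": ["F", "M", "F"],
                "origin": ["wild", "wild", "wild"],
            }
        )
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared by read-only tests."""
    scenario = SimScenario(
        seed=42,
        end_year=1990,
        n_neutral_loci=25,
        sample_plan=((1940, 60), (1970, 60), (1990, 60)),
        catch_n_per_year=80,
    )
    return scenario, generate(scenario)
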