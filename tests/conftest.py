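import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import diagsnp as dg

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_matrix(dosage, accession_ids=None, marker_ids=None) -> dg.GenotypeMatrix:
    """Small GenotypeMatrix from a nested list (−1 = missing)."""
    d = np.asarray(dosage, dtype=np.int8)
    acc = accession_ids or [f"acc{i}" for i in range(d.shape[0])]
    mk = marker_ids or [f"m{j}" for j in range(d.shape[1])]
    return dg.GenotypeMatrix(acc, mk, d)


def make_markers(n, chrom="chr1", spacing=1000, fragment_id=None) -> dg.MarkerTable:
    rows = [
        {
            "marker_id": f"m{j}",
            "chrom": chrom,
            "pos": 1 + j * spacing,
            "ref": "A",
            "alt": "C",
            "fragment_id": fragment_id,
        }
        for j in range(n)
    ]
    return dg.MarkerTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_scenario() -> dg.SimulatedDataset:
    """Paper-mimic reference design: 4 taxa sampled 11/9/5/1, 57 fragments."""
    return dg.build_scenario(dg.ScenarioConfig(rng_seed=20240901))


@pytest.fixture(scope="session")
def recovery_scenario() -> dg.SimulatedDataset:
    """Balanced design for exact planted-diagnostic recovery: 10 per taxon,
    1,000 markers, 10% fixed differences per taxon, no introgression."""
    cfg = dg.ScenarioConfig(
        rng_seed=20240902,
        accessions_per_taxon=10,
        fragments_per_chromosome=(6, 6, 6, 6, 6, 5, 5, 5, 5),
        markers_per_fragment=20,
        fixed_diff_fraction=0.10,
        private_polymorphism_fraction=0.05,
        split_difference_fraction=0.30,
        shared_polymorphism_fraction=0.03,
    )
    return dg.build_scenario(cfg)


@pytest.fixture(scope="session")
def introgression_scenario() -> dg.SimulatedDataset:
    """4 of 11 mandarin references carry pummelo-heterozygous fragments on
    an independent 20% of fragments each."""
    intro = tuple(
        dg.IntrogressionSpec(f"mandarin_{i:02d}", "pummelo", 0.2) for i in (1, 2, 3, 4)
    )
    return dg.build_scenario(dg.ScenarioConfig(rng_seed=20240903, introgressions=intro))
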