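import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import protpool as pp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_proteins():
    """Three hand-made proteins: two taxa, one shared sequence."""
    return [
        pp.ProteinRecord("p1", "diatom", "AAAGGGKTTTCCCRVVVMMMK",
                         annotations=("50S ribosomal protein L2",)),
        pp.ProteinRecord("p2", "diatom", "LLLEEEKDDDFFFR",
                         annotations=("chlorophyll a-b binding protein",)),
        pp.ProteinRecord("p3", "haptophyte", "AAAGGGKTTTCCCRVVVMMMK",
                         annotations=("50S ribosomal protein L3",)),
    ]


@pytest.fixture(scope="session")
def toy_pepmap(toy_proteins):
    return pp.build_peptide_map(toy_proteins, missed_cleavages=0,
                                length_bounds=(2, 50))


@pytest.fixture(scope="session")
def small_dataset():
    """One small DDA-acquired dataset reused by read-only tests."""
    config = pp.CommunityConfig(n_taxa=2, n_proteins_per_pool=10,
                                n_timepoints=2, seed=123)
    return pp.simulate_dataset(config, pp.DDAParams())


@pytest.fixture(scope="session")
def exhaustive_small():
    """Exhaustively observed community (identification-complete)."""
    config = pp.CommunityConfig(n_taxa=2, n_proteins_per_pool=10,
                                n_timepoints=3, noise_cv=0.05, seed=7)
    ds, table = pp.exhaustive_intensity_table(config)
    return ds, table


def simple_intensity_table(rows, tic=None):
    """rows: (peptide, timepoint, filter, injection, intensity)."""
    data = pd.DataFrame(
        rows, columns=["peptide", "timepoint", "filter", "injection", "intensity"]
    )
    tic_frame = None
    if tic is not None:
        tic_frame = pd.DataFrame(
            tic, columns=["timepoint", "filter", "injection", "tic"]
        )
    return pp.IntensityTable(data, tic=tic_frame)


def pepmap_from_specs(specs):
    """specs: peptide -> (taxa tuple, pools tuple). Minimal map frame."""
    rows = {}
    for pep, (taxa, pools) in specs.items():
        taxa, pools = tuple(sorted(set(taxa))), tuple(sorted(set(pools)))
        rows[pep] = {
            "parents": ("x",),
            "taxa": taxa,
            "pools": pools,
            "n_parents": 1,
            "taxon_unique": len(taxa) == 1,
            "pool_unique": len(pools) == 1,
            "taxon": taxa[0] if len(taxa) == 1 else None,
            "pool": pools[0] if len(pools) == 1 else None,
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
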