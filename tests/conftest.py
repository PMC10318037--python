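import numpy as np
import pandas as pd
import pytest

from microstab import CountTable, SampleMetadata, SimulationScenario, simulate_communities, simulate_processes


def make_count_table(counts: np.ndarray, sample_ids=None, taxon_ids=None, phyla=None, genera=None) -> CountTable:
    counts = np.asarray(counts)
    n, p = counts.shape
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(n)]
    taxon_ids = taxon_ids or [f"T{j + 1}" for j in range(p)]
    phyla = phyla or ["Proteobacteria"] * p
    genera = genera or [f"G{j + 1}" for j in range(p)]
    tax = pd.DataFrame(
        {
            "domain": "Bacteria",
            "phylum": phyla,
            "class": None,
            "order": None,
            "family": None,
            "genus": genera,
        },
        index=pd.Index(taxon_ids),
    )
    frame = pd.DataFrame(counts, index=pd.Index(sample_ids), columns=pd.Index(taxon_ids))
    return CountTable(counts=frame, taxonomy=tax)


@pytest.fixture
def tiny_counts() -> CountTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(6, 8))
    counts[0, 3] = 0
    return make_count_table(
        counts,
        phyla=["Proteobacteria"] * 4 + ["Actinobacteria"] * 3 + [None],
    )


@pytest.fixture(scope="session")
def small_scenario() -> SimulationScenario:
    """Down-scaled experiment for fast tests; same structure as the default."""
    return SimulationScenario(
        pool_size=120,
        dilution_cells={"D0": 20_000, "D1": 250, "D2": 80},
        depth_mean=3000.0,
        n_replicates=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_scenario):
    counts, meta = simulate_communities(small_scenario)
    proc, truth = simulate_processes(counts, meta, small_scenario)
    return counts, meta, proc, truth


def design_metadata(n_per_cell=2, land_uses=("cultivated", "prairie"), levels=("D0", "D1", "D2")) -> SampleMetadata:
    rows = {}
    for lu in land_uses:
        for dl in levels:
            for stress in ("control", "stressed"):
                for rep in range(1, n_per_cell + 1):
                    rows[f"{lu}-{dl}-{stress}-r{rep}"] = (lu, dl, stress, rep)
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["land_use", "diversity_level", "stress", "replicate"]
    )
    return SampleMetadata(frame=frame, diversity_levels=levels)
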