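import numpy as np
import pytest

from causalmap import SimulationConfig, build_reference, plant_variants, simulate_marker_panel
from causalmap.intervals import select_informative_markers


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A fast, miniature cross design for unit tests."""
    return SimulationConfig(
        chromosome_lengths={"chr1": 1_500_000, "chr2": 1_500_000},
        gene_count=40,
        marker_array_size=400,
        informative_markers=160,
        f2_size_mapping=60,
        f2_size_bulk=60,
        bulk_size=10,
        mutagen_rate=2e-5,
        intracultivar_rate=2e-5,
        linkage_n_mutant=20,
        linkage_n_wt=20,
        rnaseq_n_genes=400,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Reference + genes + planted variants + informative panel, one seed."""
    rng = np.random.default_rng(7)
    reference, genes = build_reference(small_config, rng)
    variant_set = plant_variants(reference, genes, small_config, rng)
    raw = simulate_marker_panel(small_config, rng)
    panel = select_informative_markers(raw["parent_mutant"], raw["parent_wt"], raw)
    return {
        "config": small_config,
        "reference": reference,
        "genes": genes,
        "variant_set": variant_set,
        "raw_panel": raw,
        "panel": panel,
    }


@pytest.fixture(scope="session")
def truncation_example():
    from causalmap import build_truncation_example

    return build_truncation_example()
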