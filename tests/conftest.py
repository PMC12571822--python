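from __future__ import annotations

import pytest

from gchap import call_gchaps, read_gff3, read_panel, read_traits, read_vcf
from gchap.synthetic_data import SimConfig, simulate_panel


@pytest.fixture(scope="session")
def sim_result(tmp_path_factory):
    """Small noise-free simulated dataset shared across tests."""
    config = SimConfig(
        seed=11,
        n_genes=4,
        sites_per_gene=12,
        n_haps_per_gene=8,
        populations=(
            ("Xian", "LAN", 120),
            ("Xian", "MV", 60),
            ("Geng", "LAN", 80),
            ("Geng", "MV", 40),
        ),
        het_rate=0.0,
        missing_rate=0.0,
    )
    out = tmp_path_factory.mktemp("simdata")
    return simulate_panel(config, str(out))


@pytest.fixture(scope="session")
def sim_loaded(sim_result):
    """The simulated dataset read back through the standard readers."""
    sites, samples = read_vcf(sim_result.paths["vcf"])
    models = read_gff3(sim_result.paths["gff3"])
    models.sort(key=lambda m: m.gene_id)
    panel = read_panel(sim_result.paths["panel"])
    read_traits(sim_result.paths["traits"], panel)
    assert samples == panel.accession_ids
    return sites, models, panel


@pytest.fixture(scope="session")
def sim_tables(sim_loaded):
    sites, models, panel = sim_loaded
    return [call_gchaps(m, sites, panel) for m in models]
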