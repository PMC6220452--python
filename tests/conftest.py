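import pytest

from epiregseek.methylome import call_dmcs_frame
from epiregseek.simulate import SimulationConfig, simulate


def small_config(**overrides):
    """A fast single-chromosome configuration for unit-scale simulations."""
    defaults = dict(
        seed=11,
        n_chrom=1,
        chrom_length=80_000,
        n_genes=6,
        n_tes=12,
        n_dmrs={"CHH": 2, "CG": 1},
        n_epiregs=1,
        n_positive_couplings=1,
        n_degs=3,
        n_dets=2,
        n_years=2,
        n_varieties=5,
        n_pheno_reps=2,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def sim():
    """The default-scale simulation every recovery test runs on."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_sites(sim):
    """Per-site DmC frame for the LS vs HL comparison of the session sim."""
    return call_dmcs_frame(sim.methylomes["LS"], sim.methylomes["HL"])


@pytest.fixture(scope="session")
def sim_dmrs(sim_sites):
    """DMRs called per context on the session simulation."""
    from epiregseek.dmr import call_dmrs_from_sites

    return {
        ctx: call_dmrs_from_sites(sim_sites[sim_sites["context"] == ctx], ctx)
        for ctx in ("CG", "CHG", "CHH")
    }
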