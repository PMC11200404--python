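import pytest

from mabtrain import build_topology, run_campaign
from mabtrain.configio import load_schedule, packaged_schedule
from mabtrain.monitor import monitor_campaign

#: fixed seed for the packaged campaign fixtures
FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def topology():
    return build_topology()


@pytest.fixture(scope="session")
def deviation_schedule():
    return load_schedule(packaged_schedule())


@pytest.fixture(scope="session")
def nominal_campaign(topology):
    return run_campaign(topology=topology, schedule=[], seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def deviated_campaign(topology, deviation_schedule):
    return run_campaign(topology=topology, schedule=deviation_schedule, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def deviated_summary(deviated_campaign):
    return monitor_campaign(
        deviated_campaign.chrom_cycles["proa"],
        deviated_campaign.chrom_cycles["cex"],
        deviated_campaign.ufdf_cycles,
    )


@pytest.fixture(scope="session")
def nominal_summary(nominal_campaign):
    return monitor_campaign(
        nominal_campaign.chrom_cycles["proa"],
        nominal_campaign.chrom_cycles["cex"],
        nominal_campaign.ufdf_cycles,
    )
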