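import pytest

from timernet import build_expectation_suite, build_terminal_network, simulate_all


@pytest.fixture(scope="session")
def network():
    return build_terminal_network()


@pytest.fixture(scope="session")
def trajectories(network):
    return simulate_all(network)


@pytest.fixture(scope="session")
def suite():
    return build_expectation_suite()


def brute_force_level(network, genotype, region, timepoint, factor):
    """Independent oracle: recursive evaluation of the update rules.

    Recomputes one (region, timepoint, factor) level straight from the
    definitions, without any forward simulation loop.
    """
    if isinstance(genotype, str):
        genotype = network.genotype(genotype)
    if factor in genotype.clamped:
        return 0
    fdef = network.factor(factor)
    if fdef.role == "input":
        return int(network.schedule[factor][region - 1, timepoint])
    if timepoint == 0:
        return int(network.initial.get(factor, 0))
    prev = {
        f.name: brute_force_level(network, genotype, region, timepoint - 1, f.name)
        for f in network.factors
    }
    return int(network.rules[factor](prev))
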