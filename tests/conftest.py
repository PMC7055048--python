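import dataclasses

import pytest

from fitcea import ARMS, DistributionSpec, builtin_fixture


def zero_epidemiology(params):
    """Copy of the parameter set with no disease onset and no mortality."""
    epi = params.epidemiology
    return dataclasses.replace(params, epidemiology=dataclasses.replace(
        epi,
        disease_incidence={k: 0.0 for k in epi.disease_incidence},
        activity_mortality={k: 0.0 for k in epi.activity_mortality},
        disease_mortality={k: 0.0 for k in epi.disease_mortality},
    ))


@pytest.fixture(scope="session")
def base_params():
    """Published base-case parameter set (societal perspective, trial utilities)."""
    return builtin_fixture()


def make_all_fixed(params):
    """Freeze every sampled parameter at its deterministic analysis value.

    Activity transitions at their distribution means, payoffs at their point
    values: the result runs identically to ``params`` deterministically but
    has nothing left for the PSA to sample.
    """
    blocks = {}
    for arm in ARMS:
        block = params.activity_transitions[arm]
        probs = {key: DistributionSpec.fixed(spec.mean()) for key, spec in block.probs.items()}
        blocks[arm] = dataclasses.replace(block, probs=probs)
    payoffs = params.payoffs
    utils = {src: {s: DistributionSpec.fixed(spec.point) for s, spec in mapping.items()}
             for src, mapping in payoffs.activity_utilities.items()}
    costs = {persp: {s: DistributionSpec.fixed(spec.point) for s, spec in mapping.items()}
             for persp, mapping in payoffs.activity_costs.items()}
    payoffs = dataclasses.replace(payoffs, activity_utilities=utils, activity_costs=costs)
    return dataclasses.replace(params, activity_transitions=blocks, payoffs=payoffs)


@pytest.fixture()
def all_fixed_params(base_params):
    return make_all_fixed(base_params)
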