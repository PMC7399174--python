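import pytest

import synlogic as sl


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study: 28 nodes, 6 drugs, 2 planted flips, clean data."""
    return sl.make_bundle(seed=1)


@pytest.fixture(scope="session")
def calibrated(bundle):
    return sl.calibrate(bundle.generic_model, bundle.profile_truth)


@pytest.fixture(scope="session")
def observed(bundle):
    return sl.score_screen(list(bundle.screen_records))


@pytest.fixture(scope="session")
def wt_calls(bundle, calibrated):
    return sl.predict_synergies(calibrated.model, bundle.panel,
                                reference_state=calibrated.selected_state,
                                cell_line="SYN-1")


@pytest.fixture(scope="session")
def sweep_records(bundle, calibrated, observed):
    return sl.influence_sweep(calibrated.model, bundle.panel,
                              reference_state=calibrated.selected_state,
                              observed=observed)


def random_model(seed, n_nodes, n_cycles=0, n_targets=3, flip_every=3):
    """Random logical model with mixed link operators for engine tests."""
    from synlogic.model import LinkRule

    net = sl.gen_network(n_nodes=n_nodes, n_targets=min(n_targets, n_nodes - 4),
                         n_cycles=n_cycles, seed=seed)
    model = sl.default_rules(net)
    for i, node in enumerate(sorted(model.network.nodes)):
        rule = model.rules[node]
        if isinstance(rule, LinkRule) and i % flip_every == 0:
            model = model.with_rule(LinkRule(node, rule.activators,
                                             rule.inhibitors, sl.OR_NOT))
    return model
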