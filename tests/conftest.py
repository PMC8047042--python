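import math

import pytest

from vocnet import feature_assembly as fa
from vocnet import semantic_network as sn
from vocnet import synthetic_data as sd


@pytest.fixture(scope="session")
def four_noun_lexicon():
    """Hand-built lexicon whose two-shared-feature network is the standard
    four-node / five-edge worked example (apple, eye, ball, balloon)."""
    return sd.example_lexicon()


@pytest.fixture(scope="session")
def worked_example_network(four_noun_lexicon):
    return sn.build_network(["apple", "eye", "ball", "balloon"], four_noun_lexicon)


@pytest.fixture(scope="session")
def signal_bundle():
    """Small synthetic cohort with both size and structure group effects;
    shared across modelling tests to amortise generation cost."""
    cfg = sd.SimConfig(n_children=240, prevalence=0.12, structure_bias=2.0, seed=7)
    return sd.generate_children(cfg)


@pytest.fixture(scope="session")
def signal_table(signal_bundle):
    metrics = sn.metrics_table(signal_bundle)
    return fa.assemble_features(signal_bundle.records, metrics, signal_bundle.norms)


def recovery_config(seed: int) -> sd.SimConfig:
    """Study conditions for parameter-recovery checks: n=400, prevalence
    0.10, strong size + structure effects, grammar links flattened so the
    injected signal is confined to the network measures and vocabulary
    percentile."""
    flat_grammar = sd.GrammarSpec(
        combine_midpoint=5.0,
        combine_scale=3.0,
        complexity_midpoint=300.0,
        complexity_scale=50.0,
    )
    return sd.SimConfig(
        n_children=400,
        prevalence=0.10,
        structure_bias=1.2,
        vocab_lognorm_ll=(math.log(35.0), 0.55),
        grammar_spec=flat_grammar,
        seed=seed,
    )
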