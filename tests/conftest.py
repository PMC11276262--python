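import numpy as np
import pytest

from ppilearn.dataset import assemble_dataset, build_feature_space
from ppilearn.ontology import backtrack_annotations, parse_obo_text
from ppilearn.synthetic import make_world, simulate_interactome

CHAIN_OBO = """\
format-version: 1.4

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: A
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: B
namespace: biological_process
is_a: GO:0000002 ! A

[Term]
id: GO:0000004
name: C
namespace: biological_process
relationship: part_of GO:0000003

[Term]
id: GO:0000005
name: D
namespace: biological_process
relationship: regulates GO:0000004
"""


@pytest.fixture
def chain_graph():
    """root <- A <- B <- C <- D (5 terms, 4 edges, one per relation flavour)."""
    return parse_obo_text(CHAIN_OBO)


@pytest.fixture
def chain_obo_text():
    return CHAIN_OBO


def _world_dataset(world):
    sample = simulate_interactome(world)
    go_l = backtrack_annotations(
        world.proteome.go, world.ontology, world.levels, world.level
    ).mapping
    space = build_feature_space(world.proteome.domains, go_l)
    ds = assemble_dataset(
        sample.positives, sample.negatives, space, world.proteome.domains, go_l,
        mirrored=True, shuffle_seed=7,
    )
    return world, sample, go_l, space, ds


@pytest.fixture(scope="session")
def recovery_bundle():
    """The benchmark world: 200 proteins, 40 domains, 5 domain rules, no noise."""
    world = make_world(
        n_proteins=200, n_domains=40, n_domain_rules=5, n_go_rules=0,
        level=2, noise=0.0, seed=11,
    )
    return _world_dataset(world)


@pytest.fixture(scope="session")
def small_bundle():
    """Cheaper world for unit-level classifier/network tests."""
    world = make_world(
        n_proteins=60, n_domains=15, n_domain_rules=3, n_go_rules=0,
        level=2, noise=0.0, seed=5, mean_domains_per_protein=2.5,
        ontology_terms=12, ontology_depth=3,
    )
    return _world_dataset(world)
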