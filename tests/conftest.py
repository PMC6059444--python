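import numpy as np
import pytest

from contamscreen.experiments import run_battery
from contamscreen.pipeline import build_reference_pack
from contamscreen.simulate import SimConfig, simulate_universe
from contamscreen.taxonomy import TaxonNode, TaxonomyTree


@pytest.fixture(scope="session")
def small_universe():
    """A small reference universe for unit-level end-to-end checks."""
    return simulate_universe(SimConfig(seed=11, genome_length=60_000))


@pytest.fixture(scope="session")
def small_pack(small_universe):
    return build_reference_pack(small_universe)


@pytest.fixture(scope="session")
def battery():
    """The 10-pair chimera/clean battery screened by all six methods
    (f = 10%, compositionally distant contaminants carrying their full
    marker panel)."""
    return run_battery(seed=1, n_pairs=10)


@pytest.fixture()
def toy_tree():
    """root -> dom -> {p1 (focal) -> g1 -> {s1, s2}; p2 -> g2 -> {s3, s4}}."""
    nodes = [
        TaxonNode("root", None, "root"),
        TaxonNode("dom", "root", "domain"),
        TaxonNode("p1", "dom", "phylum"),
        TaxonNode("p2", "dom", "phylum"),
        TaxonNode("g1", "p1", "genus"),
        TaxonNode("g2", "p2", "genus"),
        TaxonNode("s1", "g1", "species"),
        TaxonNode("s2", "g1", "species"),
        TaxonNode("s3", "g2", "species"),
        TaxonNode("s4", "g2", "species"),
    ]
    return TaxonomyTree(nodes, focal_id="p1")


def random_tree(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Random rooted tree: node i's parent is uniform over earlier nodes."""
    nodes = [TaxonNode("n0", None, "root")]
    for i in range(1, n_nodes):
        parent = f"n{int(rng.integers(0, i))}"
        nodes.append(TaxonNode(f"n{i}", parent, "no-rank"))
    focal = f"n{int(rng.integers(0, n_nodes))}"
    return TaxonomyTree(nodes, focal_id=focal)


def lca_oracle(tree: TaxonomyTree, taxa) -> str:
    """Brute-force LCA: intersect root-paths, take the deepest member."""
    paths = [set(tree.path_to_root(t)) for t in taxa]
    common = set.intersection(*paths)
    return max(common, key=tree.depth)
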