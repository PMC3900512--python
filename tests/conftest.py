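import dendropy
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def kamimuria_annotation():
    from mitokit.datasets import load_annotation

    return load_annotation()


@pytest.fixture(scope="session")
def kamimuria_annotation_frame():
    from mitokit.datasets import load_annotation_frame

    return load_annotation_frame()


@pytest.fixture(scope="session")
def kamimuria_codon_counts():
    from mitokit.datasets import load_codon_counts

    return load_codon_counts()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One default synthetic mitogenome (seed 1) with its truth record."""
    from mitokit.synthetic import default_genome_spec, generate_mitogenome

    return generate_mitogenome(default_genome_spec(seed=1))


@pytest.fixture(scope="session")
def evolved_alignment():
    """Per-gene alignments evolved along the 13-taxon insect guide tree."""
    from mitokit.synthetic import EvolutionSpec, evolve_alignment

    return evolve_alignment(EvolutionSpec(seed=5))


@pytest.fixture
def additive_tree_factory():
    """Random unrooted trees with positive branch lengths, plus their
    exact path-length (additive) distance matrices."""

    def build(n_taxa: int, rng: np.random.Generator):
        tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.is_rooted = False
        seed = tree.seed_node
        edges = []
        for i in range(3):
            child = seed.new_child(taxon=tns.get_taxon(f"t{i}"),
                                   edge_length=float(rng.uniform(0.1, 1.0)))
            edges.append(child.edge)
        for i in range(3, n_taxa):
            edge = edges[rng.integers(len(edges))]
            child, parent = edge.head_node, edge.tail_node
            mid = dendropy.Node()
            parent.remove_child(child)
            parent.add_child(mid)
            mid.add_child(child)
            old = child.edge.length
            mid.edge.length = old * 0.5
            child.edge.length = old * 0.5
            tip = mid.new_child(taxon=tns.get_taxon(f"t{i}"),
                                edge_length=float(rng.uniform(0.1, 1.0)))
            edges.extend([tip.edge, child.edge, mid.edge])
        pdm = tree.phylogenetic_distance_matrix()
        taxa = tuple(t.label for t in tns)
        mat = np.zeros((n_taxa, n_taxa))
        for i, a in enumerate(tns):
            for j, b in enumerate(tns):
                mat[i, j] = pdm.distance(a, b)
        return tree, taxa, mat

    return build
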