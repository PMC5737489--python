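import pytest

from tandemgenes.model import GeneRecord
from tandemgenes.simulate import SimParams, simulate_annotation
from tandemgenes.tandem import assign_gene_order


@pytest.fixture
def small_sim():
    """One small simulated annotation (≈80 genes, 4 scaffolds) with truth."""
    params = SimParams(
        seed=7,
        n_scaffolds=4,
        genes_per_scaffold=(18, 24),
        n_families=8,
        family_size=(2, 4),
        gap_runs_per_scaffold=(1, 2),
    )
    scaffolds, genes, truth = simulate_annotation(params)
    return params, scaffolds, genes, truth


def make_genes(starts, scaffold="sc1", length=800, prefix="g"):
    """Equal-length genes at the given start coordinates, ranks assigned."""
    genes = [
        GeneRecord(gene_id=f"{prefix}{i}", scaffold_id=scaffold,
                   start=s, end=s + length - 1)
        for i, s in enumerate(starts)
    ]
    assign_gene_order(genes)
    return genes
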