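import numpy as np
import pytest

from mlc.preprocess import ExpressionMatrix, center_scale
from mlc.simulate import SimulationSpec, generate


@pytest.fixture
def toy_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    values = rng.integers(0, 500, size=(10, 6)).astype(float)
    # inflate column sums so the depth filter keeps everything by default
    values *= 1e5
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(f"g{i}" for i in range(10)),
        sample_ids=tuple(f"s{j}" for j in range(6)),
        batch_ids=("A", "A", "B", "B", "C", "C"),
    )


@pytest.fixture
def small_scaled():
    rng = np.random.default_rng(7)
    return center_scale(rng.standard_normal((12, 8)))


@pytest.fixture
def small_sim():
    spec = SimulationSpec(
        n_genes=120,
        n_samples=60,
        n_terms=2,
        positives_per_term=15,
        informative_block_size=12,
        within_block_correlation=0.8,
        seed=11,
    )
    return generate(spec)


GAF_TEXT = """!gaf-version: 2.1
TAIR\tG1\tG1S\t\tGO:0000002\tREF:1\tEXP\t\tP\tn\t\tgene\ttaxon:3702\t20160901\tTAIR\t\t
TAIR\tG1\tG1S\t\tGO:0000004\tREF:1\tIDA\t\tP\tn\t\tgene\ttaxon:3702\t20160901\tTAIR\t\t
TAIR\tG2\tG2S\t\tGO:0000003\tREF:2\tIEA\t\tP\tn\t\tgene\ttaxon:3702\t20160901\tTAIR\t\t
TAIR\tG2\tG2S\t\tGO:0000002\tREF:2\tIMP\t\tP\tn\t\tgene\ttaxon:3702\t20160901\tTAIR\t\t
TAIR\tG3\tG3S\tNOT\tGO:0000002\tREF:3\tEXP\t\tP\tn\t\tgene\ttaxon:3702\t20160901\tTAIR\t\t
TAIR\tG3\tG3S\t\tGO:0000005\tREF:3\tEXP\t\tF\tn\t\tgene\ttaxon:3702\t20160901\tTAIR\t\t
TAIR\tG4\tG4S\t\tGO:0000003\tREF:4\tHDA\t\tP\tn\t\tgene\ttaxon:3702\t20160901\tTAIR\t\t
"""

OBO_TEXT = """format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: mid process
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: other mid
namespace: biological_process
is_a: GO:0000001 ! root process

[Term]
id: GO:0000004
name: leaf process
namespace: biological_process
is_a: GO:0000002 ! mid process
relationship: part_of GO:0000003 ! other mid

[Term]
id: GO:0000005
name: molecular thing
namespace: molecular_function
"""


@pytest.fixture
def gaf_file(tmp_path):
    p = tmp_path / "toy.gaf"
    p.write_text(GAF_TEXT)
    return str(p)


@pytest.fixture
def obo_file(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(OBO_TEXT)
    return str(p)
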