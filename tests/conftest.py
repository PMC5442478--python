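import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from chromdyn.core_io import ExpressionTable, GeneAnnotation, GenomeSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_genome():
    return GenomeSpec({"chr1": 50_000, "chr2": 30_000})


@pytest.fixture
def two_gene_annotation():
    # one gene per strand; the - strand gene's TSS is the larger coordinate
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gplus", "gminus"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "-"],
                "tss": [10_000, 30_000],
                "tes": [12_000, 28_000],
            }
        )
    )


@pytest.fixture
def expression_fixture():
    return ExpressionTable(
        pd.DataFrame(
            {
                "gene_id": ["gplus", "gminus"],
                "expr_a": [10.0, 20.0],
                "expr_b": [40.0, 5.0],
                "log2_fc": [2.0, -2.0],
                "deg_label": ["up", "down"],
            }
        )
    )
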