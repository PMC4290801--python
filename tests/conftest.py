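"""Shared fixtures: the 10-record worked example and taxonomy forests."""

import numpy as np
import pytest

from dpgenome import GenotypeTable, build_flat_taxonomy, make_blocks
from dpgenome.taxonomy import USER_SUPPLIED, TaxonomyForest, TaxonomyNode

# A small cohort of 10 individuals typed at 8 SNPs, used throughout as the
# hand-checkable instance (blocked in pairs it has 4 blocks with 4/4/5/2
# distinct values).
WORKED_ROWS = [
    "AG CC CC GG CT GG AA CC",
    "AG CC CC GG TT GG AA CC",
    "AA CC CC GG TT GG AA CC",
    "AG CT CT AG CT AG AG CT",
    "GG CT CT AG CC GG AA CC",
    "AA CC CC GG TT GG AA CC",
    "AG CT CT AG CT AG AG CT",
    "AA CC CC GG TT GG AA CC",
    "GG CT TT AG CC AG AA CC",
    "AG CT CT GG CT AG AA CC",
]

# True partition of the worked table under the forced trace
# (block 2 -> leaves, block 4 -> leaves) with the flat forest.
WORKED_FORCED_TRACE = [(1, "Any_2"), (3, "Any_4")]
WORKED_PARTITION = {
    ("Any", "CC GG", "Any", "AA CC"): 5,
    ("Any", "CT AG", "Any", "AA CC"): 1,
    ("Any", "CT AG", "Any", "AG CT"): 2,
    ("Any", "TT AG", "Any", "AA CC"): 1,
    ("Any", "CT GG", "Any", "AA CC"): 1,
}


def table_from_rows(rows, ids=None, snp_prefix="snp"):
    gen = np.array([r.split(" ") for r in rows], dtype="<U2")
    ids = ids if ids is not None else [str(i + 1) for i in range(len(rows))]
    snps = [f"{snp_prefix}{j + 1}" for j in range(gen.shape[1])]
    return GenotypeTable(ids, snps, gen)


def random_table(rng, n, m, alphabet=("AA", "AG", "GG", "CC", "CT", "TT")):
    gen = np.array(alphabet, dtype="<U2")[rng.integers(len(alphabet), size=(n, m))]
    return GenotypeTable([f"r{i}" for i in range(n)], [f"s{j}" for j in range(m)], gen)


@pytest.fixture
def worked_table():
    return table_from_rows(WORKED_ROWS)


@pytest.fixture
def blocks4():
    return make_blocks(8, 2)


@pytest.fixture
def flat_forest(worked_table, blocks4):
    return build_flat_taxonomy(worked_table, blocks4)


def make_example_forest(blocks):
    """User-supplied forest with a multilevel block-2 tree.

    The two depth-1 categories of block 2 are named after their
    representative values; specializing blocks 2 and 4 yields a 2 x 2
    release over (CC GG | CT AG) x (AA CC | AG CT).
    """

    def leaf(label):
        return TaxonomyNode(label)

    trees = [
        TaxonomyNode(
            "Any_1", [leaf(v) for v in ["AA CC", "AG CC", "AG CT", "GG CT"]]
        ),
        TaxonomyNode(
            "Any_2",
            [
                TaxonomyNode("CC GG", [leaf("CC GG"), leaf("CT GG")]),
                TaxonomyNode("CT AG", [leaf("CT AG"), leaf("TT AG")]),
            ],
        ),
        TaxonomyNode(
            "Any_3",
            [leaf(v) for v in ["CC AG", "CC GG", "CT AG", "CT GG", "TT GG"]],
        ),
        TaxonomyNode("Any_4", [leaf("AA CC"), leaf("AG CT")]),
    ]
    return TaxonomyForest(trees, blocks, USER_SUPPLIED)


@pytest.fixture
def example_forest(blocks4):
    return make_example_forest(blocks4)
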