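import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microtempo.datamodel import CountTable, PhyloTree, SampleTable
from microtempo.synthetic import ScenarioConfig, make_scenario


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        pd.DataFrame(
            [[6, 3, 1], [0, 5, 5], [2, 2, 2]],
            index=["s1", "s2", "s3"],
            columns=["a", "b", "c"],
        )
    )


@pytest.fixture
def three_tip_tree() -> PhyloTree:
    return PhyloTree(TreeNode.read(["(A:1,(B:1,C:1):1);"]))


@pytest.fixture
def monthly_meta() -> SampleTable:
    dates = pd.date_range("2013-04-15", periods=3, freq="MS")
    return SampleTable(
        pd.DataFrame(
            {
                "date": dates.strftime("%Y-%m-%d"),
                "site": "X",
                "size_fraction": "small",
                "temperature": [10.0, 12.0, 14.0],
            },
            index=["s1", "s2", "s3"],
        )
    )


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small two-site bundle reused by pipeline-level tests."""
    cfg = ScenarioConfig(n_taxa=40, n_months=24, pop_size=400, seed=11)
    return make_scenario(cfg)
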