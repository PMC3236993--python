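"""Shared fixtures: published-table fixtures, baseline model, random trees."""

from __future__ import annotations

import numpy as np
import pytest

from aclcea.config import (
    baseline_config,
    key_from_config,
    packaged_data_path,
    params_from_config,
)
from aclcea.costing import read_resource_csv
from aclcea.evidence import CLASSES, read_study_csv
from aclcea.tree import TreeNode


@pytest.fixture(scope="session")
def table1_records():
    return read_study_csv(packaged_data_path("table1_activity.csv"))


@pytest.fixture(scope="session")
def table2_profiles():
    return read_resource_csv(packaged_data_path("table2_resources.csv"))


@pytest.fixture(scope="session")
def config():
    return baseline_config()


@pytest.fixture(scope="session")
def baseline_params(config):
    return params_from_config(config)


@pytest.fixture(scope="session")
def baseline_key(config):
    return key_from_config(config)


def random_tree(
    rng: np.random.Generator, max_depth: int = 5, max_children: int = 4, depth: int = 0
) -> TreeNode:
    """Random valid chance/terminal tree for oracle comparisons."""
    if depth >= max_depth or rng.random() < 0.3:
        return TreeNode(
            kind="terminal",
            label=f"leaf_{depth}_{rng.integers(1 << 30)}",
            payoff_cost=float(rng.uniform(0, 20000)),
            payoff_effect=float(rng.uniform(0, 1)),
        )
    k = int(rng.integers(2, max_children + 1))
    probs = rng.dirichlet(np.ones(k))
    probs[-1] = 1.0 - probs[:-1].sum()  # exact sum-to-1
    children = [
        (float(p), random_tree(rng, max_depth, max_children, depth + 1)) for p in probs
    ]
    return TreeNode(kind="chance", label=f"chance_{depth}", children=children)
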