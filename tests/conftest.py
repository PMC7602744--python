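import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from microhost.classifier import ModelConfig, assemble_design
from microhost.diversity import chao_column
from microhost.feature_table import filter_rare
from microhost.synthetic import generate, make_study_layout


@pytest.fixture(scope="session")
def tiny_ds():
    """Small 4+4-project dataset shared across tests (fixed seed)."""
    return generate(make_study_layout("tiny"), seed=1)


@pytest.fixture(scope="session")
def paper_ds():
    """Study-layout dataset (12 pet + 10 human projects, 642 samples)."""
    return generate(make_study_layout("paper_like"), seed=7)


@pytest.fixture(scope="session")
def paper_design(paper_ds):
    """Filtered table, Chao column, and assembled design for the study layout."""
    table = filter_rare(paper_ds.table, paper_ds.metadata)
    chao = chao_column(table, depth=5000, reps=5, seed=3)
    X, y = assemble_design(table, paper_ds.metadata, chao, ModelConfig())
    return {"table": table, "chao": chao, "X": X, "y": y}
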