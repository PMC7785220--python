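import numpy as np
import pandas as pd
import pytest

from synsign import (
    SynthParams,
    default_receptor_class_table,
    generate_synthetic_dataset,
    make_worked_example_fixture,
)


@pytest.fixture(scope="session")
def table():
    return default_receptor_class_table()


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example_fixture()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """A mid-sized reproducible synthetic dataset shared across tests."""
    params = SynthParams(n_neurons=120, seed=42)
    return params, generate_synthetic_dataset(params)


@pytest.fixture
def toy_edge_file(tmp_path):
    """Write a small edge-list file and return its path."""

    def write(rows, name="edges.csv", header="pre,post,kind,weight"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
        return path

    return write
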