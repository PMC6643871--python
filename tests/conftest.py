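"""Shared fixtures: one full pipeline run on the default simulated
dataset, reused by the unit and acceptance tests."""

import json
import os

import pandas as pd
import pytest

from stratigraph.core_model import read_sam, read_tree
from stratigraph.pipeline import RunConfig, build_context, load_dataset, run_all

SEED = 1


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_run")
    summary = run_all(RunConfig(outdir=str(out), seed=SEED))
    with open(out / "summary_fixture.json", "w") as fh:
        json.dump(summary, fh)
    return out


@pytest.fixture(scope="session")
def summary(run_dir):
    with open(run_dir / "summary_fixture.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def dataset(run_dir):
    return load_dataset(os.path.join(run_dir, "dataset"))


@pytest.fixture(scope="session")
def tree(dataset):
    return read_tree(dataset.tree_newick, dataset.focal)


@pytest.fixture(scope="session")
def truth(dataset):
    return dataset.truth


@pytest.fixture(scope="session")
def reads(run_dir):
    return read_sam(os.path.join(run_dir, "dataset", "sp0", "rnaseq.sam"))


@pytest.fixture(scope="session")
def ctx(dataset, tree, reads):
    from stratigraph.trace_validate import StructureParams
    return build_context(dataset, tree, reads, StructureParams(), True)


@pytest.fixture(scope="session")
def classification(run_dir):
    return pd.read_csv(run_dir / "classification.tsv", sep="\t",
                       keep_default_na=False)


@pytest.fixture(scope="session")
def final_classes(run_dir):
    return pd.read_csv(run_dir / "final_classes.tsv", sep="\t",
                       keep_default_na=False)


@pytest.fixture(scope="session")
def mechanisms_tsv(run_dir):
    return pd.read_csv(run_dir / "mechanisms.tsv", sep="\t",
                       keep_default_na=False)


@pytest.fixture(scope="session")
def trace_tsv(run_dir):
    return pd.read_csv(run_dir / "trace_matrix.tsv", sep="\t",
                       keep_default_na=False)


@pytest.fixture(scope="session")
def structure_tsv(run_dir):
    return pd.read_csv(run_dir / "structure_status.tsv", sep="\t",
                       keep_default_na=False,
                       dtype={"exon_support": str, "junction_support": str})


@pytest.fixture(scope="session")
def evidence(run_dir):
    with open(run_dir / "mechanism_evidence.json") as fh:
        return json.load(fh)
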