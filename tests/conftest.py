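import numpy as np
import pytest

from neomotif.analysis_pipeline import run_case
from neomotif.binding_model import train_ensemble
from neomotif.synthetic_data import (
    ProteomeSpec,
    gen_binding_truth,
    gen_genotypes,
    gen_mutations,
    gen_proteome,
    gen_training_set,
)


@pytest.fixture(scope="session")
def proteome():
    """60 random human-like proteins, 80-200 residues."""
    return gen_proteome(ProteomeSpec(n_proteins=60, min_length=80, max_length=200), seed=11)


@pytest.fixture(scope="session")
def genotypes():
    return gen_genotypes(2, seed=12)


@pytest.fixture(scope="session")
def case_run(proteome, genotypes, tmp_path_factory):
    """Full pipeline run: 2 cases x 12 mutations against truth predictors."""
    mutations = []
    for i, case in enumerate(genotypes.case_id):
        mutations += gen_mutations(proteome, 12, 100 + i, rare_bias=True, case_id=case)
    outdir = tmp_path_factory.mktemp("case_run")
    config = dict(proteome=proteome, mutations=mutations, genotypes=genotypes, seed=5)
    summaries, annotations = run_case(config, outdir=outdir)
    return {"summaries": summaries, "annotations": annotations,
            "config": config, "outdir": outdir, "mutations": mutations}


@pytest.fixture(scope="session")
def binding_truth():
    return gen_binding_truth("A*02:01", seed=7, width=9)


@pytest.fixture(scope="session")
def trained_ensemble(binding_truth):
    train = gen_training_set(binding_truth, 1000, seed=8)
    return train_ensemble(train, n_candidates=30, n_keep=8, seed=3)
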