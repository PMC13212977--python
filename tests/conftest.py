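import numpy as np
import pandas as pd
import pytest

import gcnpath as gp


@pytest.fixture(scope="session")
def tiny_world():
    """A small but complete synthetic world shared across tests."""
    return gp.gen_world(
        n_genes=300, n_pathways=10, n_cells=30, n_drugs=8, min_size=5, max_size=10, seed=42
    )


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_world):
    """Scores, PCN, drug graphs and responses derived from tiny_world."""
    w = tiny_world
    expr = gp.normalize_expression(w.expression(0), "log2_pc1")
    scores = gp.score_pathways(expr, w.pathways, method="singscore")
    state = gp.fit_scaler(scores)
    scaled = gp.apply_scaler(scores, state)
    pcn = gp.build_pcn(w.gene_network, w.gene_network, scaled, w.pathways.restrict_to(expr.index))
    graphs, _ = gp.featurize_table(w.drug_table)
    responses = w.responses(0.8)
    return dict(world=w, scores=scores, scaled=scaled, pcn=pcn, graphs=graphs, responses=responses)


@pytest.fixture(scope="session")
def tiny_model(tiny_pipeline):
    cfg = gp.ModelConfig(
        n_pathways=10,
        cell_hidden=[4, 4, 4],
        drug_hidden=[8, 8, 8],
        gat_heads=2,
        cell_embed=16,
        drug_embed=16,
        head_hidden=[16],
        dropout=0.0,
        seed=7,
    )
    return gp.GCNPathModel(cfg, tiny_pipeline["pcn"])


@pytest.fixture()
def response_frame():
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c1", "c1", "c2", "c2", "c3"],
            "drug_id": ["d1", "d1", "d2", "d1", "d2", "d1"],
            "ln_ic50": [1.0, 3.0, 0.5, 2.0, -1.0, 4.0],
            "source": ["GDSC1"] * 6,
        }
    )
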