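import numpy as np
import pytest

import pathprime as pp


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small pathway-structured dataset: 3 types x 40 cells, 6 pathways."""
    cfg = pp.SyntheticConfig(
        n_cell_types=3,
        cells_per_type=40,
        n_genes=300,
        n_pathways=6,
        genes_per_pathway=20,
        active_pathways_per_type=2,
        background_gene_fraction=0.5,
        seed=42,
    )
    return pp.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_masked(tiny_dataset):
    """Gene space reduced to pathway members, with its mask."""
    X, y, collection, truth = tiny_dataset
    Xb, collb = pp.intersect_gene_space(X, collection, mode="biological_only")
    mask = pp.build_mask(Xb.gene_ids, collb)
    return Xb, y, collb, mask, truth


@pytest.fixture(scope="session")
def trained_tiny(tiny_masked):
    """A pathway network trained briefly on the tiny dataset."""
    Xb, y, collb, mask, truth = tiny_masked
    Xp, stats = pp.preprocess(Xb, "zscore")
    cfg = pp.NetworkConfig(
        input_genes=Xb.gene_ids,
        hidden_layers=[pp.LayerSpec(biological=True)],
        n_classes=y.n_classes,
        activation="tanh",
        seed=7,
    )
    model = pp.build_network(cfg, mask)
    model.preprocessing = stats
    pp.train(model, Xp, y, pp.TrainingConfig(epochs=15, seed=7))
    return model, Xp, y


@pytest.fixture()
def separable_toy():
    """20 cells x 4 genes, two classes split by the first two genes."""
    rng = np.random.default_rng(0)
    a = rng.normal(loc=[3, 3, 0, 0], scale=0.3, size=(10, 4))
    b = rng.normal(loc=[0, 0, 3, 3], scale=0.3, size=(10, 4))
    X = pp.ExpressionMatrix(
        np.vstack([a, b]),
        [f"g{i}" for i in range(4)],
        [f"c{i}" for i in range(20)],
    )
    y = pp.LabelVector(["A"] * 10 + ["B"] * 10)
    return X, y
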