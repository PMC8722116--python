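"""Train a pathway-primed classifier on synthetic single-cell data.

Generates a labelled count matrix whose cell types differ by the activity
of designated pathways, restricts the gene space to pathway members, builds
the gene-by-pathway prior mask and trains the masked network. The printed
accuracy is on a held-out stratified 30% split; the parameter count shows
how sparse the masked first layer is compared to a dense layer of the same
width.
"""

import numpy as np

import pathprime as pp

cfg = pp.SyntheticConfig(n_cell_types=5, cells_per_type=100, seed=0)
X, y, collection, truth = pp.generate_dataset(cfg)
print(f"simulated {X.n_cells} cells x {X.n_genes} genes, {len(collection)} pathways")

Xb, collb = pp.intersect_gene_space(X, collection, mode="biological_only")
mask = pp.build_mask(Xb.gene_ids, collb)
print(f"pathway gene space: {Xb.n_genes} genes -> {mask.n_nodes} pathway nodes")

net_cfg = pp.NetworkConfig(
    input_genes=Xb.gene_ids,
    hidden_layers=[pp.LayerSpec(biological=True)],
    n_classes=y.n_classes,
    activation="tanh",
    seed=0,
)
dense_cfg = pp.NetworkConfig(
    input_genes=Xb.gene_ids,
    hidden_layers=[pp.LayerSpec(dense_nodes=mask.n_nodes)],
    n_classes=y.n_classes,
)
print(
    f"effective parameters: masked {pp.count_effective_parameters(net_cfg, mask):,} "
    f"vs dense {pp.count_effective_parameters(dense_cfg):,}"
)

train_idx, test_idx = pp.stratified_split(y, test_size=0.30, seed=0)
X_tr = pp.ExpressionMatrix(Xb.values[train_idx], Xb.gene_ids,
                           [Xb.cell_ids[i] for i in train_idx])
X_te = pp.ExpressionMatrix(Xb.values[test_idx], Xb.gene_ids,
                           [Xb.cell_ids[i] for i in test_idx])
y_tr, y_te = y.subset(train_idx), y.subset(test_idx)

Xp_tr, stats = pp.preprocess(X_tr, "zscore")  # fit on the training fold only
Xp_te, _ = pp.preprocess(X_te, "zscore", fit_stats=stats)

model = pp.build_network(net_cfg, mask)
pp.train(model, Xp_tr, y_tr, pp.TrainingConfig(epochs=100, batch_size=10, seed=0))
print(f"cross-entropy: epoch 1 {model.history[0]:.3f} -> epoch 100 {model.history[-1]:.4f}")

metrics = pp.supervised_metrics(y_te, pp.predict(model, Xp_te))
print(f"held-out accuracy {metrics.accuracy:.3f}, macro F1 {metrics.f1_macro:.3f}")
print(
    "masked first-layer weights still zero:",
    np.abs(model.weights[0][model.first_layer_mask == 0]).max() == 0.0,
)
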