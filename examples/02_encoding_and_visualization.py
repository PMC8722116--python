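"""Reuse a trained classifier as an unsupervised encoder.

After supervised training, detaching the output layer turns the network
into an encoder: the last hidden layer's activations are a low-dimensional
representation of each cell. Here we cluster that encoding with K-Means and
compare the clusters to the true cell types (six agreement scores), then
project the encoding to 2-D with PCA for plotting. High scores mean the
encoding separates cell types without ever being told the test labels.
"""

import pathprime as pp

cfg = pp.SyntheticConfig(n_cell_types=4, cells_per_type=80, seed=1)
X, y, collection, _ = pp.generate_dataset(cfg)
Xb, collb = pp.intersect_gene_space(X, collection)
mask = pp.build_mask(Xb.gene_ids, collb)

net_cfg = pp.NetworkConfig(
    input_genes=Xb.gene_ids,
    hidden_layers=[pp.LayerSpec(biological=True)],
    n_classes=y.n_classes,
    seed=1,
)
Xp, _ = pp.preprocess(Xb, "zscore")
model = pp.build_network(net_cfg, mask)
pp.train(model, Xp, y, pp.TrainingConfig(epochs=60, seed=1))

enc = pp.encode(model, Xp)
print(f"encoding: {enc.n_cells} cells x {enc.width} pathway dimensions")

clusters = pp.kmeans_cluster(enc, K=y.n_classes, seed=1)
scores = pp.clustering_metrics(y, clusters)
for name, value in scores.as_dict().items():
    print(f"  {name:16s} {value:.3f}")
print("(1.0 = clusters match the true cell types exactly)")

coords = pp.embed_2d(enc, method="pca")
print(f"2-D PCA coordinates ready for plotting: shape {coords.shape}")
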