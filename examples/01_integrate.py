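"""Integrate two simulated modalities and score the shared latent space.

Generates a two-modality dataset with three shared cell types and a batch
effect on modality y, runs the standard preprocessing, trains the coupled
VAE with UOT alignment for 2,000 iterations, and reports label-transfer and
mixing metrics on the latent means.
"""

import warnings

warnings.filterwarnings("ignore")

from otvae import SimConfig, TrainConfig, compute_report, embed, fit, preprocess_pair, simulate

adata_x, adata_y, truth = simulate(SimConfig(seed=0))
partition = preprocess_pair(adata_x, adata_y, min_genes_per_cell=1, min_cells_per_gene=1)

config = TrainConfig(max_iterations=2000, hidden_dims=(256, 64), patience=10_000, seed=0)
result = fit(partition, config)

z_x = embed(result.model, partition.common["x"])
z_y = embed(result.model, partition.common["y"])
report = compute_report(z_x, z_y, partition.cell_types["x"], partition.cell_types["y"],
                        batch_entropy_kwargs=dict(rng=0))

print(f"final total loss          {result.history['total'].iloc[-1]:.1f}")
print(f"label-transfer ARI        {report.ari:.3f}")
print(f"label-transfer macro F1   {report.f1:.3f}")
print(f"silhouette (0-1)          {report.silhouette_scaled:.3f}")
print(f"batch entropy (0-1)       {report.batch_entropy:.3f}")
print()
print("ARI/F1 near 1 mean cell types transfer across modalities almost "
      "perfectly; batch entropy near 1 means the two modalities are well "
      "mixed within shared cell types.")
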