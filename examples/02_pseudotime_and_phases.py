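"""Infer circular cell-cycle pseudotime and discretise it into phases.

A cyclic population (cell types + a sinusoidal cell-cycle program over a
latent phase) is integrated with a noisy copy of itself; the private
embedding of the trained network is read out as pseudotime and compared with
the generator's phase, then cut into three stages with a Gaussian mixture.
"""

import numpy as np

from ccan import (AlignedPair, DomainDataset, RunConfig, SimConfig,
                  call_phases, circular_correlation, generate_cyclic_base,
                  preprocess, pretrain, pseudotime)

sim = SimConfig(n_cells=400, n_genes=100, n_types=3, seed=0)
ds, truth = generate_cyclic_base(sim)
rng = np.random.default_rng(1)
noisy = DomainDataset(ds.matrix + rng.normal(0, 0.5, ds.matrix.shape),
                      [f"t_{c}" for c in ds.cell_ids], ds.gene_ids,
                      role="target")
pair = AlignedPair(preprocess(ds, scale=True), preprocess(noisy, scale=True))

cfg = RunConfig(encoder_dims=[64, 32], classifier_dims=[16], latent_dim=16,
                epochs=500, circular_warmup_fraction=0.6, seed=0)
state = pretrain(pair, cfg, epochs=500)

pt = pseudotime(state, pair.source)
cc = circular_correlation(pt.pseudotime, truth.phase_of_cell)
print(f"circular correlation with true phase: {abs(cc):.3f}")
# 1.0 means the inferred circle matches the generator's phase exactly up to
# rotation/reflection; uncorrelated angles would give ~0.

pt = call_phases(pt, seed=0)
for phase in ("G1", "S", "G2M"):
    n = int((pt.phase_call == phase).sum())
    print(f"phase {phase:<3}: {n:4d} cells")
print("component means on the circle:",
      np.round(pt.gmm_means, 2), "weights:", np.round(pt.gmm_weights, 2))
# phase names follow ascending component mean; biological identity of each
# stage must come from marker genes.
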