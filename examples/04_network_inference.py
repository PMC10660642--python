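"""Infer one cell-type/condition regulatory network by message passing over
motif, protein-interaction, and coexpression evidence."""

import warnings

import numpy as np

from grnrewire import synth
from grnrewire.grn import PandaConfig, coexpression_network, panda_infer
from grnrewire.preprocess import log_normalize

warnings.simplefilter("ignore")

truth0 = synth.default_truth(seed=4)
motif, ppi, regulon = synth.generate_priors(12, 80, 0.2, 0.3, seed=4)
adata = synth.simulate_counts(truth0, 150, seed=4)
log_normalize(adata)

ct, cond = truth0.cell_types[0], truth0.case
mask = ((adata.obs["cell_type"] == ct) & (adata.obs["condition"] == cond)).values
coexpr = coexpression_network(
    np.asarray(adata.layers["lognorm"])[mask], list(adata.var_names)
)
net = panda_infer(motif, ppi, coexpr, PandaConfig(alpha=0.1, tol=1e-5),
                  cell_type=ct, condition=cond)
print(f"network for ({ct}, {cond}): {len(net.tfs)} TFs x {len(net.genes)} genes")
print(f"converged: {net.converged} after {net.iterations_run} iterations")

edges = net.to_frame().sort_values("weight", ascending=False)
print("\nstrongest edges (positive weight = supported interaction):")
print(edges.head(5).to_string(index=False))
in_prior = motif.values[
    [net.tfs.index(t) for t in edges.head(5)["tf"]],
    [net.genes.index(g) for g in edges.head(5)["gene"]],
]
print(f"of which in the motif prior: {int(in_prior.sum())}/5")
# Edge weights are z-score-like: positive supports an interaction, negative
# counts against it. The co-evolved TF-TF layer is in net.ppi_out.
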