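"""Reading the mixture probability pi: which decoder path explains a gene.

For every cell and gene the model learns the probability pi that the
count is generated through the shared decoder path rather than the
private one.  On the simulation, genes of a group's own programs should
lean private (low pi) while the deeply sequenced cell-type genes lean
shared (high pi).

Run from the repository root:  python examples/04_mixing_parameter.py
"""

import numpy as np

import spvae
from spvae.interpret import mixing_parameter

bundle, truth = spvae.simulate_grouped_counts(
    spvae.SimulationConfig(n_cells_per_group=500, seed=2)
)
model, _ = spvae.train(
    bundle,
    spvae.EncoderConfig(d_shared=7, d_private=5),
    spvae.TrainingConfig(mode="supervised", epochs=120, seed=0),
)

group = 0
genes = bundle.groups[group].gene_names
# one cell-type gene and one program gene owned by this group
picks = [genes[100], genes[2100]]
pi = mixing_parameter(model, bundle, picks, group)
print(pi.describe().loc[["mean", "25%", "75%"]].round(3))

pi_all = model.mixing_parameters(bundle, group)
print(f"mean pi, cell-type block: {pi_all[:, :2000].mean():.3f}")
print(f"mean pi, own program block: {pi_all[:, 2000:2250].mean():.3f}")
print("(higher = routed through the shared path)")
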