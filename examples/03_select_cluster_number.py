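"""Scan the number of clusters K with entropy loss and log-likelihood.

On a small synthetic bundle, scores K in {2, 5, 8}: the entropy loss
measures the information the classifier's per-residue distributions carry
beyond the background, and the mixture log-likelihood how well K von Mises
components describe the held-out angles.  With 5 generative basins, K = 5
should sit at (or near) the plateau.
"""

from ramamix import network, selection, synthetic

proteins = synthetic.generate_protein_set(30, (40, 80), noise=0.4, seed=5)
train, val = synthetic.split_proteins(proteins, 0.75, seed=5)

arch = network.Architecture(n_blocks=1, n_filters=16, half_window=2)


def recipe(prots, cluster_model, seed):
    examples = network.examples_from_proteins(prots, cluster_model)
    return network.train(examples, cluster_model.K, arch=arch, epochs=6,
                         seed=seed, track_objective=False)


rows = selection.k_scan(train, val, [2, 5, 8], recipe, seed=0)
print("K   entropy_loss  loglik")
for r in rows:
    print(f"{r.K:<3d} {r.entropy_loss:12.3f}  {r.loglik:7.3f}")
print("plateau rule, epsilon=0.05:", selection.select_k(rows))
print("plateau rule, epsilon=0.02:", selection.select_k(rows, epsilon=0.02))
# The rule returns the smallest K whose entropy loss is within epsilon of
# the best; on a shallow curve a loose epsilon prefers fewer clusters,
# while a tighter one lands on the generative K = 5.
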