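"""Representational similarity analysis of pseudopopulation choice
representations: does rule adherence reorganize choice geometry?

The warping generator expands rule-relevant choice coding, compresses
rule-irrelevant coding, and suppresses identity (interaction) coding on
rule trials; the RSA contrasts should recover exactly that signature.
"""
from rulewarp import pseudopop, rsa, synth

trials, truth = synth.simulate_behavior(synth.AgentSpec(), n_blocks=40, seed=1)
spikes, _ = synth.simulate_neurons(trials, truth, synth.warping_tuning(), seed=2,
                                   with_presentation_epochs=False)

for scheme in ("rule_vs_residual", "color_vs_shape_rule"):
    matrix = pseudopop.build_pseudotrials(spikes, trials, truth.states,
                                          scheme, seed=5)
    centroids, labels = rsa.condition_centroids(matrix)
    rmat = rsa.distance_matrix(centroids, labels, scheme)
    print(f"\n=== scheme: {scheme} "
          f"({matrix.n_rows} pseudotrials, {matrix.values.shape[1]} neurons) ===")
    print(rsa.rsa_contrasts(rmat)
          .round(3)[["contrast", "context", "mean_a", "mean_b", "t", "p"]]
          .to_string(index=False))

print("\nNegative shared-vs-unshared differences under rule-based (but not")
print("residual) conditions show the categorical reorganization; within")
print("each rule domain, pairs differing only along the compressed")
print("irrelevant dimension sit closest.")
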