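"""Simulate DASS-21-like responses and estimate their symptom network.

Draws n = 318 respondents (the scale of a typical student survey) from a
known sparse partial-correlation truth, runs the estimation pipeline
(nonparanormal transform -> correlations -> EBIC graphical lasso) and
compares the recovered edges with the generating network.
"""

import symptomnet as sn

model = sn.make_truth(seed=1)
x = sn.sample_ordinal(model, n=318, seed=2)

z = sn.npn_transform(x)
r = sn.correlation_matrix(z)
net = sn.select_network(r)  # gamma defaults to 0.50

true_edges = int(model.edge_mask().sum() / 2)
print(f"true network: {true_edges} edges "
      f"(3 communities x 7 items, 2 bridges per community pair)")
print(f"estimated network: {net.n_edges} edges "
      f"at penalty lambda = {net.lam:.3f} (EBIC-selected)")

m = sn.recovery_metrics(model, net)
print(f"edge sensitivity  {m['sensitivity']:.2f}   "
      f"(share of true edges recovered)")
print(f"edge specificity  {m['specificity']:.2f}   "
      f"(share of absent pairs kept absent)")
print(f"strength rank corr {m['strength_rank_correlation']:.2f}   "
      f"(ordering of node importance preserved)")
# At n = 318 with weak edges (partial r ~ 0.15-0.25) the regularized
# estimate is conservative: high specificity, moderate sensitivity.
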