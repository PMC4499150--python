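"""Sign edges from expression correlation and evaluate prior recovery.

Signs each true edge by the regulator–target Pearson correlation (strict
|r| > 0.1 rule), then measures how strongly prior pairs are enriched in a
functional network as a function of their prior probability.
"""

import numpy as np

from loopnet import evaluation, priors, synthetic

truth = synthetic.generate_true_network(150, 25, 8.0, seed=11)
expr = synthetic.simulate_expression(truth, 400, 0.5, seed=12)
signed = evaluation.infer_edge_signs(truth.to_network(), expr, threshold=0.1)
m = signed.metadata
print(f"signed {len(signed.edges)} edges: {m['n_activation']} activation, "
      f"{m['n_inhibition']} inhibition, ratio {m['activation_inhibition_ratio']:.2f}")
print("-> activations outnumber inhibitions (the generator draws 60% positive signs).")

# prior recovery enrichment on a second instance
truth2 = synthetic.generate_true_network(30, 5, 3.0, seed=7)
landscape = synthetic.generate_landscape(truth2, decoy_binding_rate=0.5, seed=2)
table = priors.build_tf_priors(landscape)
functional = truth2.to_network()  # the true network stands in for a learned one
for r in evaluation.prior_recovery_enrichment(table, functional):
    print(f"  prior bin {r.label:12s} n={r.n_prior:3d} recovered={r.recovered_fraction:.2f} "
          f"odds ratio={r.odds_ratio:6.1f}")
print("-> true-edge support concentrates in strong evidence classes, so")
print("   high-probability priors are recovered far above chance.")
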