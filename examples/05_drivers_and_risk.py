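"""Driver discovery, driver-risk connectivity and risk-allele analysis.

Builds a tumor/normal cohort with a mutated driver TF and a risk allele
that amplifies one target's responsiveness, then runs the three
interpretation statistics: regulatory-driver discovery from recurrent
non-coding mutations, the driver→risk permutation test, and group-wise
misregulation concordance by risk-allele status.
"""

import networkx as nx

from loopnet import analysis, synthetic

truth = synthetic.generate_true_network(30, 5, 3.0, seed=7)
landscape = synthetic.generate_landscape(truth, decoy_binding_rate=0.3, seed=1)
network = truth.to_network()
driver = truth.regulators[0]
risk_gene = next(v for u, v in truth.edges if u == driver)

# 1) regulatory drivers from recurrent non-coding mutations
patients = [f"P{i:02d}" for i in range(21)]
mutations = synthetic.simulate_noncoding_mutations(
    landscape, patients, [driver], mutations_per_patient=5,
    driver_hit_fraction=0.7, seed=2,
)
drivers_df = analysis.identify_regulatory_drivers(
    network, mutations, landscape, n_sim=199, mode="insilico", seed=3
)
print("regulatory driver test (mutations concentrated on", driver, "sites):")
print(drivers_df.sort_values("p_value").to_string(index=False))

# 2) driver -> risk connectivity
downstream = set(nx.descendants(network.to_networkx(), driver))
risk_set = set(list(downstream)[:4]) or {risk_gene}
res = analysis.driver_risk_connectivity_test(network, {driver}, risk_set, n_perm=999, seed=4)
print(f"\ndriver->risk: {res.observed['driver_to_risk_edges']:.0f} direct edges, "
      f"{res.observed['risk_with_incoming_pct']:.0f}% of risk genes with incoming links "
      f"(p = {res.p_values['risk_with_incoming_pct']:.3f})")

# 3) risk-allele susceptibility
cohort = synthetic.simulate_cohort(truth, 170, [driver], {"rs1": risk_gene}, seed=5)
table, frac = analysis.risk_allele_susceptibility(cohort, [(driver, risk_gene, "rs1")])
row = table.iloc[0]
print(f"\nmisregulation concordance {driver}->{risk_gene}: "
      f"risk group |r|={row.risk_r:.2f}, non-risk |r|={row.nonrisk_r:.2f}")
print("-> the risk allele amplifies the target's responsiveness, so its")
print("   misregulation tracks the driver more closely in allele carriers.")
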