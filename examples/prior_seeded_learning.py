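"""Seed structure learning with a curated knowledge prior.

Two species' knowledge networks are intersected into an adirectional prior
(direction is always discarded before seeding); any feedback loops in
directed inputs are broken deterministically first. The prior seeds the Tabu
search's initial structure and contributes a soft -kappa penalty per
modelled edge absent from the prior skeleton, so data can overrule it.
"""
import cytobn as cb

# directed knowledge edges for each species (e.g. curated + text mining)
rat_knowledge = [
    ("MCP-1", "RANTES"), ("MCP-1", "KC"), ("IL-10", "IL-6"),
    ("TNF-alpha", "IL-10"), ("IL-10", "TNF-alpha"),  # feedback loop
]
mouse_knowledge = [("RANTES", "MCP-1"), ("KC", "MCP-1"), ("IL-6", "IL-10")]

rat_dag, removed = cb.remove_feedback_loops(rat_knowledge)
print("removed feedback edges:", removed)

prior = cb.intersect_networks(rat_dag, mouse_knowledge)
print("prior skeleton (undirected intersection):", prior.sorted_pairs())

model = cb.ground_truth_demo(seed=4)
panel = cb.generate_panel(model, 200, seed=4)
seeded = cb.run_pipeline(panel, prior=prior, config=cb.LearnConfig(kappa=1.0, seed=4))
unseeded = cb.run_pipeline(panel, config=cb.LearnConfig(seed=4))

print("\nseeded edges:  ", seeded.dag.edges())
print("unseeded edges:", unseeded.dag.edges())
print("\nWith informative data the two agree on well-supported edges; the")
print("penalty only tilts the score where the data are ambivalent (kappa=0")
print("recovers the uniform structure prior exactly).")
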