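# cytobn

Discrete Bayesian network inference for multiplex cytokine panels.

Cytokines act as networks — synergistic, antagonistic, redundant — yet
immunoassay studies usually report them one at a time. `cytobn` takes
per-subject multiplex panels (subjects × analytes, pg/ml; e.g. 24-plex
seminal-fluid and serum profiles from ~20 animals) and infers the
interrelationships between mediators as a directed acyclic graph, alongside
the classical per-analyte compartment statistics.

The pipeline:

1. **Panel statistics** — paired (or unpaired) per-analyte comparisons,
   routed by Shapiro–Wilk to a t-test or Wilcoxon signed-rank / Mann–Whitney,
   with Holm's step-down family-wise correction and significance tiers.
2. **Discretisation** — per-analyte z-scoring, then three equal-frequency
   relative-concentration bins (low / intermediate / high).
3. **Knowledge priors** — undirected intersection of two species' knowledge
   networks (direction discarded; feedback loops removed deterministically),
   used to seed the search and as a soft −κ penalty on non-prior edges.
4. **Structure learning** — BDeu score

       score(G) = Σ_i Σ_j [lnΓ(α_ij) − lnΓ(α_ij+N_ij)] + Σ_j Σ_k [lnΓ(α_ijk+N_ijk) − lnΓ(α_ijk)]

   (α_ijk = ESS/(q_i·r), r = 3 states, q_i = 3^|pa(i)|) optimised by Tabu
   search with seeded random restarts; exact enumeration oracle for ≤ 4 nodes.
5. **Bootstrap confidence** — 100 subject-resampling replicates; each edge
   of the point-estimate DAG carries its replicate fraction (directed and
   skeleton) and a grey/red tier at the 0.80 threshold.
6. **Reporting** — posterior-mean CPTs; node roles (parent/root, terminal,
   orphan, hub, internal); CPT-derived colours (high → green, low → red,
   intermediate → white, intensity ∝ modal probability); cross-species
   abridged re-learning; SIF/GraphML export for Cytoscape.

A synthetic-data module generates panels from known ground-truth DAGs
(ancestral sampling + lognormal emission, optionally calibrated to published
mean ± SEM tables), so every stage is testable for structure recovery
without raw assay data. See `docs/methods.md` for models, parameters and
limitations.

## Worked example

`examples/structure_recovery.py` samples panels from the fixed 8-node /
8-edge benchmark model, learns a network per seed with 100-replicate
bootstrap, and scores recovery:

```
ground truth: [('IFN-gamma', 'TNF-alpha'), ('IL-10', 'IFN-gamma'), ('IL-10', 'IL-6'),
               ('IL-12 (p70)', 'IL-10'), ('KC', 'TNF-alpha'), ('MCP-1', 'KC'),
               ('MCP-1', 'RANTES'), ('RANTES', 'KC')]
seed 0: skeleton F1 1.000; weakest true-edge confidence 1.00 vs strongest false 0.05
seed 1: skeleton F1 1.000; weakest true-edge confidence 1.00 vs strongest false 0.01
...
mean F1 1.000; positive margins mean every true edge outranks every false pair.
```

Skeleton F1 = 1.0 means the learned undirected structure matches the truth
exactly at n = 1000; the confidence margin line shows that every true edge's
bootstrap skeleton confidence exceeds that of every false pair, which is the
property the grey/red edge tiers rely on.

Other examples: `generate_synthetic_panel.py` (panel calibrated to published
rat seminal-fluid moments), `compare_compartments.py` (Holm-corrected
seminal vs serum table), `learn_network.py` (end-to-end run with topology,
colours and export), `prior_seeded_learning.py` (knowledge-prior seeding),
`abridged_cross_species.py` (shared-analyte re-learning).

A minimal end-to-end call:

```python
import cytobn as cb

panel = cb.read_panel("rat_seminal.csv", compartment="seminal_fluid", species="rat")
result = cb.run_pipeline(panel, config=cb.LearnConfig(seed=0))
print(result.consensus.edges)   # parent, child, confidence, skeleton_confidence, tier
print(result.topology)          # node, role, in_degree, out_degree
cb.write_result(result, "run1/net", format="sif")
```

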