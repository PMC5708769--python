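"""Cross-species comparison via abridged networks.

To compare rat and mouse networks fairly, analytes not measured in both
species are dropped and the whole pipeline is re-run from scratch on the
shared analyte set (the full network is never edited in place). Built-in
presets list each species' unshared analytes.
"""
import cytobn as cb
from cytobn.reference import (
    RAT_ABRIDGE_EXCLUSIONS,
    RAT_SEMINAL_FLUID,
)

spec = cb.PanelSpec(
    analytes=tuple(RAT_SEMINAL_FLUID), n_subjects=20,
    target_moments=RAT_SEMINAL_FLUID,
)
panel = cb.generate_panel(
    cb.calibrate_to_moments(spec, seed=9), 20, seed=9,
    compartment="seminal_fluid", species="rat",
)

cfg = cb.LearnConfig(n_bootstrap=25, seed=9)
full = cb.run_pipeline(panel, config=cfg)
abridged = cb.abridge_and_relearn(panel, RAT_ABRIDGE_EXCLUSIONS, config=cfg)

print("rat-only analytes dropped:", RAT_ABRIDGE_EXCLUSIONS)
print(f"full network: {len(full.dag.nodes)} nodes, {len(full.consensus.edges)} edges")
print(f"abridged:     {len(abridged.dag.nodes)} nodes, {len(abridged.consensus.edges)} edges")
print("\nabridged node roles:")
print(abridged.topology["role"].value_counts().to_string())
print("\nThe abridged run restarts discretisation, learning and bootstrap on")
print("the reduced panel, mirroring how cross-species networks are rebuilt.")
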