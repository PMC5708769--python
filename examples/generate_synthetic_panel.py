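"""Generate a synthetic 24-analyte rat seminal-fluid panel.

The generator is calibrated by moment matching to published per-analyte
mean +/- SEM values (pg/ml), so the simulated concentrations live on
realistic scales: heavy right tails, all-positive values, and an
always-undetectable VEGF column recorded as exact zeros.
"""
import cytobn as cb
from cytobn.reference import RAT_SEMINAL_FLUID

spec = cb.PanelSpec(
    analytes=tuple(RAT_SEMINAL_FLUID),
    n_subjects=20,
    compartment="seminal_fluid",
    species="rat",
    target_moments=RAT_SEMINAL_FLUID,
)
model = cb.calibrate_to_moments(spec, seed=1)
panel = cb.generate_panel(model, 20, seed=1, compartment="seminal_fluid", species="rat")

print(panel.values.iloc[:5, :5].round(2))
print()
for analyte in ("KC", "RANTES", "IL-6", "VEGF"):
    target = RAT_SEMINAL_FLUID[analyte][0]
    observed = panel.values[analyte].mean()
    print(f"{analyte:8s} target mean {target:8.2f}  sample mean {observed:8.2f} pg/ml")
# Sample means wobble around the published targets because n=20 per panel;
# at large n the generator matches the target mean by construction.
cb.write_panel(panel, "rat_seminal_synthetic.csv")
print("\nwrote rat_seminal_synthetic.csv (subjects x analytes, pg/ml)")
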