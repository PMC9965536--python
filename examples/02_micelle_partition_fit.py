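"""Estimate micelle:water partition constants from biorelevant solubility.

Two calibration media — a fasted-strength medium with oleic acid and
cholesterol (pH 6.5, 3 mM bile) and its fed-strength counterpart
(pH 4.8, 15 mM) — identify the two constants of the solubilization
model exactly.  The fitted partition then predicts luminal solubility
in every gut segment.
"""

from pbbm import (
    build_physiology,
    calibration_measurements,
    default_compound,
    fit_logkmw,
    predict_solubility_table,
    regional_luminal_solubility,
)

compound = default_compound()
measurements = calibration_measurements("oa_ch")
partition = fit_logkmw(measurements, compound)

print(f"logK_neutral = {partition.logk_neutral:.4f}")
print(f"logK_ion     = {partition.logk_ion:.4f}")
print(f"fit residual = {partition.fit_residual:.2e} (exact two-point fit)\n")

table = predict_solubility_table(
    partition,
    [m.medium for m in measurements],
    [m.mean_mg_per_ml for m in measurements],
    compound,
)
print(table.to_string(index=False), "\n")

for state in ("fasted", "fed"):
    phys = build_physiology(state)
    sol = regional_luminal_solubility(phys, partition, compound)
    print(f"{state:>6} duodenal solubility: {sol[1]:.3f} mg/mL")

print(
    "\nThe fed duodenum (15 mM bile) holds several-fold more dissolved "
    "drug than the fasted one (3 mM) — the solubility half of the "
    "positive food effect."
)
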