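"""Ampholyte speciation and pH-dependent aqueous solubility.

The modelled compound carries an acid-side pKa of 4.63 and a base-side
pKa of 8.65: it is cationic in the stomach, predominantly net-neutral
(zwitterionic) through the small intestine, and picks up anionic
character only above pH ~8.  Aqueous solubility follows the same
speciation — minimal near the midpoint of the two pKa, rising steeply
toward gastric pH.
"""

from pbbm import default_compound

compound = default_compound()

print(f"{compound.name}: pKa {compound.pKa1}/{compound.pKa2}, "
      f"S0 = {compound.intrinsic_solubility} mg/mL\n")
print(f"{'pH':>5} {'cation':>8} {'neutral':>8} {'anion':>8} {'S_aq mg/mL':>12}")
for ph in (1.8, 4.63, 5.8, 6.5, 6.64, 7.4, 8.65):
    ion = compound.ionization(ph)
    s_aq = compound.aqueous_solubility(ph)
    print(f"{ph:5.2f} {ion.f_cation:8.4f} {ion.f_neutral:8.4f} "
          f"{ion.f_anion:8.4f} {s_aq:12.3e}")

print(
    "\nAt gastric pH the cation dominates and aqueous solubility is about "
    "700x the intrinsic value; across the small intestine (pH 5.4-7.4) "
    "the drug is >85% net-neutral and essentially at its intrinsic "
    "solubility — which is why bile-micelle solubilization controls its "
    "luminal concentration."
)
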