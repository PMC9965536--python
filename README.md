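# pbbm — physiologically based biopharmaceutic modelling of a BCS IV zwitterion

`pbbm` is an open, tested pipeline for mechanistic oral-absorption and
food-effect prediction of a poorly soluble, poorly permeable (BCS class
IV) zwitterionic drug.  It is written for biopharmaceutics and DMPK
scientists who want the full chain — biorelevant solubility → micelle
partition estimation → particle dissolution → gastrointestinal transit
and permeability → hepatic clearance → plasma pharmacokinetics →
verification statistics — as inspectable Python rather than a closed
commercial platform.

## The model

**Speciation and solubility.** The drug is a three-pool
Henderson–Hasselbalch ampholyte (cation ⇌ neutral ⇌ anion, pKa 4.63 /
8.65) with aqueous solubility
`S_aq(pH) = S0 · (1 + 10^(pKa1−pH) + 10^(pH−pKa2))`.
Bile-micelle solubilization is a species-weighted linear
solubilization-capacity model,

    S_total(pH, C_BS) = S_aq(pH) + S0 · (f_n·10^logK_n + f_ion·10^logK_ion) · C_BS · v_w

with `C_BS` the total bile-salt concentration, `v_w = 0.018` L/mol, and
two log10 micelle:water partition constants fitted to equilibrium
solubilities in a fasted/fed pair of biorelevant media (an exact
two-point solve).  The free dissolved fraction is `fu = S_aq/S_total`.

**Dissolution.** The measured particle-size quantiles (D10/D50/D90 =
3.2/8.1/23.1 µm) are fitted to a volume-weighted lognormal and cut into
equal-volume bins (population balance, 50 bins by default).  Each bin
follows the Nernst–Brunner diffusion-layer rate
`dr/dt = −D_eff (Cs − Cb) / (ρ h_eff)` with the Hintz–Johnson boundary
layer `h_eff = min(r, 30 µm)`; first-order supersaturation
precipitation is configured but inert at the study's critical
supersaturation ratio of 1000.

**Absorption.** Nine well-stirred segments (stomach → duodenum →
jejunum I/II → ileum I–IV → colon) with static fed/fasted pH, bile,
volumes and first-order transit.  Regional permeability combines the
LogP-derived intrinsic transcellular permeability
`P_trans,0 = a·(10^LogP)^b`, a paracellular fraction, and an
unstirred-boundary-layer resistance whose diffusivity mixes free and
micelle-bound drug; the published regional Peff values are applied with
a micelle-binding UBL correction, and the colon carries a 0.001
absorption scalar.  The permeation driving force is the total dissolved
concentration (the configuration supported by the MDCK data).

**Disposition.** Recombinant CYP3A4/UGT1A4/UGT2B7, additional
microsomal and biliary intrinsic clearances are scaled through enzyme
abundance, MPPGL, hepatocellularity and liver mass, then through the
well-stirred liver model; systemic kinetics are one-compartment
(V = Vss·BW) with hepatic first pass `(1 − E_H)` on oral input.

**Verification.** Noncompartmental metrics (linear-up/log-down AUC,
best-adjusted-R² terminal slope), Wagner–Nelson and impulse-response
deconvolution, geometric summaries, predicted/observed ratio tables,
fold-error fractions and the average absolute fold error
`AAFE = 10^mean(|log10(pred/obs)|)`.

Every input the analysis needs (compound parameters, media recipes,
observed solubilities, MDCK permeabilities, IV and oral PK tables) is
packaged as checksummed plain-text fixtures; seeded generators provide
synthetic solubility datasets, plasma profiles and virtual populations
for testing.

## Worked example

Running `python examples/04_food_effect_simulation.py` (fed vs fasted
200 mg immediate-release tablet) prints:

```
fasted: fa = 0.073, Cmax = 0.45 µg/mL, AUC(0-inf) = 12.2 µg·h/mL, Tmax = 6.0 h
   fed: fa = 0.254, Cmax = 1.48 µg/mL, AUC(0-inf) = 42.1 µg·h/mL, Tmax = 7.5 h

fed/fasted Cmax ratio = 3.28, AUC ratio = 3.46
```

Fasted absorption is solubility-limited (7% of the dose absorbed; the
fraction falls further with dose), while fed-state bile micelles lift
the luminal solubility ceiling (25% absorbed, flat in dose) — a
positive food effect of ~3–3.5-fold, matching the direction and
magnitude of the observed geometric means (1.43 fed vs 0.35 µg/mL
fasted).  The same workflow is available from the shell:

```bash
pbbm run --config examples/demo_config.yaml --out pbbm_out --seed 1
pbbm fit-solubility          # partition constants + prediction table
pbbm simulate --dose 200 --state fed
pbbm report                  # AAFE and fold-error statistics
```

The other examples cover speciation (`01`), partition fitting (`02`),
dissolution oracles (`03`), clearance scale-up and the IV microdose
(`05`), verification statistics (`06`) and synthetic-data recovery
(`07`).

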