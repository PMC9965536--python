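"""Synthetic-data generators and parameter recovery.

Seeded generators emulate the statistical structure of the study's raw
data: triplicate solubilities with multiplicative lognormal noise,
plasma profiles with lognormal residuals, and a lognormal virtual
population.  Refitting the partition from noisy synthetic solubilities
checks that the estimation step is unbiased at bench-realistic noise.
"""

import numpy as np

from pbbm import (
    GeneratorSpec,
    MicellePartition,
    default_assay_media,
    default_compound,
    fit_logkmw,
    gen_solubility_dataset,
    gen_virtual_population,
    geometric_stats,
)

compound = default_compound()
true = MicellePartition(0.5, 4.2)

errors = []
for seed in range(50):
    data = gen_solubility_dataset(
        true, default_assay_media(), GeneratorSpec(seed=seed, cv=10.0), compound
    )
    fit = fit_logkmw(data, compound)
    errors.append(fit.logk_ion - true.logk_ion)
errors = np.array(errors)
print(f"logK_ion recovery over 50 seeded datasets (10% CV, n=3):")
print(f"  bias = {errors.mean():+.4f}, RMSE = {np.sqrt((errors**2).mean()):.4f}")

pop = gen_virtual_population({"CL_L_h": 1.04, "Vss_L_kg": 0.36},
                             {"CL_L_h": 40.0, "Vss_L_kg": 17.0}, 5000, seed=1)
gm, cv = geometric_stats([s["CL_L_h"] for s in pop])
print(f"\nvirtual population (n=5000): CL geometric mean {gm:.2f} L/h, "
      f"geometric CV {cv:.1f}% (target 40%)")
print(
    "\nThe ionized-species partition constant — the parameter the food "
    "effect hinges on — is recovered essentially without bias at "
    "bench-level noise."
)
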