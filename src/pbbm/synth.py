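"""Seeded synthetic-data generators.

The study's raw bench and clinical data are not deposited; these
generators produce inputs with the statistical structure the analysis
assumes, so every pipeline stage is testable end to end:

* triplicate biorelevant solubility measurements with multiplicative
  lognormal noise around a known true micelle partition;
* plasma concentration-time profiles from known disposition/input
  parameters with lognormal residuals;
* virtual populations with lognormal inter-individual variability on
  selected parameters.

Noise is multiplicative lognormal throughout (concentrations are
positive and the published summary tables report geometric CVs); the
noise factor has median 1 and log-sd ``sqrt(ln(1 + cv^2))``.  All
randomness flows through one ``numpy`` generator seeded from
``GeneratorSpec.seed``: a fixed seed reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .disposition import DispositionParams, plasma_clearance
from .micelle import (
    MediumComposition,
    MicellePartition,
    SolubilityMeasurement,
    total_solubility,
)
from .physchem import CompoundRecord
from .pk import ConcentrationProfile

__all__ = [
    "GeneratorSpec",
    "gen_solubility_dataset",
    "gen_plasma_profiles",
    "gen_virtual_population",
    "default_assay_media",
]


@dataclass
class GeneratorSpec:
    """Seeded noise specification for the generators."""

    seed: int
    noise_model: str = "multiplicative-lognormal"
    cv: float = 10.0  # percent
    n_replicates: int = 3
    true_parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_model != "multiplicative-lognormal":
            raise ValueError("only multiplicative-lognormal noise is supported")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")

    @property
    def log_sd(self) -> float:
        return math.sqrt(math.log(1.0 + (self.cv / 100.0) ** 2))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_assay_media() -> list[MediumComposition]:
    """A six-medium solubility assay design spanning pH and bile level.

    Mirrors the published bench design: fasted-strength (3 mM) and
    fed-strength (15 mM) media at low, mid and high intestinal pH, which
    makes both partition constants identifiable from one dataset.
    """
    grid = [
        ("fasted_pH6.5", 6.5, 3.0, "fasted"),
        ("fasted_pH5.8", 5.8, 3.0, "fasted"),
        ("fasted_pH5.0", 5.0, 3.0, "fasted"),
        ("fed_pH4.8", 4.8, 15.0, "fed"),
        ("fed_pH5.8", 5.8, 15.0, "fed"),
        ("fed_pH6.5", 6.5, 15.0, "fed"),
    ]
    return [
        MediumComposition(label=lab, pH=ph, total_bile_salt=bs, prandial_state=st)
        for lab, ph, bs, st in grid
    ]


def gen_solubility_dataset(
    true_partition: MicellePartition,
    media: Sequence[MediumComposition],
    spec: GeneratorSpec,
    compound: CompoundRecord,
) -> list[SolubilityMeasurement]:
    """Replicate solubility measurements from a known true partition.

    Each replicate is the model solubility in the medium times an i.i.d.
    lognormal factor (median 1, CV per ``spec``), reported in µg/mL.
    """
    if len(media) == 0:
        raise ValueError("media must be non-empty")
    rng = spec.rng()
    out = []
    for medium in media:
        s_true = total_solubility(
            medium.pH, medium.bile_molar, true_partition, compound
        )
        noise = np.exp(rng.normal(0.0, spec.log_sd, size=spec.n_replicates))
        out.append(
            SolubilityMeasurement(
                medium=medium, replicates=list(s_true * 1000.0 * noise)
            )
        )
    return out


def gen_plasma_profiles(
    params: DispositionParams,
    input_spec: dict,
    spec: GeneratorSpec,
    n_profiles: int = 1,
    t_end_h: float = 72.0,
    dt_h: float = 0.25,
) -> list[ConcentrationProfile]:
    """Noisy plasma profiles from a first-order absorption model.

    ``input_spec`` carries ``dose_mg``, ``ka_per_h`` and optionally
    ``f_abs`` (absorbed fraction reaching the systemic circulation,
    default 1).  The noiseless curve is the Bateman solution of the
    one-compartment model with the package's clearance scale-up; each
    profile multiplies it by independent lognormal residuals.  A zero
    dose yields all-zero profiles.
    """
    dose = float(input_spec["dose_mg"])
    ka = float(input_spec["ka_per_h"])
    f_abs = float(input_spec.get("f_abs", 1.0))
    cl, _ = plasma_clearance(params)
    v = params.volume_l
    kel = cl / v
    rng = spec.rng()
    times = np.arange(0.0, t_end_h + dt_h / 2, dt_h)
    if abs(ka - kel) < 1e-9:
        ka *= 1.0 + 1e-6  # avoid the degenerate Bateman denominator
    base = (
        dose * f_abs * ka / (v * (ka - kel))
        * (np.exp(-kel * times) - np.exp(-ka * times))
    ) * 1000.0  # mg/L -> ng/mL
    base = np.maximum(base, 0.0)
    profiles = []
    for i in range(n_profiles):
        noise = np.exp(rng.normal(0.0, spec.log_sd, size=times.shape))
        conc = base * noise if dose > 0 else np.zeros_like(base)
        profiles.append(
            ConcentrationProfile(times, conc, dose, f"synthetic_{i}")
        )
    return profiles


def gen_virtual_population(
    base_params: dict,
    cv_map: dict,
    n: int,
    seed: int,
) -> list[dict]:
    """Lognormal virtual population over named scalar parameters.

    ``base_params`` maps parameter names to their population-typical
    values, ``cv_map`` names the subset to perturb with a geometric CV
    (percent).  Unknown names in ``cv_map`` raise.  The geometric mean of
    each sampled parameter converges to its base value as ``n`` grows.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    unknown = set(cv_map) - set(base_params)
    if unknown:
        raise KeyError(f"cv_map names unknown parameters: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n):
        subject = dict(base_params)
        for name, cv in cv_map.items():
            sd = math.sqrt(math.log(1.0 + (cv / 100.0) ** 2))
            subject[name] = base_params[name] * math.exp(rng.normal(0.0, sd))
        subjects.append(subject)
    return subjects
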