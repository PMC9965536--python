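"""Ampholyte speciation, pH-dependent solubility and permeability correlations.

The compound modelled throughout this package is a large, lipophilic
ampholyte (zwitterion): it carries an acid-side macro-constant ``pKa1``
(cation ⇌ net-neutral) and a base-side macro-constant ``pKa2``
(net-neutral ⇌ anion).  Between the two pKa values the molecule is
predominantly net-neutral (the zwitterion and the uncharged tautomer are
lumped into a single neutral pool); below pKa1 the cation grows in, above
pKa2 the anion.  Three-pool Henderson-Hasselbalch macro-speciation is used
deliberately: microspecies resolution adds parameters that the available
data cannot identify.

Two permeability-facing correlations live here as well:

* the power-law relation between the octanol:water partition coefficient
  and the intrinsic transcellular permeability of the neutral species,
  ``P_trans,0 = a * (P_O:W)**b``; and
* an Avdeef-type molecular-weight correlation for the free aqueous
  diffusion coefficient, ``D = 9.9e-5 * MW**-0.453`` (cm^2/s), used by the
  unstirred-boundary-layer resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "CompoundRecord",
    "IonizationState",
    "species_fractions",
    "aqueous_solubility",
    "ptrans0_from_logp",
    "diffusion_coefficient_free",
    "PTRANS0_A_DEFAULT",
    "PTRANS0_B_DEFAULT",
    "PTRANS0_A_SUGANO",
    "PTRANS0_B_SUGANO",
]

#: Default coefficients of the LogP -> P_trans,0 power law (cm/s and
#: dimensionless exponent).  The alternative (Sugano) coefficient set is
#: provided for sensitivity work; it produces permeabilities orders of
#: magnitude higher for lipophilic compounds.
PTRANS0_A_DEFAULT = 24.172e-6
PTRANS0_B_DEFAULT = 0.415
PTRANS0_A_SUGANO = 2.36e-6
PTRANS0_B_SUGANO = 1.1


@dataclass(frozen=True)
class IonizationState:
    """Macro-species fractions of an ampholyte at a given pH.

    ``f_neutral`` is the net-neutral pool (zwitterion plus uncharged
    tautomer).  The three fractions sum to one.
    """

    f_cation: float
    f_neutral: float
    f_anion: float

    @property
    def f_ionized(self) -> float:
        """Total ionized fraction (cation + anion)."""
        return self.f_cation + self.f_anion


@dataclass
class CompoundRecord:
    """Physicochemical identity of the modelled compound.

    Parameters
    ----------
    mol_weight : float
        Molecular weight, g/mol.
    logP : float
        log10 octanol:water partition coefficient.
    pKa1, pKa2 : float
        Acid-side (cation ⇌ neutral) and base-side (neutral ⇌ anion)
        macro-constants; ``pKa1 < pKa2`` is required.
    intrinsic_solubility : float
        Aqueous solubility of the neutral species, mg/mL.
    fu_plasma : float
        Fraction unbound in plasma.
    blood_plasma_ratio : float
        Whole-blood to plasma concentration ratio.
    fu_gut : float, optional
        Fraction unbound in the gut wall.  Carried for completeness; the
        model assigns all metabolism hepatically, so it is unused.
    diffusion_coeff_free : float, optional
        Free aqueous diffusion coefficient, cm^2/s.  Derived from the
        molecular weight when absent.
    diffusion_coeff_micelle : float
        Diffusion coefficient of micelle-bound drug, cm^2/s.  Default
        1.0e-6 is typical mixed-micelle hydrodynamics.
    """

    name: str
    mol_weight: float
    logP: float
    pKa1: float
    pKa2: float
    intrinsic_solubility: float
    fu_plasma: float
    blood_plasma_ratio: float
    fu_gut: Optional[float] = None
    diffusion_coeff_free: Optional[float] = None
    diffusion_coeff_micelle: float = 1.0e-6

    def __post_init__(self) -> None:
        if not self.mol_weight > 0:
            raise ValueError("mol_weight must be positive")
        if not 0 < self.pKa1 < self.pKa2:
            raise ValueError("require 0 < pKa1 < pKa2")
        if not self.intrinsic_solubility > 0:
            raise ValueError("intrinsic_solubility must be positive")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must be in (0, 1]")
        if self.diffusion_coeff_free is None:
            self.diffusion_coeff_free = diffusion_coefficient_free(self.mol_weight)

    @classmethod
    def from_dict(cls, block: dict) -> "CompoundRecord":
        """Build a record from a structured-text config block.

        Keys mirror the tabulated input-parameter labels: ``name``,
        ``mol_weight``, ``logP``, ``pKa1``, ``pKa2``,
        ``intrinsic_solubility`` (or ``solubility``), ``fu`` (or
        ``fu_plasma``), ``b_p`` (or ``blood_plasma_ratio``), ``fu_gut``.
        """
        aliases = {
            "solubility": "intrinsic_solubility",
            "fu": "fu_plasma",
            "b_p": "blood_plasma_ratio",
            "log_p": "logP",
            "logp": "logP",
            "pka1": "pKa1",
            "pka2": "pKa2",
        }
        kwargs = {}
        for key, value in block.items():
            k = aliases.get(str(key).lower(), key)
            kwargs[k] = value
        return cls(**kwargs)

    def ionization(self, pH: float) -> IonizationState:
        return species_fractions(pH, self.pKa1, self.pKa2)

    def aqueous_solubility(self, pH: float) -> float:
        return aqueous_solubility(pH, self.intrinsic_solubility, self.pKa1, self.pKa2)


def species_fractions(pH: float, pKa1: float, pKa2: float) -> IonizationState:
    """Henderson-Hasselbalch macro-species fractions at ``pH``.

    Relative abundances are cation ∝ 10^(pKa1-pH), neutral ∝ 1 and anion
    ∝ 10^(pH-pKa2); the returned fractions are normalized to sum to one.
    """
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    r_cat = 10.0 ** (pKa1 - pH)
    r_an = 10.0 ** (pH - pKa2)
    denom = 1.0 + r_cat + r_an
    return IonizationState(
        f_cation=r_cat / denom, f_neutral=1.0 / denom, f_anion=r_an / denom
    )


def aqueous_solubility(pH: float, s0: float, pKa1: float, pKa2: float) -> float:
    """Total aqueous (micelle-free) solubility of the ampholyte, mg/mL.

    At saturation the neutral species is pinned at its intrinsic
    solubility ``s0`` and the ionized species add on top of it:
    ``S_aq = s0 * (1 + 10^(pKa1-pH) + 10^(pH-pKa2))``, hence ``S_aq >= s0``
    with the minimum near the midpoint between the two pKa.
    """
    if not s0 > 0:
        raise ValueError("intrinsic solubility must be positive")
    return s0 * (1.0 + 10.0 ** (pKa1 - pH) + 10.0 ** (pH - pKa2))


def ptrans0_from_logp(
    logP: float, a: float = PTRANS0_A_DEFAULT, b: float = PTRANS0_B_DEFAULT
) -> float:
    """Intrinsic transcellular permeability (cm/s) from LogP.

    ``P_trans,0 = a * (10^logP)**b`` — the built-in lipophilicity
    correlation of mechanistic permeability models.  Strictly increasing
    in ``logP`` for ``b > 0``.
    """
    if not a > 0:
        raise ValueError("coefficient a must be positive")
    if not (math.isfinite(logP) and math.isfinite(b)):
        raise ValueError("logP and b must be finite")
    return a * (10.0 ** logP) ** b


def diffusion_coefficient_free(mol_weight: float) -> float:
    """Free aqueous diffusion coefficient, cm^2/s, from molecular weight.

    Avdeef-type correlation ``D = 9.9e-5 * MW**-0.453``; monotonically
    decreasing in MW.
    """
    if not mol_weight > 0:
        raise ValueError("mol_weight must be positive")
    return 9.9e-5 * mol_weight ** (-0.453)
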