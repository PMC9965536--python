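"""Bile-micelle solubilization and micelle:water partition estimation.

Biorelevant media (FaSSIF/FeSSIF families, optionally enriched with oleic
acid and cholesterol) solubilize poorly soluble drugs in mixed bile-salt /
phospholipid micelles.  The model here is a species-weighted, linear
solubilization-capacity form:

    S_total(pH, C_BS) = S_aq(pH)
                      + S0 * (f_n(pH) * 10**logK_n + f_ion(pH) * 10**logK_ion)
                           * C_BS * v_w

where ``S_aq`` is the micelle-free aqueous solubility, ``S0`` the
intrinsic (neutral-species) solubility, ``f_n``/``f_ion`` the
Henderson-Hasselbalch neutral and ionized fractions, ``C_BS`` the total
bile-salt concentration (mol/L) and ``v_w = 0.018`` L/mol the molar volume
scale of the micellar pseudophase.  The micellar term is referenced to the
intrinsic concentration ``S0``: at saturation the aqueous neutral species
sits at ``S0`` regardless of pH, so the uptake per bile salt depends on pH
only through the speciation weights.  The term is linear in ``C_BS``,
reduces to ``S_aq`` when no micelles are present, and obeys the identity
``S_total * fu_dissolved = S_aq`` with the free dissolved fraction defined
below.

Two dimensionless log10 partition constants are estimated from measured
equilibrium solubilities in at least two media of distinct (pH, C_BS):
``logK_n`` for the neutral pool and a single ``logK_ion`` shared by cation
and anion.  With exactly two informative media the two-parameter fit is an
exact 2x2 linear solve; with more media a bounded nonlinear least-squares
fit in log-solubility space is used, which weights fasted and fed media
evenly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .physchem import CompoundRecord, species_fractions

__all__ = [
    "V_W",
    "MediumComposition",
    "SolubilityMeasurement",
    "MicellePartition",
    "total_solubility",
    "fraction_unbound_dissolved",
    "fit_logkmw",
    "predict_solubility_table",
    "regional_luminal_solubility",
    "InfeasibleSolubilityWarning",
]

#: Molar volume scale of the micellar pseudophase, L/mol bile salt.
V_W = 0.018

#: Lower floor for fitted log10 partition constants (effectively "no
#: partitioning" on the scale of physiological bile concentrations).
LOGK_FLOOR = -6.0
LOGK_CEIL = 12.0


class InfeasibleSolubilityWarning(UserWarning):
    """Observed solubility at or below the aqueous value: the micellar
    term carries no information and the fit is floored."""


@dataclass
class MediumComposition:
    """Recipe of a biorelevant medium.

    ``bile_salt_fractions`` maps bile-salt identities (TC, TCDC, GC, GDC)
    to percentages summing to 100; it is carried as metadata — the
    solubilization model depends only on the total bile-salt concentration,
    pH and the measured solubilities (bile-salt mixture identity was found
    immaterial experimentally).  Oleic acid (OA), cholesterol (CH) and
    phospholipid (PC) likewise enter only through the measurements made in
    their presence.
    """

    label: str
    pH: float
    total_bile_salt: float  # mM
    bile_salt_fractions: Optional[dict] = None  # {name: percent}
    PC: float = 0.0  # mM
    OA: float = 0.0  # mg/mL
    CH: float = 0.0  # mg/mL
    prandial_state: str = "fasted"

    def __post_init__(self) -> None:
        if self.total_bile_salt < 0:
            raise ValueError("total_bile_salt must be non-negative")
        if not 1.0 <= self.pH <= 10.0:
            raise ValueError("medium pH out of the supported range [1, 10]")
        if self.prandial_state not in ("fasted", "fed"):
            raise ValueError("prandial_state must be 'fasted' or 'fed'")
        if self.bile_salt_fractions:
            total = sum(self.bile_salt_fractions.values())
            if abs(total - 100.0) > 0.5:
                raise ValueError(
                    f"bile_salt_fractions sum to {total}, expected 100%"
                )

    @property
    def bile_molar(self) -> float:
        """Total bile salt in mol/L."""
        return self.total_bile_salt * 1e-3


@dataclass
class SolubilityMeasurement:
    """Replicate equilibrium solubility results in one medium.

    Replicates are in µg/mL (the bench unit); model-facing conversions to
    mg/mL happen inside the fitting routines.
    """

    medium: MediumComposition
    replicates: Sequence[float]  # µg/mL
    timepoint: float = 24.0  # h
    measured_pH: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.replicates) == 0:
            raise ValueError("replicates must be non-empty")
        if any(r <= 0 for r in self.replicates):
            raise ValueError("replicate solubilities must be positive")

    @property
    def pH(self) -> float:
        return self.measured_pH if self.measured_pH is not None else self.medium.pH

    @property
    def mean_mg_per_ml(self) -> float:
        """Arithmetic mean of the replicates, converted to mg/mL."""
        return float(np.mean(self.replicates)) * 1e-3


@dataclass
class MicellePartition:
    """Fitted micelle:water log10 partition constants.

    ``logk_ion`` is a single value applied identically to cation and
    anion; whether the two ionized species should differ is an open
    scientific question, but the data available (two calibration media)
    cannot identify separate values.
    """

    logk_neutral: float
    logk_ion: float
    source_media: Sequence[str] = field(default_factory=list)
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.logk_neutral) and np.isfinite(self.logk_ion)):
            raise ValueError("partition constants must be finite")


def _capacity(pH: float, partition: MicellePartition, compound: CompoundRecord) -> float:
    """Species-weighted solubilization capacity f_n*K_n + f_ion*K_ion."""
    ion = species_fractions(pH, compound.pKa1, compound.pKa2)
    return (
        ion.f_neutral * 10.0 ** partition.logk_neutral
        + ion.f_ionized * 10.0 ** partition.logk_ion
    )


def total_solubility(
    pH: float,
    c_bs: float,
    partition: MicellePartition,
    compound: CompoundRecord,
    v_w: float = V_W,
) -> float:
    """Total (aqueous + micellar) solubility, mg/mL.

    Parameters
    ----------
    pH : float
        Bulk pH of the medium or luminal segment.
    c_bs : float
        Total bile-salt concentration, mol/L.
    """
    if c_bs < 0:
        raise ValueError("bile salt concentration must be non-negative")
    s_aq = compound.aqueous_solubility(pH)
    s0 = compound.intrinsic_solubility
    return s_aq + s0 * _capacity(pH, partition, compound) * c_bs * v_w


def fraction_unbound_dissolved(
    pH: float,
    c_bs: float,
    partition: MicellePartition,
    compound: CompoundRecord,
    v_w: float = V_W,
) -> float:
    """Free (micelle-unbound) fraction of dissolved drug, in (0, 1].

    Defined as ``S_aq / S_total`` under the solubilization model, i.e. the
    bound:free ratio of dissolved drug equals the micellar:aqueous ratio
    at saturation.  Equals 1 with no micellar phase and decreases
    monotonically with bile-salt concentration.
    """
    if c_bs < 0:
        raise ValueError("bile salt concentration must be non-negative")
    ion = species_fractions(pH, compound.pKa1, compound.pKa2)
    # S0 / S_aq = f_neutral, so the bound:free ratio is
    # f_n * capacity * C_BS * v_w.
    bound_over_free = ion.f_neutral * _capacity(pH, partition, compound) * c_bs * v_w
    return 1.0 / (1.0 + bound_over_free)


def _design_row(pH: float, compound: CompoundRecord) -> tuple[float, float]:
    ion = species_fractions(pH, compound.pKa1, compound.pKa2)
    return ion.f_neutral, ion.f_ionized


def fit_logkmw(
    measurements: Sequence[SolubilityMeasurement],
    compound: CompoundRecord,
    logk_floor: float = LOGK_FLOOR,
    v_w: float = V_W,
) -> MicellePartition:
    """Estimate (logK_neutral, logK_ion) from solubility measurements.

    Replicates are averaged arithmetically per medium, then the two
    constants are fitted by least squares on log10 solubility.  With
    exactly two media of distinct (pH, C_BS) the fit is the exact linear
    solve of the two saturation equations (residual ~ 0) whenever that
    solution is feasible (both constants positive); otherwise, and for
    more than two media, a bounded nonlinear least-squares fit is used.

    Raises
    ------
    ValueError
        If fewer than two measurements are supplied or all media share an
        identical (pH, C_BS) pair (the two constants are then degenerate).

    Warns
    -----
    InfeasibleSolubilityWarning
        When a medium's observed solubility does not exceed the aqueous
        solubility at its pH; such media carry no micellar information.
    """
    if len(measurements) < 2:
        raise ValueError(
            "at least two media are required to identify (logK_neutral, logK_ion)"
        )
    keys = {(round(m.pH, 6), round(m.medium.bile_molar, 9)) for m in measurements}
    if len(keys) < 2:
        raise ValueError(
            "all media share the same (pH, bile) condition: the two "
            "partition constants are not identifiable"
        )

    s0 = compound.intrinsic_solubility
    rows, rhs, obs, labels, cond = [], [], [], [], []
    informative = 0
    for m in measurements:
        s_obs = m.mean_mg_per_ml
        s_aq = compound.aqueous_solubility(m.pH)
        c = m.medium.bile_molar
        fn, fi = _design_row(m.pH, compound)
        labels.append(m.medium.label)
        obs.append(s_obs)
        cond.append((m.pH, c))
        if s_obs <= s_aq or c == 0:
            warnings.warn(
                f"medium '{m.medium.label}': observed solubility "
                f"{s_obs:.3g} mg/mL does not exceed the aqueous value "
                f"{s_aq:.3g} mg/mL; no micellar information",
                InfeasibleSolubilityWarning,
            )
            continue
        rows.append([fn, fi])
        rhs.append((s_obs - s_aq) / (s0 * c * v_w))
        informative += 1

    if informative == 0:
        # Nothing above the aqueous line: floor both constants.
        part = MicellePartition(logk_floor, logk_floor, labels, np.inf)
        return part

    def residuals(x: np.ndarray) -> np.ndarray:
        part = MicellePartition(x[0], x[1])
        pred = [
            total_solubility(pH, c, part, compound, v_w=v_w) for (pH, c) in cond
        ]
        return np.log10(pred) - np.log10(obs)

    x0 = None
    if informative == 2 and len(rows) == 2:
        # Exact two-point solve (2 parameters, 2 saturation equations).
        sol = np.linalg.solve(np.asarray(rows), np.asarray(rhs))
        if np.all(sol > 0):
            x = np.log10(sol)
            part = MicellePartition(
                float(x[0]), float(x[1]), labels,
                float(np.sqrt(np.mean(residuals(x) ** 2))),
            )
            return part
        x0 = np.log10(np.clip(sol, 1e-6, None))

    if x0 is None:
        # Start from the pure-neutral capacity of the most enhanced medium.
        x0 = np.array([np.log10(max(np.max(rhs), 1e-6)), 3.0])
    fit = least_squares(
        residuals,
        np.clip(x0, logk_floor, LOGK_CEIL),
        bounds=(logk_floor, LOGK_CEIL),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    return MicellePartition(
        float(fit.x[0]),
        float(fit.x[1]),
        labels,
        float(np.sqrt(np.mean(fit.fun ** 2))),
    )


def predict_solubility_table(
    partition: MicellePartition,
    media: Sequence[MediumComposition],
    observed: Sequence[float],
    compound: CompoundRecord,
) -> pd.DataFrame:
    """Observed vs predicted solubility comparison table.

    ``observed`` is in mg/mL, aligned with ``media``.  The returned frame
    carries raw predictions and ratios; ``ratio_2dp`` is the ratio rounded
    to two decimals for report rendering.
    """
    if len(media) != len(observed):
        raise ValueError("media and observed must have equal length")
    rows = []
    for medium, s_obs in zip(media, observed):
        pred = total_solubility(medium.pH, medium.bile_molar, partition, compound)
        ratio = pred / s_obs
        rows.append(
            {
                "label": medium.label,
                "observed_mg_mL": s_obs,
                "predicted_mg_mL": pred,
                "ratio_pred_obs": ratio,
                "ratio_2dp": round(ratio, 2),
            }
        )
    return pd.DataFrame(rows)


def regional_luminal_solubility(
    physiology: Sequence,
    partition: MicellePartition,
    compound: CompoundRecord,
) -> np.ndarray:
    """Total solubility (mg/mL) in each gastrointestinal segment.

    ``physiology`` is a sequence of segment records carrying ``luminal_pH``
    and ``bile_salt_mM`` attributes (see :mod:`pbbm.absorption`).
    """
    if len(physiology) == 0:
        raise ValueError("physiology must contain at least one segment")
    return np.array(
        [
            total_solubility(
                seg.luminal_pH, seg.bile_salt_mM * 1e-3, partition, compound
            )
            for seg in physiology
        ]
    )
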