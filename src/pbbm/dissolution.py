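"""Particle-size discretization and diffusion-layer dissolution.

Solid drug is represented as a volume-weighted lognormal particle-size
distribution discretized into equal-volume-probability bins (population
balance).  Each bin dissolves by the Nernst-Brunner diffusion-layer rate

    dr/dt = -(D_eff / (rho * h_eff)) * (Cs - Cb)        [cm/s]

with the Hintz-Johnson effective boundary layer ``h_eff = min(r, cutoff)``
(default cutoff 30 µm): small particles see a boundary layer of their own
radius, large particles a capped one.  ``Cs`` is the surface solubility
(taken as the total micellar solubility at bulk segment conditions), ``Cb``
the bulk dissolved concentration; the rate is floored at zero when
``Cb >= Cs`` (particle growth is not modelled — excess dissolved drug is
handled by the first-order supersaturation precipitation term, which with
the configured critical supersaturation ratio of 1000 is effectively
inert for this compound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import norm

__all__ = [
    "ParticleSizeDistribution",
    "ParticleBins",
    "DLMConfig",
    "fit_lognormal_from_quantiles",
    "discretize_psd",
    "effective_boundary_layer",
    "dissolution_rate",
    "precipitation_rate",
    "dissolve_suspension",
]

#: z-scores of the 10th, 50th and 90th percentiles of a standard normal.
_Z_QUANTILES = np.array([-1.2815515655446004, 0.0, 1.2815515655446004])

#: Radius (µm) below which a bin is considered fully dissolved.
R_MIN_UM = 1e-3


def fit_lognormal_from_quantiles(
    d10: float, d50: float, d90: float
) -> tuple[float, float]:
    """Least-squares lognormal parameters from the three volume quantiles.

    Fits ``ln d_q = mu + z_q * sigma`` over z = (-1.28155, 0, +1.28155);
    the fit is exact when ``ln d50`` is the midpoint of ``ln d10`` and
    ``ln d90``.  Returns ``(mu, sigma)`` with ``mu`` in ln-µm.
    """
    if not 0 < d10 < d50 < d90:
        raise ValueError("require 0 < d10 < d50 < d90")
    logs = np.log([d10, d50, d90])
    # Closed-form simple linear regression; z values are symmetric so the
    # intercept is the plain mean of the log-quantiles.
    sigma = float(np.dot(_Z_QUANTILES, logs) / np.dot(_Z_QUANTILES, _Z_QUANTILES))
    mu = float(np.mean(logs))
    return mu, sigma


@dataclass
class ParticleSizeDistribution:
    """Volume-weighted lognormal PSD given by its quantile diameters (µm)."""

    d10: float
    d50: float
    d90: float
    density: float = 1.2  # g/mL

    def __post_init__(self) -> None:
        if not 0 < self.d10 < self.d50 < self.d90:
            raise ValueError("require 0 < d10 < d50 < d90")
        if not self.density > 0:
            raise ValueError("density must be positive")
        self.fitted_log_median, self.fitted_log_sd = fit_lognormal_from_quantiles(
            self.d10, self.d50, self.d90
        )


@dataclass
class ParticleBins:
    """Discretized PSD: per-bin radii (µm) and volume fractions."""

    radii_um: np.ndarray
    volume_fractions: np.ndarray
    density: float  # g/mL

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.radii_um) > 0):
            raise ValueError("bin radii must be strictly increasing")
        if abs(self.volume_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.radii_um)

    def particle_numbers(self, dose_mg: float) -> np.ndarray:
        """Number of particles per bin for a given dose.

        ``N_k = dose * vf_k / (rho * (4/3) * pi * r_k^3)`` with the density
        in mg/cm^3 and radii in cm, so that total particle volume times
        density recovers the dose mass exactly.
        """
        rho = self.density * 1000.0  # mg/cm^3
        r_cm = self.radii_um * 1e-4
        vol = (4.0 / 3.0) * np.pi * r_cm ** 3
        return dose_mg * self.volume_fractions / (rho * vol)


def discretize_psd(
    dist: ParticleSizeDistribution, n_bins: int = 50
) -> ParticleBins:
    """Equal-probability volume-weighted bins of the lognormal PSD.

    The volume-weighted diameter distribution is cut between its 0.1th and
    99.9th percentiles into ``n_bins`` slices of equal volume probability;
    each bin is represented by the diameter at its slice midpoint.  In the
    monodisperse limit (sigma -> 0) all bins collapse onto the median.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    mu, sigma = dist.fitted_log_median, dist.fitted_log_sd
    p = 0.001 + (np.arange(n_bins) + 0.5) / n_bins * 0.998
    diameters = np.exp(mu + sigma * norm.ppf(p))
    if sigma == 0:
        diameters = np.full(n_bins, np.exp(mu))
    radii = diameters / 2.0
    # Guard strict monotonicity for degenerate sigma.
    if not np.all(np.diff(radii) > 0):
        radii = radii + np.arange(n_bins) * 1e-12
    vf = np.full(n_bins, 1.0 / n_bins)
    return ParticleBins(radii_um=radii, volume_fractions=vf, density=dist.density)


@dataclass
class DLMConfig:
    """Diffusion-layer-model numerical configuration."""

    heff_cutoff_um: float = 30.0
    precipitation_rate_constant: float = 1e-4  # 1/h (PRC)
    critical_supersaturation_ratio: float = 1000.0  # CSR
    precipitation_reference: str = "unbound-unionized"

    def __post_init__(self) -> None:
        if not self.heff_cutoff_um > 0:
            raise ValueError("heff_cutoff_um must be positive")
        if self.precipitation_rate_constant < 0:
            raise ValueError("PRC must be non-negative")
        if not self.critical_supersaturation_ratio > 1:
            raise ValueError("CSR must exceed 1")


def effective_boundary_layer(radius_um: float, cutoff_um: float = 30.0) -> float:
    """Hintz-Johnson effective boundary-layer thickness, µm."""
    if not radius_um > 0:
        raise ValueError("radius must be positive")
    return min(radius_um, cutoff_um)


def dissolution_rate(
    radius_um: float,
    cs: float,
    cb: float,
    d_eff: float,
    density: float,
    heff_cutoff_um: float = 30.0,
) -> float:
    """Radial shrinkage rate dr/dt, cm/s (negative while dissolving).

    Parameters
    ----------
    radius_um : float
        Current particle radius, µm.
    cs, cb : float
        Surface solubility and bulk dissolved concentration, mg/mL.
    d_eff : float
        Effective diffusion coefficient of dissolved drug, cm^2/s.
    density : float
        Particle density, g/mL.

    The rate is floored at zero when ``cb >= cs`` (growth suppressed).
    """
    if not cs > 0:
        raise ValueError("surface solubility must be positive")
    h_cm = effective_boundary_layer(radius_um, heff_cutoff_um) * 1e-4
    rho = density * 1000.0  # mg/cm^3
    driving = cs - cb
    if driving <= 0:
        return 0.0
    return -d_eff * driving / (rho * h_cm)


def precipitation_rate(
    c_free_unionized: float, s_aq_unionized: float, config: DLMConfig
) -> float:
    """First-order supersaturation precipitation rate, mg/mL/h.

    Zero until the unbound-unionized concentration exceeds CSR times the
    unionized aqueous solubility, then first order in the excess:
    ``PRC * (C - CSR * S)``.  The first-order model family is
    underdetermined by its label alone; the excess-above-threshold form
    implemented here is inert at the configured CSR of 1000 for any
    physically attainable luminal concentration of this compound.
    """
    if not s_aq_unionized > 0:
        raise ValueError("unionized aqueous solubility must be positive")
    threshold = config.critical_supersaturation_ratio * s_aq_unionized
    if c_free_unionized <= threshold:
        return 0.0
    return config.precipitation_rate_constant * (c_free_unionized - threshold)


def dissolve_suspension(
    dose_mg: float,
    bins: ParticleBins,
    cs: float,
    volume_ml: float,
    d_eff: float,
    t_end_h: float,
    config: Optional[DLMConfig] = None,
    sink: bool = False,
    n_times: int = 200,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> dict:
    """Single-vessel population-balance dissolution of a dosed suspension.

    Integrates per-bin undissolved masses together with the dissolved
    mass in a closed, well-stirred vessel of ``volume_ml`` at constant
    surface solubility ``cs`` (mg/mL).  The state is formulated in mass
    (radii recovered from per-bin mass and fixed particle number), so the
    dissolution flux appears with opposite signs in the solid and
    dissolved equations and total mass is conserved structurally.  With
    ``sink=True`` the bulk concentration is pinned at zero (the
    analytic-oracle regime).  Returns a dict with ``t_h``,
    ``dissolved_mg``, ``undissolved_mg``, per-bin radii trajectories and
    the worst per-step mass-balance residual (relative to the dose).
    """
    if config is None:
        config = DLMConfig()
    n = bins.particle_numbers(dose_mg)  # particles per bin
    m0 = dose_mg * bins.volume_fractions
    rho = bins.density * 1000.0  # mg/cm^3
    cutoff_cm = config.heff_cutoff_um * 1e-4
    rmin_cm = R_MIN_UM * 1e-4
    d_eff_h = d_eff * 3600.0  # cm^2/h
    four_pi = 4.0 * np.pi

    def radii(m):
        return np.cbrt(3.0 * np.maximum(m, 0.0) / (four_pi * rho * n))

    def rhs(t, y):
        m = y[:-1]
        dissolved = y[-1]
        cb = 0.0 if sink else max(dissolved, 0.0) / volume_ml
        r = radii(m)
        h = np.clip(r, rmin_cm, cutoff_cm)
        driving = max(cs - cb, 0.0)
        diss = n * four_pi * r**2 * d_eff_h * driving / h
        return np.concatenate([-diss, [diss.sum()]])

    y0 = np.concatenate([m0, [0.0]])
    t_eval = np.linspace(0.0, t_end_h, n_times)
    sol = solve_ivp(
        rhs, (0.0, t_end_h), y0, method="LSODA", t_eval=t_eval, rtol=rtol,
        atol=atol * max(dose_mg, 1.0),
    )
    if not sol.success:
        raise RuntimeError(f"dissolution integration failed: {sol.message}")
    solid_bins = np.maximum(sol.y[:-1], 0.0)
    solid = solid_bins.sum(axis=0)
    dissolved = sol.y[-1]
    balance = np.abs(solid + dissolved - dose_mg) / dose_mg
    return {
        "t_h": sol.t,
        "dissolved_mg": dissolved,
        "undissolved_mg": solid,
        "solid_bins_mg": solid_bins,
        "radii_cm": np.cbrt(
            3.0 * solid_bins / (four_pi * rho * n[:, None])
        ),
        "max_balance_residual": float(balance.max()),
    }
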