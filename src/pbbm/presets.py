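"""Domain objects assembled from the packaged fixtures.

Convenience constructors for the shipped compound record, calibration
media, disposition parameters and dissolution configuration, so examples
and pipeline runs can start from the published study conditions in one
call.
"""

from __future__ import annotations

from .dissolution import DLMConfig, ParticleSizeDistribution
from .disposition import ClearanceEntry, DispositionParams
from .fixtures import fixture
from .micelle import MediumComposition, SolubilityMeasurement
from .physchem import CompoundRecord

__all__ = [
    "default_compound",
    "default_psd",
    "default_dlm_config",
    "default_disposition",
    "calibration_media",
    "calibration_measurements",
    "regional_peff_overrides",
]


def default_compound() -> CompoundRecord:
    """The studied compound built from the packaged parameter table."""
    return CompoundRecord.from_dict(fixture("compound_model")["compound"])


def default_psd() -> ParticleSizeDistribution:
    psd = fixture("compound_model")["dissolution"]["psd"]
    return ParticleSizeDistribution(
        d10=psd["d10_um"], d50=psd["d50_um"], d90=psd["d90_um"],
        density=psd["density_g_mL"],
    )


def default_dlm_config() -> DLMConfig:
    block = fixture("compound_model")["dissolution"]
    prec = block["precipitation"]
    return DLMConfig(
        heff_cutoff_um=block["heff_cutoff_um"],
        precipitation_rate_constant=prec["prc_per_h"],
        critical_supersaturation_ratio=prec["csr"],
    )


def default_disposition() -> DispositionParams:
    block = fixture("compound_model")
    elim = block["elimination"]
    compound = block["compound"]
    return DispositionParams(
        vss_l_per_kg=block["distribution"]["vss_l_per_kg"],
        clint_entries=tuple(
            ClearanceEntry(e["pathway"], e["value"], e["units"])
            for e in elim["clint"]
        ),
        renal_clearance_l_h=elim["cl_renal_l_h"],
        fu_plasma=compound["fu"],
        blood_plasma_ratio=compound["b_p"],
    )


def calibration_media(media_set: str = "oa_ch") -> list[MediumComposition]:
    """Calibration media pair (``oa_ch`` default, or ``conventional``)."""
    df = fixture("calibration_media")
    df = df[df["media_set"] == media_set]
    if df.empty:
        raise KeyError(f"unknown media set '{media_set}'")
    media = []
    for _, row in df.iterrows():
        fractions = {
            name: row[f"{name}_pct"]
            for name in ("TC", "TCDC", "GC", "GDC")
            if row[f"{name}_pct"] > 0
        }
        media.append(
            MediumComposition(
                label=row["label"],
                pH=row["pH"],
                total_bile_salt=row["total_BS_mM"],
                bile_salt_fractions=fractions,
                PC=row["PC_mM"],
                OA=row["OA_mg_mL"],
                CH=row["CH_mg_mL"],
                prandial_state=row["prandial_state"],
            )
        )
    return media


def calibration_measurements(
    media_set: str = "oa_ch",
) -> list[SolubilityMeasurement]:
    """Calibration media with their observed equilibrium solubilities
    attached as single 'replicates' (µg/mL)."""
    df = fixture("calibration_media")
    df = df[df["media_set"] == media_set]
    media = calibration_media(media_set)
    return [
        SolubilityMeasurement(medium=m, replicates=[obs * 1000.0])
        for m, obs in zip(media, df["observed_solubility_mg_mL"])
    ]


def regional_peff_overrides() -> dict:
    """Regional permeability overrides (1e-4 cm/s) from the fixture."""
    return dict(
        fixture("compound_model")["absorption"]["peff_regional_1e4_cm_s"]
    )
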