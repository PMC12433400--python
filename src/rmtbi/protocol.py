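"""Closed-form calculators for the imaging/impact protocol's physical quantities.

These are the deterministic numbers a study protocol pins down before any
scan is run: the kinetic energy delivered by the pneumatic impactor, the
ferumoxytol bolus needed to hit a target blood iron concentration, the
molar equivalent of a mass concentration of elemental iron, and voxel sizes
from field-of-view / matrix geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: molar mass of elemental iron, g/mol
FE_MOLAR_MASS_G_PER_MOL = 55.845


@dataclass(frozen=True)
class ImpactSpec:
    """Momentum-exchange head-impact parameters (50 g piston at 7.4 m/s)."""

    mass_kg: float = 0.050
    velocity_m_s: float = 7.4

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise ValueError("compactor mass must be positive")
        if self.velocity_m_s < 0:
            raise ValueError("impact velocity must be non-negative")


@dataclass(frozen=True)
class DoseSpec:
    """Ferumoxytol dosing assumptions.

    Blood volume is approximated as ``blood_fraction`` of body weight at a
    blood density of 1 g/mL; the injected volume is chosen to reach
    ``target_blood_ug_per_ml`` µg Fe per mL of blood from a stock of
    ``stock_mg_per_ml`` mg Fe/mL.
    """

    body_weight_g: float
    blood_fraction: float = 0.07
    target_blood_ug_per_ml: float = 200.0
    stock_mg_per_ml: float = 6.0

    def __post_init__(self) -> None:
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be positive")
        if not 0 < self.blood_fraction < 0.15:
            raise ValueError("blood fraction must lie in (0, 0.15)")
        if self.target_blood_ug_per_ml <= 0 or self.stock_mg_per_ml <= 0:
            raise ValueError("concentrations must be positive")


def impact_kinetic_energy(spec: ImpactSpec = ImpactSpec()) -> float:
    """Kinetic energy in joules, KE = m v^2 / 2 (default spec -> 1.37 J)."""
    return 0.5 * spec.mass_kg * spec.velocity_m_s**2


def ferumoxytol_dose_volume(spec: DoseSpec) -> dict[str, float]:
    """Injection volume (mL) and iron mass (mg) for a target blood level."""
    blood_ml = spec.blood_fraction * spec.body_weight_g  # 1 g ~ 1 mL
    fe_mg = spec.target_blood_ug_per_ml * blood_ml / 1000.0
    volume_ml = fe_mg / spec.stock_mg_per_ml
    return {"blood_volume_ml": blood_ml, "fe_mass_mg": fe_mg, "volume_ml": volume_ml}


def fe_molar_concentration(mass_ug_per_ml: float) -> float:
    """Convert µg Fe/mL to mmol/L (200 µg/mL -> 3.58 mmol/L)."""
    if mass_ug_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    # µg/mL == mg/L; divide by g/mol to get mmol/L
    return mass_ug_per_ml / FE_MOLAR_MASS_G_PER_MOL


def voxel_geometry(fov_mm, matrix) -> np.ndarray:
    """Per-axis voxel size in mm, FOV / matrix (30 mm / 180 -> 0.1667 mm)."""
    fov = np.atleast_1d(np.asarray(fov_mm, dtype=float))
    mat = np.atleast_1d(np.asarray(matrix))
    if np.any(fov <= 0):
        raise ValueError("FOV must be positive")
    if np.any(mat < 1) or not np.issubdtype(mat.dtype, np.integer):
        mat_int = np.round(mat).astype(int)
        if np.any(mat_int < 1) or np.any(mat_int != mat):
            raise ValueError("matrix sizes must be positive integers")
        mat = mat_int
    return fov / mat


def protocol_table() -> list[tuple[str, float, str]]:
    """Worked protocol examples as (name, value, unit) rows."""
    dose = ferumoxytol_dose_volume(DoseSpec(body_weight_g=250.0))
    return [
        ("impact kinetic energy", impact_kinetic_energy(), "J"),
        ("Fe molar concentration at 200 ug/mL", fe_molar_concentration(200.0), "mmol/L"),
        ("QUTE-CE voxel size (30 mm / 180)", float(voxel_geometry(30.0, 180)[0]) * 1000, "um"),
        ("DWI in-plane voxel (30 mm / 96)", float(voxel_geometry(30.0, 96)[0]), "mm"),
        ("ferumoxytol volume, 250 g rat", dose["volume_ml"], "mL"),
        ("ferumoxytol Fe mass, 250 g rat", dose["fe_mass_mg"], "mg"),
    ]
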