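"""Compound physicochemistry -> layer-specific transport coefficients.

Three quantitative structure-property relationships (QSPRs) drive the
stratum corneum (SC) barrier:

* ``log10 k_trans`` — trans-bilayer permeability (cm/s) from molecular
  weight: ``-0.570 - 0.840 * MW**(1/3)``.
* ``log10 PC_pro/w`` — SC protein (corneocyte keratin)/water partition from
  lipophilicity: ``0.27 * logKow + log10(5.4)``.
* ``log10 K_lip/w`` — SC intercellular lipid/water partition:
  ``0.81 * logKow + log10(0.43)``.

Each carries a published uncertainty half-width (1.26, 0.32 and 0.434 log
units respectively) inside which the adult in vitro fit is allowed to move
the parameter.  The viable epidermis and dermis are treated as tortuous
aqueous gels with near-unity partitioning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np

from .config import RunConfig

IonizationClass = Literal["acidic", "basic", "neutral"]

#: Table of uncertainty half-widths (log10 units) for the fittable set P*.
QSPR_UNCERTAINTY = {
    "log10_ktrans": 1.26,
    "log10_pc_pro_w": 0.32,
    "log10_k_lip_w": 0.434,
}


@dataclass(frozen=True)
class Compound:
    """Physicochemical identity of a permeant.

    Units: molecular_weight g/mol, solubility_water mg/L (== ug/cm^3),
    solubility_vehicle mg/mL, melting_point Celsius.
    """

    name: str
    molecular_weight: float
    log_kow: float
    pka: Optional[float] = None
    ionization_class: IonizationClass = "neutral"
    solubility_water: Optional[float] = None
    solubility_vehicle: Optional[float] = None
    melting_point: Optional[float] = None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"molecular_weight must be > 0, got {self.molecular_weight}")
        if self.ionization_class not in ("acidic", "basic", "neutral"):
            raise ValueError(f"unknown ionization_class {self.ionization_class!r}")
        for field in ("solubility_water", "solubility_vehicle"):
            value = getattr(self, field)
            if value is not None and value <= 0:
                raise ValueError(f"{field} must be > 0 when present, got {value}")
        if self.ionization_class != "neutral" and self.pka is None:
            raise ValueError("acidic/basic compounds require a pKa")


@dataclass(frozen=True)
class QsprParameterSet:
    """The fittable/uncertain SC parameter triple P*."""

    log10_ktrans: float
    log10_pc_pro_w: float
    log10_k_lip_w: float
    provenance: Literal["nominal", "fitted", "sampled"] = "nominal"

    @classmethod
    def nominal(cls, compound: Compound) -> "QsprParameterSet":
        return cls(
            log10_ktrans=log10_ktrans_nominal(compound.molecular_weight),
            log10_pc_pro_w=log10_pc_pro_w_nominal(compound.log_kow),
            log10_k_lip_w=log10_k_lip_w_nominal(compound.log_kow),
            provenance="nominal",
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.log10_ktrans, self.log10_pc_pro_w, self.log10_k_lip_w])

    @classmethod
    def from_array(
        cls, values: np.ndarray, provenance: Literal["nominal", "fitted", "sampled"]
    ) -> "QsprParameterSet":
        return cls(float(values[0]), float(values[1]), float(values[2]), provenance)

    def with_provenance(self, provenance) -> "QsprParameterSet":
        return replace(self, provenance=provenance)


def qspr_bounds(compound: Compound) -> tuple[np.ndarray, np.ndarray]:
    """(lower, upper) bounds of the P* box: nominal +/- published range."""
    nominal = QsprParameterSet.nominal(compound).as_array()
    half = np.array(
        [
            QSPR_UNCERTAINTY["log10_ktrans"],
            QSPR_UNCERTAINTY["log10_pc_pro_w"],
            QSPR_UNCERTAINTY["log10_k_lip_w"],
        ]
    )
    return nominal - half, nominal + half


@dataclass(frozen=True)
class LayerCoefficients:
    """Lumped diffusivity (cm^2/h) and layer/water partition per skin layer."""

    d_sc: float
    d_ed: float
    d_de: float
    k_sc_w: float
    k_ed_w: float
    k_de_w: float

    def __post_init__(self) -> None:
        for name in ("d_sc", "d_ed", "d_de", "k_sc_w", "k_ed_w", "k_de_w"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be positive and finite, got {value}")


def log10_ktrans_nominal(molecular_weight: float) -> float:
    """Nominal log10 trans-bilayer permeability (cm/s) from MW (g/mol)."""
    if molecular_weight < 0:
        raise ValueError(f"molecular_weight must be >= 0, got {molecular_weight}")
    return -0.570 - 0.840 * molecular_weight ** (1.0 / 3.0)


def log10_pc_pro_w_nominal(log_kow: float) -> float:
    """Nominal log10 SC protein/water partition coefficient."""
    return 0.27 * log_kow + math.log10(5.4)


def log10_k_lip_w_nominal(log_kow: float) -> float:
    """Nominal log10 SC lipid/water partition coefficient."""
    return 0.81 * log_kow + math.log10(0.43)


def fraction_nonionized(
    ph: float, pka: Optional[float], ionization_class: IonizationClass
) -> float:
    """Henderson-Hasselbalch neutral fraction at the given pH."""
    if ionization_class == "neutral":
        return 1.0
    if pka is None:
        raise ValueError("pKa required for acidic/basic compounds")
    if ionization_class == "acidic":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    if ionization_class == "basic":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    raise ValueError(f"unknown ionization_class {ionization_class!r}")


def aqueous_diffusivity(molecular_weight: float) -> float:
    """Free aqueous diffusivity (cm^2/h) from the MW correlation.

    log10 D_aq(cm^2/s) = -4.15 - 0.655 log10(MW); converted to per-hour.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be > 0")
    d_cm2_s = 10.0 ** (-4.15 - 0.655 * math.log10(molecular_weight))
    return d_cm2_s * 3600.0


def sc_permeability(
    compound: Compound,
    qspr: QsprParameterSet,
    config: RunConfig,
    vehicle_ph: Optional[float] = None,
) -> float:
    """Whole-SC permeability P_sc (cm/h) for the neutral permeant species.

    The SC is treated as a homogeneous pseudo-phase: a single trans-bilayer
    permeability acts across ``n_bilayers`` lipid bilayers in series, carried
    by the lipid-phase concentration (hence the K_lip/w factor).
    """
    ktrans_cm_h = 10.0 ** qspr.log10_ktrans * 3600.0
    k_lip_w = 10.0 ** qspr.log10_k_lip_w
    p_sc = ktrans_cm_h * k_lip_w / config.qspr.n_bilayers
    if config.qspr.ionize_permeability and vehicle_ph is not None:
        p_sc *= fraction_nonionized(vehicle_ph, compound.pka, compound.ionization_class)
    return p_sc


def layer_coefficients(
    compound: Compound,
    qspr: QsprParameterSet,
    physiology,
    config: RunConfig,
    vehicle_ph: Optional[float] = None,
) -> LayerCoefficients:
    """Compose the lumped (D, K) pair for each skin layer.

    K_sc/w is the hydration-weighted sum of the water, protein and lipid
    phase partitions; only the lipid term sees the non-ionized fraction.
    D_sc is derived from the SC permeability at the *adult reference*
    thickness, so it is a material property that does not rescale when a
    subject's actual SC thickness changes — thinner SC therefore means
    proportionally higher steady flux.
    """
    phases = config.phases
    if physiology.h_sc <= 0 or physiology.h_ed <= 0 or physiology.h_de <= 0:
        raise ValueError("all layer thicknesses must be positive")

    f_ni = 1.0
    if config.qspr.ionize_lipid_partition and vehicle_ph is not None:
        f_ni = fraction_nonionized(vehicle_ph, compound.pka, compound.ionization_class)

    k_sc_w = (
        phases.water * physiology.hydration_ratio
        + phases.protein * 10.0 ** qspr.log10_pc_pro_w
        + phases.lipid * 10.0 ** qspr.log10_k_lip_w * f_ni
    )

    p_sc = sc_permeability(compound, qspr, config, vehicle_ph)
    h_sc_ref_cm = config.adult.h_sc_um * 1e-4
    d_sc = p_sc * h_sc_ref_cm / k_sc_w

    d_tissue = aqueous_diffusivity(compound.molecular_weight) / config.qspr.tortuosity

    return LayerCoefficients(
        d_sc=d_sc,
        d_ed=d_tissue,
        d_de=d_tissue,
        k_sc_w=k_sc_w,
        k_ed_w=config.qspr.k_ed_w,
        k_de_w=config.qspr.k_de_w,
    )
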