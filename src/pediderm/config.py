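"""Run configuration: every tunable model knob, validated and hashable.

The configuration is deliberately flat-ish and strict: unknown keys are
rejected so that a typo in a YAML file fails loudly instead of silently
falling back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhaseFractions(_StrictModel):
    """Volume fractions of the fully hydrated adult stratum corneum.

    Held age-invariant: infant and adult SC show similar lipid/protein
    composition, so only the water fraction is allowed to move (via the
    hydration maturation ratio).
    """

    water: float = Field(0.60, gt=0)
    protein: float = Field(0.325, gt=0)
    lipid: float = Field(0.075, gt=0)


class QsprConfig(_StrictModel):
    """Closure constants mapping QSPR outputs to layer coefficients.

    n_bilayers : effective number of lipid bilayers crossed in series in the
        SC; converts a single trans-bilayer permeability into a whole-SC
        permeability. Any constant offset here is absorbed when log10ktrans
        is fitted within its uncertainty band.
    tortuosity : path-length factor reducing free aqueous diffusivity in the
        viable epidermis and dermis.
    k_ed_w / k_de_w : near-aqueous tissue/water partition coefficients.
    ionize_lipid_partition : apply the non-ionized fraction to the lipid
        term of K_sc/w (standard pH-partition assumption).
    ionize_permeability : also scale the SC permeability by the non-ionized
        fraction. Off by default: for a saturated donor the neutral-species
        activity equals its intrinsic solubility regardless of vehicle pH.
    """

    n_bilayers: float = Field(70.0, gt=0)
    tortuosity: float = Field(3.0, gt=0)
    k_ed_w: float = Field(0.7, gt=0)
    k_de_w: float = Field(0.7, gt=0)
    ionize_lipid_partition: bool = True
    ionize_permeability: bool = False


class AdultReferenceConfig(_StrictModel):
    """Adult reference skin geometry (fully hydrated, in vitro)."""

    h_sc_um: float = Field(43.0, gt=0)
    h_ed_um: float = Field(60.0, gt=0)
    # dermatomed (split-thickness) dermis as mounted in Franz-cell IVPT;
    # full-thickness in vivo dermis is several-fold thicker
    h_de_um: float = Field(500.0, gt=0)
    hydration_ref: float = Field(1.0, gt=0)


class VehicleConfig(_StrictModel):
    """Donor vehicle geometry and thermodynamics.

    The default depth corresponds to ~1 mL of liquid donor per cm^2, the
    usual solution-dosing arrangement in Franz diffusion cells; it only
    matters in the finite (depleting-donor) regime.
    """

    thickness_um: float = Field(10000.0, gt=0)
    partition_vs_water: float = Field(1.0, gt=0)


class NumericsConfig(_StrictModel):
    """Spatial grid and stiff-integrator controls."""

    nodes_sc: int = Field(15, ge=5)
    nodes_ed: int = Field(15, ge=5)
    nodes_de: int = Field(30, ge=5)
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-10, gt=0)
    n_output: int = Field(201, ge=10)


class MaturationConfig(_StrictModel):
    """Which maturation curves to use and how hydration enters."""

    sc_model: str = Field("model2", pattern="^model[12]$")
    in_vitro_full_hydration: bool = True
    preterm_sc_multiplier: float = Field(1.0, gt=0)


class WorkflowConfig(_StrictModel):
    """Adult-fit and Monte Carlo extrapolation settings."""

    fit_starts: int = Field(10, ge=1)
    mc_samples: int = Field(100, ge=2)
    fit_warn_rel_error: float = Field(0.5, gt=0)
    adult_age_days: float = Field(10950.0, gt=0)  # 30 years


class RunConfig(_StrictModel):
    """Top-level configuration for a model run."""

    phases: PhaseFractions = PhaseFractions()
    qspr: QsprConfig = QsprConfig()
    adult: AdultReferenceConfig = AdultReferenceConfig()
    vehicle: VehicleConfig = VehicleConfig()
    numerics: NumericsConfig = NumericsConfig()
    maturation: MaturationConfig = MaturationConfig()
    workflow: WorkflowConfig = WorkflowConfig()
    seed: int = 0

    @model_validator(mode="after")
    def _check_fractions(self) -> "RunConfig":
        total = self.phases.water + self.phases.protein + self.phases.lipid
        if not 0.5 <= total <= 1.5:
            raise ValueError(f"SC phase fractions sum to {total:.3f}; expected near 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def content_hash(self) -> str:
        """Stable hash of the full configuration, for provenance records."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
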