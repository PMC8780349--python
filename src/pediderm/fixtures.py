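"""Packaged study fixtures, the synthetic ratio-data generator, and report
writers.

The fixture catalog transcribes the study's printed tables: compound
physicochemistry, adult and infant in vitro permeation conditions and
observations, adult SC-thickness measurements, and the maturation-curve
coefficient sets.  Each file's SHA-256 is pinned so that silent edits fail
loudly at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .compound_qspr import Compound
from .config import RunConfig
from .maturation_fit import RatioDataset
from .permeation_solver import ExposureScenario
from .skin_physiology import (
    LognormalSpec,
    MaturationModel,
    estimate_cv_lognormal,
    lognormal_from_mean_cv,
)

_DATA_FILES = {
    "compounds": "compounds.csv",
    "table1": "compounds.csv",
    "adult_observations": "adult_observations.csv",
    "table2": "adult_observations.csv",
    "infant_observations": "infant_observations.csv",
    "table3": "infant_observations.csv",
    "maturation_models": "maturation_models.yaml",
    "table4": "maturation_models.yaml",
    "sc_thickness_adult": "sc_thickness_adult.csv",
    "table6": "sc_thickness_adult.csv",
}


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("pediderm").joinpath("data", filename)))


def _verify_checksum(filename: str, payload: bytes) -> None:
    manifest_path = _data_path("checksums.json")
    manifest = json.loads(manifest_path.read_bytes())
    expected = manifest.get(filename)
    actual = hashlib.sha256(payload).hexdigest()
    if expected is None or actual != expected:
        raise ValueError(
            f"fixture {filename!r} failed its checksum "
            f"(expected {expected}, got {actual}); fixtures are read-only"
        )


def load_fixture(name: str):
    """Load a named fixture table (checksum-verified).

    CSV fixtures return a :class:`pandas.DataFrame`; the maturation-model
    fixture returns the parsed mapping.
    """
    if name not in _DATA_FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(set(_DATA_FILES))}")
    filename = _DATA_FILES[name]
    payload = _data_path(filename).read_bytes()
    _verify_checksum(filename, payload)
    if filename.endswith(".yaml"):
        return yaml.safe_load(payload)
    frame = pd.read_csv(_data_path(filename))
    if filename == "infant_observations.csv":
        unit_to_days = {"d": 1.0, "h": 1.0 / 24.0, "w": 7.0}
        frame["postnatal_age_days"] = frame.apply(
            lambda r: r["postnatal_age_value"] * unit_to_days[r["postnatal_age_unit"]],
            axis=1,
        )
    return frame


def load_compounds() -> dict[str, Compound]:
    """The three study compounds, keyed by name."""
    frame = load_fixture("compounds")
    out: dict[str, Compound] = {}
    for _, row in frame.iterrows():
        out[row["name"]] = Compound(
            name=row["name"],
            molecular_weight=float(row["mw_g_mol"]),
            log_kow=float(row["log_kow"]),
            pka=None if pd.isna(row["pka"]) else float(row["pka"]),
            ionization_class=row["ionization_class"],
            solubility_water=None
            if pd.isna(row["sol_water_mg_L"])
            else float(row["sol_water_mg_L"]),
            solubility_vehicle=None
            if pd.isna(row["sol_vehicle_mg_mL"])
            else float(row["sol_vehicle_mg_mL"]),
            melting_point=None
            if pd.isna(row["melting_point_c"])
            else float(row["melting_point_c"]),
        )
    return out


def load_maturation_models(sc_model: str = "model2") -> dict[str, MaturationModel]:
    """Maturation curves from the packaged coefficient fixture."""
    spec = load_fixture("maturation_models")
    models: dict[str, MaturationModel] = {}
    for pid, entry in spec.items():
        if pid == "sc_thickness":
            entry = entry[sc_model]
        models[pid] = MaturationModel(
            parameter_id=pid,
            form=entry["form"],
            coefficients={k: float(v) for k, v in entry["coefficients"].items()},
            cap_age=None if entry.get("cap_age") is None else float(entry["cap_age"]),
            min_age=float(entry.get("min_age", 0.0)),
        )
    return models


def scenario_from_row(
    row: Mapping, compound: Compound, config: RunConfig
) -> ExposureScenario:
    """Build an exposure scenario from a fixture observation row.

    Aqueous vehicles use the compound's water solubility as the dissolvable
    ceiling (mg/L == ug/cm^3); organic vehicles (ethanol) use the reported
    vehicle solubility (mg/mL -> ug/cm^3) and carry no aqueous pH.
    """
    solvent = str(row["solvent"]).lower()
    if "ethanol" in solvent:
        if compound.solubility_vehicle is None:
            raise ValueError(f"{compound.name}: no vehicle solubility for {solvent}")
        solubility = compound.solubility_vehicle * 1000.0
        ph = None
    else:
        solubility = compound.solubility_water
        raw_ph = row.get("ph")
        ph = None if raw_ph is None or pd.isna(raw_ph) else float(raw_ph)
    return ExposureScenario(
        dose_per_area=float(row["dose_ug_cm2"]),
        duration_h=float(row["duration_h"]),
        vehicle_ph=ph,
        vehicle_thickness_um=config.vehicle.thickness_um,
        solubility_in_vehicle=solubility,
        vehicle_partition=config.vehicle.partition_vs_water,
    )


def default_sc_lognormal(mean_um: float = 43.0) -> LognormalSpec:
    """Adult hydrated-SC-thickness uncertainty derived from the fixture.

    The coefficient of variation comes from the packaged site-averaged SC
    measurements; applied to the hydrated nominal mean this reproduces
    Lognormal(mu=3.68, sigma^2=0.17).
    """
    values = load_fixture("sc_thickness_adult")["mean_um"].to_numpy(float)
    cv = estimate_cv_lognormal(values)
    return lognormal_from_mean_cv(mean_um, cv)


def generate_synthetic_ratios(
    model: MaturationModel,
    ages: Sequence[float],
    noise_sd: float,
    seed: int,
    floor: float = 0.01,
) -> RatioDataset:
    """Synthetic child:adult ratio observations from a maturation curve.

    Emulates literature ratio-vs-age scatter: the curve value plus additive
    Gaussian noise, floored at a small positive ratio.  This is a test and
    demo stand-in for digitized literature data, not a reproduction of it.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ages_arr = np.asarray(list(ages), dtype=float)
    rng = np.random.default_rng(seed)
    ratios = model.ratio(ages_arr) + rng.normal(0.0, noise_sd, size=ages_arr.size)
    ratios = np.maximum(ratios, floor)
    return RatioDataset(
        parameter_id=model.parameter_id,
        age_days=ages_arr,
        ratio=ratios,
        source_label=tuple(f"synthetic_{i}" for i in range(ages_arr.size)),
    )


def write_evaluation_report(
    records: Iterable, destination: str | Path, metadata: Optional[Mapping] = None
) -> dict:
    """Write the evaluation table (CSV) and a JSON summary.

    Returns the summary payload.  The JSON carries per-row fold errors and
    per-compound min/max fold-error summaries, plus optional provenance
    metadata (seed, config hash, package version).
    """
    records = list(records)
    if not records:
        raise ValueError("no evaluation records to write")
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)

    frame = pd.DataFrame([asdict(r) for r in records])
    frame.to_csv(destination / "evaluation.csv", index=False)

    summary: dict = {"records": frame.to_dict(orient="records"), "per_compound": {}}
    for name, group in frame.groupby("compound"):
        summary["per_compound"][name] = {
            "min_fold_error": float(group["fold_error"].min()),
            "max_fold_error": float(group["fold_error"].max()),
            "n": int(len(group)),
        }
    if metadata:
        summary["provenance"] = dict(metadata)
    (destination / "evaluation.json").write_text(json.dumps(summary, indent=2))
    return summary
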