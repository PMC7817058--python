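"""Configuration schema, presets, and CSV/JSON readers and writers."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .pair import BindingModifiers, DoseResponseSurface, PairSystem
from .single_drug import (
    DEFAULT_KAPPA_T,
    DEFAULT_R_MAX,
    DEFAULT_R_MIN,
    DoseResponseCurve,
    DrugKinetics,
    GrowthLaws,
    ResponseShape,
    kinetics_from_shape,
)

log = logging.getLogger("ribocomb")

#: Response parameters of reference drugs (fitted values from the literature)
#: and the resistance-enzyme parameter sets used in the worked examples.
PRESETS = {
    "CHL": {"alpha": 1.04},
    "STR": {"alpha": 0.46},
    "cerg_strong": {"v_max_prime": 1000.0, "k_rem": 0.1},
    "cerg_sweep": [0.0, 100.0, 950.0],
}


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GrowthConfig(_StrictModel):
    kappa_t: float = Field(DEFAULT_KAPPA_T, gt=0)
    r_min: float = Field(DEFAULT_R_MIN, gt=0)
    r_max: float = Field(DEFAULT_R_MAX, gt=0)
    lambda0: float = Field(1.0, gt=0)

    def build(self) -> GrowthLaws:
        return GrowthLaws(self.kappa_t, self.r_min, self.r_max, self.lambda0)


class KineticsConfig(_StrictModel):
    p_in: float = Field(gt=0)
    p_out: float = Field(ge=0)
    k_on: float = Field(gt=0)
    k_off: float = Field(ge=0)


class ShapeConfig(_StrictModel):
    alpha: float = Field(ge=0)
    ic50: float = Field(1.0, gt=0)


class DrugConfig(_StrictModel):
    name: str = "drug"
    kinetics: Optional[KineticsConfig] = None
    shape: Optional[ShapeConfig] = None

    @model_validator(mode="after")
    def _exactly_one(self) -> "DrugConfig":
        if (self.kinetics is None) == (self.shape is None):
            raise ValueError(
                f"drug '{self.name}': specify exactly one of kinetics or shape"
            )
        return self

    def build_kinetics(self, laws: GrowthLaws) -> DrugKinetics:
        if self.kinetics is not None:
            return DrugKinetics(**self.kinetics.model_dump())
        return kinetics_from_shape(
            ResponseShape.from_alpha(self.shape.alpha, laws, self.shape.ic50), laws
        )


class DeltaConfig(_StrictModel):
    on_a: float = Field(1.0, ge=0)
    on_b: float = Field(1.0, ge=0)
    off_a: float = Field(1.0, ge=0)
    off_b: float = Field(1.0, ge=0)

    def build(self) -> BindingModifiers:
        return BindingModifiers(self.on_a, self.on_b, self.off_a, self.off_b)


class GridConfig(_StrictModel):
    c_max: float = Field(3.0, gt=0)
    n: int = Field(121, ge=2)

    def build(self) -> np.ndarray:
        return np.linspace(0.0, self.c_max, self.n)


class SmaConfig(_StrictModel):
    alpha_f: float = Field(ge=0)
    ic50_f: float = Field(1.0, gt=0)
    g_alpha: Optional[float] = None
    g_csv: Optional[str] = None
    cs_max: float = Field(3.0, gt=0)
    n_cs: int = Field(21, ge=2)

    @model_validator(mode="after")
    def _one_g(self) -> "SmaConfig":
        if (self.g_alpha is None) == (self.g_csv is None):
            raise ValueError("sma: specify exactly one of g_alpha or g_csv")
        return self


class EnzymeConfig(_StrictModel):
    v_max_prime: float = Field(ge=0)
    k_rem: float = Field(gt=0)
    target: Literal["A", "B"] = "A"


class CergConfig(_StrictModel):
    enzymes: list[EnzymeConfig] = Field(default_factory=list)
    rescale_axes: bool = True


class ToleranceConfig(_StrictModel):
    additive_band: float = Field(0.01, gt=0)


class ModelConfig(_StrictModel):
    """Validated run configuration; defaults follow the standard growth-law constants."""

    growth: GrowthConfig = Field(default_factory=GrowthConfig)
    drugs: list[DrugConfig] = Field(default_factory=list)
    deltas: DeltaConfig = Field(default_factory=DeltaConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    sma: Optional[SmaConfig] = None
    cerg: Optional[CergConfig] = None
    tolerances: ToleranceConfig = Field(default_factory=ToleranceConfig)
    output_dir: str = "."
    seed: int = 0

    def build_pair(self) -> PairSystem:
        if len(self.drugs) < 2:
            raise ValueError("two drugs required")
        laws = self.growth.build()
        return PairSystem(
            laws=laws,
            kin_a=self.drugs[0].build_kinetics(laws),
            kin_b=self.drugs[1].build_kinetics(laws),
            deltas=self.deltas.build(),
        )


def load_config(path: str | Path) -> ModelConfig:
    """Read and validate a YAML or JSON configuration file.

    Unset growth-law constants fall back to the standard values
    (kappa_t = 0.06 uM^-1 h^-1, r_min = 19.3 uM, r_max = 65.8 uM), which
    is logged for provenance.  Schema violations raise ``ValueError``
    listing the offending fields.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        cfg = ModelConfig.model_validate(data or {})
    except ValidationError as err:
        fields = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in err.errors()
        )
        raise ValueError(f"invalid config {path}: {fields}") from err
    if "growth" not in (data or {}):
        log.info("growth constants not given; using standard defaults "
                 "kappa_t=%.3g, r_min=%.3g, r_max=%.3g",
                 cfg.growth.kappa_t, cfg.growth.r_min, cfg.growth.r_max)
    return cfg


# ---------------------------------------------------------------------------
# Artifact readers/writers (CSV with '.' decimals and header row; JSON)
# ---------------------------------------------------------------------------


def write_curve_csv(curve: DoseResponseCurve, path: str | Path) -> None:
    branch = curve.branch or tuple("upper" for _ in curve.growth)
    pd.DataFrame(
        {
            "concentration": curve.concentrations,
            "concentration_units": curve.concentration_units,
            "growth_relative": curve.growth,
            "branch": branch,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_curve_csv(path: str | Path) -> DoseResponseCurve:
    df = pd.read_csv(path)
    units = str(df["concentration_units"].iloc[0]) if "concentration_units" in df else "ic50"
    return DoseResponseCurve(
        df["concentration"].to_numpy(),
        df["growth_relative"].to_numpy(),
        alpha=float("nan"),
        branch=tuple(df["branch"]) if "branch" in df else (),
        concentration_units=units,
    )


def write_surface_csv(surf: DoseResponseSurface, path: str | Path) -> None:
    """Long-format export: one (c_A, c_B, y) row per grid point."""
    ca, cb = np.meshgrid(surf.c_a, surf.c_b, indexing="ij")
    pd.DataFrame(
        {"c_A": ca.ravel(), "c_B": cb.ravel(), "y": surf.y.ravel()}
    ).to_csv(path, index=False, float_format="%.17g")


def read_surface_csv(path: str | Path) -> DoseResponseSurface:
    df = pd.read_csv(path)
    c_a = np.unique(df["c_A"].to_numpy())
    c_b = np.unique(df["c_B"].to_numpy())
    y = (
        df.pivot(index="c_A", columns="c_B", values="y")
        .reindex(index=c_a, columns=c_b)
        .to_numpy()
    )
    return DoseResponseSurface(c_a, c_b, y, {"source": str(path)})


def write_surface_json(surf: DoseResponseSurface, path: str | Path) -> None:
    payload = {
        "schema": "ribocomb/surface/v1",
        "c_a": surf.c_a.tolist(),
        "c_b": surf.c_b.tolist(),
        "y": surf.y.tolist(),
        "meta": surf.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_surface_json(path: str | Path) -> DoseResponseSurface:
    payload = json.loads(Path(path).read_text())
    return DoseResponseSurface(
        np.asarray(payload["c_a"]), np.asarray(payload["c_b"]),
        np.asarray(payload["y"]), payload.get("meta", {}),
    )
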