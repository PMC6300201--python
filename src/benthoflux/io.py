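"""CSV schema readers and structured run configuration.

Every table the pipeline consumes has a declared schema (required columns and
their types). :func:`read_table` validates the header, coerces numerics and
collects row-level problems with their line numbers instead of silently
dropping rows; empty cells are legitimate missing values.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, SchemaError

#: schema name -> {column: kind}, kind in {"str", "num", "int"}
SCHEMAS: dict[str, dict[str, str]] = {
    "layers": {
        "location": "str", "replicate": "int", "top_cm": "num", "bottom_cm": "num",
        "wet_mass_g": "num", "dry_mass_g": "num", "salinity_psu": "num",
        "chl_a_ug_g": "num", "phaeo_ug_g": "num", "fuco_ug_g": "num",
        "tc_ugC_mg": "num", "toc_ugC_mg": "num", "tn_ugN_mg": "num",
    },
    "incubations": {
        "location": "str", "chamber_id": "str", "light": "str", "analyte": "str",
        "time_h": "num", "conc_umol_L": "num", "tech_sd_umol_L": "num",
    },
    "geometry": {"chamber_id": "str", "diameter_cm": "num", "height_cm": "num"},
    "profiles": {"profile_id": "str", "depth_mm": "num", "o2_umol_L": "num"},
    "profiles_meta": {
        "profile_id": "str", "temperature_C": "num", "salinity_psu": "num",
        "porosity_first_cm": "num",
    },
    "porewater": {"core_id": "str", "analyte": "str", "depth_cm": "num", "conc_umol_L": "num"},
    "taxa": {
        "location": "str", "replicate": "int", "taxon": "str",
        "density_ind_m2": "num", "biomass_gC_m2": "num", "Mi": "int", "Ri": "int",
    },
    "census": {
        "location": "str", "replicate": "int",
        "prok_density_cells_cm3": "num", "prok_cell_volume_um3": "num",
        "meio_biomass_ugC_10cm2": "num",
        "laternula_density_ind_m2": "num", "laternula_biomass_gC_m2": "num",
        "laternula_Mi": "int", "laternula_Ri": "int",
    },
}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`SchemaError` when required columns are missing or when any
    cell that is neither empty nor numeric appears in a numeric column; the
    error message carries the 1-based file line numbers of offending rows.
    Unknown extra columns produce a warning and are kept.
    """
    if schema_name not in SCHEMAS:
        raise DomainError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    schema = SCHEMAS[schema_name]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"{path}: unknown column(s) {', '.join(extra)} kept as-is", stacklevel=2)
    errors = []
    out = {}
    for col, kind in schema.items():
        raw = df[col]
        if kind == "str":
            out[col] = raw.replace("", np.nan)
            continue
        coerced = pd.to_numeric(raw.mask(raw == ""), errors="coerce")
        bad = coerced.isna() & (raw != "")
        for idx in df.index[bad]:
            errors.append(f"line {idx + 2}: column {col!r} value {raw[idx]!r} is not numeric")
        out[col] = coerced.astype(float if kind == "num" else "Int64")
    if errors:
        raise SchemaError(f"{path}: {len(errors)} bad cell(s): " + "; ".join(errors[:10]))
    result = pd.DataFrame(out)
    for c in extra:
        result[c] = df[c]
    return result


@dataclass(frozen=True)
class RunConfig:
    """Every paper-gap knob of the pipeline as a named, validated key."""

    alpha: float = 0.05
    smoothing_window: int = 3
    detection_k: float = 3.0
    gradient_span_mm: float = 0.5
    anoxia_threshold: float = 1.0
    bpc_variant: str = "as_printed"
    molar_mass_c: float = 12.0
    supply_min_mmolC: float = 19.7
    supply_max_mmolC: float = 21.6
    porewater_intervals: dict = field(default_factory=dict)  # analyte -> (start, end) cm
    output_dir: str = "results"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha {self.alpha} outside (0, 1)")
        for name in ("detection_k", "gradient_span_mm", "anoxia_threshold", "molar_mass_c"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise DomainError("smoothing_window must be odd and >= 3")
        if self.bpc_variant not in ("as_printed", "sqrt"):
            raise DomainError(f"unknown bpc_variant {self.bpc_variant!r}")
        if self.supply_max_mmolC < self.supply_min_mmolC:
            raise DomainError("supply_max_mmolC < supply_min_mmolC")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {', '.join(sorted(unknown))}")
        if "porewater_intervals" in data:
            data["porewater_intervals"] = {
                k: tuple(v) for k, v in data["porewater_intervals"].items()
            }
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        data["porewater_intervals"] = {
            k: list(v) for k, v in data["porewater_intervals"].items()
        }
        with path.open("w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
        return path
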