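"""CSV/JSON readers and writers with validation, plus run manifests.

File conventions
----------------
* Titration CSV: columns ``mg_mM, value`` (absolute units) or
  ``mg_rel, value`` with a leading comment line ``# units=relative``.
* Lifetime-curve CSV: ``mg_mM, lifetime_s`` or ``mg_rel, lifetime_rel``.
* Spec JSON: ``{"states": .., "folding": {..}, "rates": {..}, "units": ..}``;
  unknown keys are rejected, and the folding/rates blocks must match the
  state count.
* Site-cleavage CSV: long form ``position, mg_mM, extent``; structure mask
  CSV: ``position, structure`` with 'paired'/'unpaired'.

Readers validate and reject with the offending line number; they never
guess.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .fitting import FitResult, TitrationDataset
from .models import (
    CleavageRates,
    FoldingThreeState,
    FoldingTwoState,
    LifetimeCurve,
    ModelSpec,
)
from .reduction import SiteCleavageTable

__all__ = [
    "SchemaError",
    "RunManifest",
    "read_titration_csv",
    "write_titration_csv",
    "read_curve_csv",
    "write_curve_csv",
    "validate_spec_json",
    "spec_to_dict",
    "spec_from_dict",
    "write_spec_json",
    "read_site_table_csv",
    "write_site_table_csv",
    "read_structure_mask_csv",
    "read_sequence_fasta",
    "n_bonds_from_fasta",
    "fit_result_to_dict",
    "write_manifest",
]


class SchemaError(ValueError):
    """A file does not match its declared schema."""


# ---------------------------------------------------------------- titrations


def _read_units(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        decl = first.lstrip("#").strip()
        if decl == "units=relative":
            return "relative"
        if decl == "units=absolute":
            return "absolute"
        raise SchemaError(f"{path}: unrecognised header comment {first!r}")
    return "absolute"


def read_titration_csv(path, kind: str) -> TitrationDataset:
    """Read and validate a titration CSV; bad rows are reported by line."""
    path = Path(path)
    units = _read_units(path)
    df = pd.read_csv(path, comment="#")
    mg_col = "mg_rel" if units == "relative" else "mg_mM"
    if kind == "lifetime":
        val_cols = ["lifetime_s"] if units == "absolute" else ["lifetime_rel"]
        val_cols.append("value")
    else:
        val_cols = ["fraction_folded", "value"]
    val_col = next((c for c in val_cols if c in df.columns), None)
    if mg_col not in df.columns or val_col is None:
        raise SchemaError(
            f"{path}: expected columns {mg_col!r} and one of {val_cols}, got {list(df.columns)}"
        )
    offset = 3 if units != _read_units_default() else 2  # header line index + 1
    for idx, row in df.iterrows():
        line = idx + offset
        for col in (mg_col, val_col):
            try:
                v = float(row[col])
            except (TypeError, ValueError):
                raise SchemaError(f"{path}, line {line}: non-numeric {col}={row[col]!r}") from None
            if not np.isfinite(v):
                raise SchemaError(f"{path}, line {line}: non-finite {col}")
        if float(row[mg_col]) <= 0:
            raise SchemaError(f"{path}, line {line}: mg must be positive")
    mg = df[mg_col].to_numpy(dtype=float)
    if pd.Series(mg).duplicated().any():
        dup = pd.Series(mg)[pd.Series(mg).duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate mg value {dup}")
    try:
        return TitrationDataset(
            kind=kind, mg=mg, value=df[val_col].to_numpy(dtype=float), units=units,
            metadata={"source": str(path)},
        )
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


def _read_units_default() -> str:
    return "absolute"


def write_titration_csv(path, data: TitrationDataset) -> None:
    path = Path(path)
    mg_col = "mg_rel" if data.units == "relative" else "mg_mM"
    val_col = (
        ("lifetime_rel" if data.units == "relative" else "lifetime_s")
        if data.kind == "lifetime"
        else "fraction_folded"
    )
    with open(path, "w") as fh:
        if data.units == "relative":
            fh.write("# units=relative\n")
        pd.DataFrame({mg_col: data.mg, val_col: data.value}).to_csv(fh, index=False)


def read_curve_csv(path) -> LifetimeCurve:
    path = Path(path)
    units = _read_units(path)
    df = pd.read_csv(path, comment="#")
    mg_col = "mg_rel" if units == "relative" else "mg_mM"
    lt_col = "lifetime_rel" if units == "relative" else "lifetime_s"
    if mg_col not in df.columns or lt_col not in df.columns:
        raise SchemaError(f"{path}: expected columns {mg_col!r}, {lt_col!r}")
    return LifetimeCurve(
        mg=df[mg_col].to_numpy(dtype=float),
        lifetime=df[lt_col].to_numpy(dtype=float),
        units=units,
    )


def write_curve_csv(path, curve: LifetimeCurve) -> None:
    path = Path(path)
    mg_col = "mg_rel" if curve.units == "relative" else "mg_mM"
    lt_col = "lifetime_rel" if curve.units == "relative" else "lifetime_s"
    with open(path, "w") as fh:
        if curve.units == "relative":
            fh.write("# units=relative\n")
        pd.DataFrame({mg_col: curve.mg, lt_col: curve.lifetime}).to_csv(fh, index=False)


# ---------------------------------------------------------------- model spec


_TWO_STATE_KEYS = {"K_D", "n"}
_THREE_STATE_KEYS = {"K_D1", "n1", "K_D2", "n2"}
_RATE_KEYS = {"k_u", "k_i", "k_f"}


def spec_from_dict(obj: dict) -> ModelSpec:
    if not isinstance(obj, dict):
        raise SchemaError("spec must be a JSON object")
    allowed = {"states", "folding", "rates", "units"}
    unknown = set(obj) - allowed
    if unknown:
        raise SchemaError(f"unknown top-level keys: {sorted(unknown)}")
    states = obj.get("states")
    if states not in (1, 2, 3):
        raise SchemaError(f"states must be 1, 2 or 3, got {states!r}")
    units = obj.get("units", "absolute")
    rates_obj = obj.get("rates")
    if not isinstance(rates_obj, dict):
        raise SchemaError("rates block is required")
    unknown = set(rates_obj) - _RATE_KEYS
    if unknown:
        raise SchemaError(f"unknown rate keys: {sorted(unknown)}")
    folding_obj = obj.get("folding")
    if states == 1:
        if folding_obj is not None:
            raise SchemaError("states=1 admits no folding block")
        folding = None
    elif states == 2:
        if not isinstance(folding_obj, dict) or set(folding_obj) != _TWO_STATE_KEYS:
            raise SchemaError(
                f"states=2 requires folding keys {sorted(_TWO_STATE_KEYS)}, "
                f"got {sorted(folding_obj or [])}"
            )
        folding = FoldingTwoState(**{k: float(v) for k, v in folding_obj.items()})
    else:
        if not isinstance(folding_obj, dict) or set(folding_obj) != _THREE_STATE_KEYS:
            raise SchemaError(
                f"states=3 requires folding keys {sorted(_THREE_STATE_KEYS)}, "
                f"got {sorted(folding_obj or [])}"
            )
        folding = FoldingThreeState(**{k: float(v) for k, v in folding_obj.items()})
    try:
        rates = CleavageRates(**{k: float(v) for k, v in rates_obj.items()})
        return ModelSpec(states=states, folding=folding, rates=rates, units=units)
    except (TypeError, ValueError) as e:
        raise SchemaError(str(e)) from e


def spec_to_dict(spec: ModelSpec) -> dict:
    out: dict = {"states": spec.states, "units": spec.units}
    if spec.folding is not None:
        out["folding"] = {k: v for k, v in asdict(spec.folding).items()}
    out["rates"] = {k: v for k, v in asdict(spec.rates).items() if v is not None}
    return out


def validate_spec_json(path) -> ModelSpec:
    """Load and schema-validate a ModelSpec JSON file."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: invalid JSON ({e})") from e
    try:
        return spec_from_dict(obj)
    except SchemaError as e:
        raise SchemaError(f"{path}: {e}") from e


def write_spec_json(path, spec: ModelSpec) -> None:
    Path(path).write_text(json.dumps(spec_to_dict(spec), indent=2) + "\n")


# ---------------------------------------------------------------- site table


def read_site_table_csv(path, mask_path=None) -> SiteCleavageTable:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"position", "mg_mM", "extent"}
    if set(df.columns) < required:
        raise SchemaError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    wide = df.pivot(index="position", columns="mg_mM", values="extent")
    if wide.isna().any().any():
        raise SchemaError(f"{path}: missing (position, condition) combinations")
    mask = read_structure_mask_csv(mask_path) if mask_path is not None else None
    try:
        return SiteCleavageTable(wide, structure_mask=mask)
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


def write_site_table_csv(path, table: SiteCleavageTable) -> None:
    long = (
        table.extent.rename_axis("position")
        .reset_index()
        .melt(id_vars="position", var_name="mg_mM", value_name="extent")
        .sort_values(["mg_mM", "position"])
    )
    long.to_csv(path, index=False)


def read_structure_mask_csv(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if not {"position", "structure"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns position, structure")
    bad = ~df["structure"].isin(["paired", "unpaired"])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise SchemaError(f"{path}, line {line}: structure must be 'paired' or 'unpaired'")
    return pd.Series(df["structure"].to_numpy(), index=df["position"].astype(int).to_numpy())


def read_sequence_fasta(path) -> str:
    """Read a single-record FASTA construct sequence."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise SchemaError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    seq = str(records[0].seq)
    if not seq:
        raise SchemaError(f"{path}: empty sequence")
    return seq


def n_bonds_from_fasta(path) -> int:
    """Phosphodiester bond count of the construct: sequence length - 1."""
    return len(read_sequence_fasta(path)) - 1


# ------------------------------------------------------------------ results


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "spec": spec_to_dict(fit.spec),
        "ssr": fit.ssr,
        "loss_scale": fit.loss_scale,
        "converged": fit.converged,
        "n_tied": fit.n_tied,
        "starts": fit.starts,
        "best_start_index": fit.best_start_index,
        "residuals": [float(r) for r in fit.residuals],
    }


# ----------------------------------------------------------------- manifest


@dataclass(frozen=True)
class RunManifest:
    """Provenance record tying a CLI run to its inputs, seed and version."""

    command: str
    arguments: dict
    input_hashes: dict
    seed: Optional[int]
    package_version: str
    timestamp: str


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_path,
    command: str,
    arguments: dict,
    inputs: Union[list, tuple] = (),
    seed: Optional[int] = None,
) -> RunManifest:
    from . import __version__

    manifest = RunManifest(
        command=command,
        arguments={k: str(v) for k, v in arguments.items()},
        input_hashes={str(p): _sha256(Path(p)) for p in inputs},
        seed=seed,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    Path(out_path).write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest
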