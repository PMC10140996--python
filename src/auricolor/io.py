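"""CSV/TSV/YAML/JSON formats and schema validation.

All tables are plain UTF-8 CSV with a header row.  Validation errors name
the offending file, row (1-based data rows) and field.

Schemas
-------
strains.csv : strain_id, mating_type (MAT1|MAT2|empty), haplotype_class
    (AB|Ab|aB|ab|empty), role (parent|tester|mapping|empty), provenance
crosses_<design>.csv : cross_id, parent1, parent2, design, fruited
    (true|false), color (purple|white|empty), replicate
markers.csv : strain_id then one column per marker; codes A, B or empty
truth.csv : strain_id, mating_type, haplotype_class, in_inbred_subset
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import Color, HaplotypeClass, MatingType
from .linkage import MarkerMatrix
from .simulate import CrossResult, Monokaryon

__all__ = [
    "TableValidationError",
    "read_strain_table",
    "write_strain_table",
    "read_cross_table",
    "write_cross_table",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_config",
    "write_config",
    "write_report",
    "strains_to_frame",
    "crosses_to_frame",
    "normalize_color",
]

STRAIN_COLUMNS = ["strain_id", "mating_type", "haplotype_class", "role", "provenance"]
CROSS_COLUMNS = ["cross_id", "parent1", "parent2", "design", "fruited", "color", "replicate"]


class TableValidationError(ValueError):
    """A table failed schema validation; message names file, row and field."""

    def __init__(self, path, row: Optional[int], field: str, problem: str):
        self.path, self.row, self.field = str(path), row, field
        loc = f"{path}" + (f", row {row}" if row is not None else "")
        super().__init__(f"{loc}, field {field!r}: {problem}")


def normalize_color(value) -> Optional[str]:
    """Case-insensitive colour normalisation to 'purple'/'white'; empty -> None."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s == "":
        return None
    if s not in (Color.PURPLE.value, Color.WHITE.value):
        raise ValueError(f"unknown colour {value!r}")
    return s


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as e:
        raise TableValidationError(path, None, "<file>", f"malformed CSV: {e}")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(
            path, None, ",".join(missing), "missing required column(s)"
        )


def read_strain_table(path) -> pd.DataFrame:
    """Read and validate a strain table; unknown columns are preserved."""
    df = _read_csv(path)
    _require_columns(df, ["strain_id", "mating_type"], path)
    seen = {}
    for i, sid in enumerate(df["strain_id"], start=1):
        if not sid:
            raise TableValidationError(path, i, "strain_id", "empty id")
        if sid in seen:
            raise TableValidationError(
                path, i, "strain_id", f"duplicate id {sid!r} (first at row {seen[sid]})"
            )
        seen[sid] = i
    valid_mt = {m.value for m in MatingType} | {""}
    for i, mt in enumerate(df["mating_type"], start=1):
        if mt not in valid_mt:
            raise TableValidationError(
                path, i, "mating_type",
                f"unknown idiomorph {mt!r}; expected MAT1, MAT2 or empty",
            )
    if "haplotype_class" in df.columns:
        valid_hc = {h.value for h in HaplotypeClass} | {""}
        for i, hc in enumerate(df["haplotype_class"], start=1):
            if hc not in valid_hc:
                raise TableValidationError(
                    path, i, "haplotype_class", f"unknown class {hc!r}"
                )
    return df


def write_strain_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cross_table(path) -> pd.DataFrame:
    """Read and validate a cross table.

    ``fruited`` is parsed to bool; ``color`` must be present iff fruited.
    """
    df = _read_csv(path)
    _require_columns(df, ["cross_id", "parent1", "parent2", "design", "fruited", "color"], path)
    fruited = []
    for i, v in enumerate(df["fruited"], start=1):
        s = str(v).strip().lower()
        if s in ("true", "1", "yes"):
            fruited.append(True)
        elif s in ("false", "0", "no"):
            fruited.append(False)
        else:
            raise TableValidationError(
                path, i, "fruited", f"expected true/false, got {v!r}"
            )
    colors = []
    for i, (v, f) in enumerate(zip(df["color"], fruited), start=1):
        try:
            c = normalize_color(v)
        except ValueError as e:
            raise TableValidationError(path, i, "color", str(e))
        if c is None and f:
            raise TableValidationError(
                path, i, "color", "fruited cross must carry a colour"
            )
        if c is not None and not f:
            raise TableValidationError(
                path, i, "color", "colour present but fruited is false"
            )
        colors.append(c if c is not None else "")
    out = df.copy()
    out["fruited"] = fruited
    out["color"] = colors
    if "replicate" in out.columns:
        out["replicate"] = out["replicate"].replace("", "1").astype(int)
    else:
        out["replicate"] = 1
    return out


def write_cross_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["fruited"] = out["fruited"].map(lambda b: "true" if b else "false")
    out.to_csv(path, index=False)


def read_marker_matrix(path) -> MarkerMatrix:
    """Read a strains x markers CSV of parental-origin codes A/B/missing."""
    df = _read_csv(path)
    if df.columns[0] != "strain_id":
        raise TableValidationError(
            path, None, df.columns[0], "first column must be strain_id"
        )
    df = df.set_index("strain_id")
    for i, (sid, row) in enumerate(df.iterrows(), start=1):
        for col, v in row.items():
            if v not in ("A", "B", "", "-"):
                raise TableValidationError(
                    path, i, str(col),
                    f"invalid marker code {v!r} for strain {sid!r}; "
                    "expected A, B or missing",
                )
    calls = df.replace({"": np.nan, "-": np.nan})
    return MarkerMatrix(calls)


def write_marker_matrix(calls: pd.DataFrame, path) -> None:
    out = calls.fillna("")
    out.index.name = "strain_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Object <-> frame adapters
# ---------------------------------------------------------------------------


def strains_to_frame(bundle) -> pd.DataFrame:
    """Strain table covering parents, testers and the mapping population."""
    rows = []
    for role, group in (("parent", bundle.parents), ("tester", bundle.testers)):
        for mk in group.values():
            rows.append(
                {
                    "strain_id": mk.id,
                    "mating_type": mk.mating.value if mk.mating else "",
                    "haplotype_class": mk.haplotype.haplotype_class.value,
                    "role": role,
                    "provenance": f"synthetic seed={bundle.config.seed}",
                }
            )
    for mk in bundle.mapping_strains:
        rows.append(
            {
                "strain_id": mk.id,
                "mating_type": mk.mating.value if mk.mating else "",
                "haplotype_class": "",  # truth withheld from the analysis table
                "role": "mapping",
                "provenance": f"synthetic seed={bundle.config.seed}",
            }
        )
    return pd.DataFrame(rows, columns=STRAIN_COLUMNS)


def crosses_to_frame(crosses: Iterable[CrossResult]) -> pd.DataFrame:
    rows = [
        {
            "cross_id": c.id,
            "parent1": c.parent1,
            "parent2": c.parent2,
            "design": c.design,
            "fruited": c.fruited,
            "color": c.color.value if c.color else "",
            "replicate": c.replicate,
        }
        for c in crosses
    ]
    return pd.DataFrame(rows, columns=CROSS_COLUMNS)


# ---------------------------------------------------------------------------
# Config and reports
# ---------------------------------------------------------------------------


def write_config(cfg, path) -> None:
    """Serialise a StudyConfig to YAML."""
    d = dataclasses.asdict(cfg)
    d["marker_plan"] = [dataclasses.asdict(p) for p in cfg.marker_plan]
    d["trait_positions"] = {k: list(v) for k, v in cfg.trait_positions.items()}
    for k in ("mating_weights", "a_weights", "b_weights"):
        d[k] = list(d[k])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_config(path):
    """Load a StudyConfig from YAML; missing keys fall back to defaults."""
    from .synth import ContigPlan, StudyConfig

    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(d) - known
    if unknown:
        raise TableValidationError(
            path, None, ",".join(sorted(unknown)), "unknown config key(s)"
        )
    if "marker_plan" in d:
        d["marker_plan"] = tuple(ContigPlan(**p) for p in d["marker_plan"])
    if "trait_positions" in d:
        d["trait_positions"] = {
            k: (v[0], int(v[1])) for k, v in d["trait_positions"].items()
        }
    for k in ("mating_weights", "a_weights", "b_weights"):
        if k in d:
            d[k] = tuple(float(x) for x in d[k])
    return StudyConfig(**d)


def write_report(report: dict, path) -> None:
    """Write a deterministic (sorted, timestamp-free) JSON report."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
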