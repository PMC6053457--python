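"""Delimited-text readers and writers for designs, models and configs.

All tables are comma-separated, period-decimal, UTF-8; Unicode minus signs
(occasionally produced by table extraction) are normalized to ASCII on
ingest.  Readers are tolerant of extra annotation columns (logged, ignored)
but strict about required columns and non-numeric cells, which are reported
with their line numbers.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .designs import DesignMatrix, FactorSpec, classify_point_types, code_point
from .rsm import QuadraticModel

__all__ = [
    "SchemaError",
    "read_design_csv",
    "write_design_csv",
    "read_steps_csv",
    "read_kinetics_csv",
    "model_to_json",
    "model_from_json",
    "load_config",
    "factors_from_config",
]

logger = logging.getLogger("rsmga")

_UNICODE_MINUS = "−"


class SchemaError(ValueError):
    """A table does not match the expected column schema."""


def _read_table(path) -> pd.DataFrame:
    text = Path(path).read_text(encoding="utf-8").replace(_UNICODE_MINUS, "-")
    return pd.read_csv(_io.StringIO(text))


def _numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    """Coerce columns to float, reporting offending data lines (1-based,
    header is line 1)."""
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
            raise SchemaError(f"{path}: non-numeric values in column {col!r} at line(s) {lines}")
        if coerced.isna().any():
            lines = [int(i) + 2 for i in np.flatnonzero(coerced.isna().to_numpy())]
            raise SchemaError(f"{path}: missing values in column {col!r} at line(s) {lines}")
        out[col] = coerced
    return out


def read_design_csv(
    path,
    factors: list[FactorSpec],
    response: str | None = "response",
    alpha: float = 2.0,
    require_response: bool = False,
) -> DesignMatrix:
    """Read a runs × factors table in natural units, with optional response
    and point_type columns.  Factor columns are matched by name; unknown
    columns are ignored with a logged notice."""
    df = _read_table(path)
    names = [f.name for f in factors]
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required factor column(s) {missing}")
    if require_response and (response is None or response not in df.columns):
        raise SchemaError(f"{path}: missing required response column {response!r}")
    need_response = response is not None and response in df.columns
    known = set(names) | {response, "point_type", "run"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.info("%s: ignoring extra column(s) %s", path, extra)

    df = _numeric(df, names + ([response] if need_response else []), path)
    natural = df[names].to_numpy(dtype=float)
    coded = code_point(natural, factors)
    if "point_type" in df.columns:
        point_type = [str(t) for t in df["point_type"]]
    elif all(f.role == "ccd" for f in factors):
        point_type = classify_point_types(coded, alpha=alpha)
    else:
        point_type = ["pbd"] * len(df)
    resp = df[response].to_numpy(dtype=float) if need_response else None
    return DesignMatrix(
        factors=list(factors), coded=coded, natural=natural, point_type=point_type, response=resp
    )


def write_design_csv(design: DesignMatrix, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_steps_csv(path) -> pd.DataFrame:
    """Purification steps: columns step, protein_mg, activity_u."""
    df = _read_table(path)
    for col in ("step", "protein_mg", "activity_u"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return _numeric(df, ["protein_mg", "activity_u"], path)


def read_kinetics_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Kinetics points: columns substrate_mm, velocity."""
    df = _read_table(path)
    for col in ("substrate_mm", "velocity"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    df = _numeric(df, ["substrate_mm", "velocity"], path)
    return df["substrate_mm"].to_numpy(dtype=float), df["velocity"].to_numpy(dtype=float)


def model_to_json(model: QuadraticModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n", encoding="utf-8")


def model_from_json(path) -> QuadraticModel:
    return QuadraticModel.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def load_config(path) -> dict:
    """Load a JSON or YAML configuration file (by extension)."""
    p = Path(path)
    text = p.read_text(encoding="utf-8")
    if p.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def factors_from_config(entries: list[dict]) -> list[FactorSpec]:
    """Factor specifications from config entries: name, role, and levels
    (low/high for screening, center/step for ccd)."""
    out = []
    for e in entries:
        role = e.get("role", "screening")
        kw = {k: e[k] for k in ("low", "high", "center", "step", "units") if k in e}
        out.append(FactorSpec(name=e["name"], role=role, **kw))
    return out
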