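"""CSV schemas and validated I/O for the four observation tables.

All tables are UTF-8 comma-delimited text with a header row.  Sex is coded
``F``/``H``, booleans are ``0``/``1`` and missing values are empty fields.
One file per record type:

* ``survey.csv``   — stem-level transect survey records
* ``plants.csv``   — whole-plant monitoring records
* ``flowers.csv``  — flower-level records (one row per flower)
* ``pairs.csv``    — age-matched flower pairs in long form (two rows per
  pair sharing a ``pair_id``; exactly one row has ``egg = 1``)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DatasetError", "SCHEMAS", "write_dataset", "read_dataset"]


class DatasetError(ValueError):
    """Raised for malformed dataset files or records."""


_BOOL = "bool01"
_COUNT = "count"
_OPT_COUNT = "opt_count"
_POS = "positive_float"
_OPT_POS = "opt_positive_float"
_SEX = "sex"
_LABEL = "label"
_FLOAT = "float"

SCHEMAS: dict[str, dict[str, str]] = {
    "survey": {
        "population": _LABEL,
        "sex": _SEX,
        "open_flowers": _COUNT,
        "eggs": _COUNT,
        "caterpillars": _COUNT,
        "leaf_damage": _BOOL,
        "flower_damage": _BOOL,
    },
    "plants": {
        "plant_id": _LABEL,
        "sex": _SEX,
        "stems": _COUNT,
        "height": _POS,
        "projected_area": _POS,
        "open_flowers": _COUNT,
        "flower_depth": _POS,
        "flower_width": _POS,
        "egg_c1": _BOOL,
        "egg_c2": _BOOL,
        "egg_c3": _BOOL,
        "egg_c4": _BOOL,
        "ever_egg": _BOOL,
        "eggs_total": _COUNT,
        "bud_damage_a1": _BOOL,
        "bud_damage_a2": _BOOL,
        "calyx_damage_a1": _BOOL,
        "calyx_damage_a2": _BOOL,
        "petal_damage_a1": _BOOL,
        "petal_damage_a2": _BOOL,
        "ovary_damage_a1": _BOOL,
        "ovary_damage_a2": _BOOL,
        "fruits_expanded": _COUNT,
        "fruits_damaged": _COUNT,
    },
    "flowers": {
        "population": _LABEL,
        "stem_id": _LABEL,
        "sex": _SEX,
        "egg": _BOOL,
    },
    "pairs": {
        "pair_id": _LABEL,
        "plant_id": _LABEL,
        "population": _LABEL,
        "sex": _SEX,
        "egg": _BOOL,
        "floral_face_width": _POS,
        "flower_length": _POS,
        "calyx_width": _POS,
        "calyx_length": _POS,
        "tube_opening": _POS,
        "seeds": _OPT_COUNT,
        "fruit_mass": _OPT_POS,
    },
}


def _validate_column(name: str, kind: str, col: pd.Series, kind_name: str) -> pd.Series:
    """Coerce and validate one column, reporting the first offending line.

    Line numbers are 1-based file lines (header is line 1).
    """

    def bad(mask: pd.Series, why: str) -> None:
        if bool(mask.any()):
            idx = int(np.flatnonzero(mask.to_numpy())[0])
            line = idx + 2
            value = col.iloc[idx]
            raise DatasetError(
                f"{kind_name} dataset, column {name!r}, line {line}: "
                f"invalid value {value!r} ({why})"
            )

    if kind == _LABEL:
        out = col.astype("string")
        bad(out.isna() | (out.str.len() == 0), "label required")
        return out.astype(object)
    if kind == _SEX:
        out = col.astype("string").str.strip()
        bad(~out.isin(["F", "H"]), "sex must be 'F' or 'H'")
        return out.astype(object)

    numeric = pd.to_numeric(col, errors="coerce")
    missing = numeric.isna() & ~col.isna() if col.dtype == object else numeric.isna() & col.notna()
    bad(missing, "not a number")

    if kind == _BOOL:
        bad(numeric.isna(), "boolean 0/1 required")
        bad(~numeric.isin([0, 1]), "boolean must be 0 or 1")
        return numeric.astype(np.int64)
    if kind in (_COUNT, _OPT_COUNT):
        if kind == _COUNT:
            bad(numeric.isna(), "count required")
        bad(numeric.notna() & ((numeric < 0) | (numeric != numeric.round())), "nonnegative integer required")
        return numeric.astype("Int64")
    if kind in (_POS, _OPT_POS):
        if kind == _POS:
            bad(numeric.isna(), "value required")
        bad(numeric.notna() & (numeric <= 0), "positive value required")
        return numeric.astype(float)
    if kind == _FLOAT:
        bad(numeric.isna(), "value required")
        return numeric.astype(float)
    raise AssertionError(f"unknown column kind {kind!r}")


def validate_dataset(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Validate a dataframe against the named schema; return a coerced copy."""
    if kind not in SCHEMAS:
        raise DatasetError(f"unknown dataset kind {kind!r}")
    schema = SCHEMAS[kind]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise DatasetError(f"{kind} dataset is missing columns: {missing}")
    out = pd.DataFrame(index=df.index)
    for name, ckind in schema.items():
        out[name] = _validate_column(name, ckind, df[name], kind)
    if kind == "survey" and len(out):
        if int((out["open_flowers"] < 1).sum()):
            raise DatasetError("survey dataset: open_flowers must be >= 1 (stems were selected for bearing an open flower)")
    if kind == "pairs" and len(out):
        sizes = out.groupby("pair_id")["egg"].agg(["size", "sum"])
        bad = sizes[(sizes["size"] != 2) | (sizes["sum"] != 1)]
        if len(bad):
            raise DatasetError(
                "pairs dataset: each pair_id needs exactly two rows with exactly "
                f"one egg=1; offending pair_ids: {list(bad.index[:5])}"
            )
    return out


def write_dataset(df: pd.DataFrame, path, kind: str) -> None:
    """Write a validated dataset as CSV (missing values as empty fields)."""
    out = validate_dataset(df, kind)
    out.to_csv(path, index=False, na_rep="")


def read_dataset(path, kind: str) -> pd.DataFrame:
    """Read and validate a dataset CSV.

    A header-only file yields an empty, correctly typed dataframe.  Malformed
    rows raise :class:`DatasetError` naming the column and file line.
    """
    try:
        raw = pd.read_csv(path, dtype=object, keep_default_na=True, na_values=[""])
    except FileNotFoundError:
        raise DatasetError(f"dataset file not found: {path}") from None
    except pd.errors.EmptyDataError:
        raise DatasetError(f"dataset file {path} has no header row") from None
    return validate_dataset(raw, kind)
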