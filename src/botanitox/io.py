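"""Readers and writers for plate tables, annotation tables, and result tables.

All tables are delimited text (CSV canonical; tab-delimited accepted on
read), UTF-8, "." decimal. Concentrations are stored in ug/mL throughout;
an optional ``concentration_unit`` column ("ug/mL" or "mg/mL") converts
mg/mL inputs on read.
"""
from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import numpy as np
import pandas as pd

from .types import (
    ROLE_EMPTY,
    ROLE_SUBSTANCE,
    ROLES,
    EndpointSpec,
    FormatError,
    IntegrityError,
    SubstanceSpec,
)
from .config import StudyConfig, load_config  # noqa: F401  (re-export)

ROW_LETTERS = "ABCDEFGHIJKLMNOP"

#: canonical column order of a well table
WELL_COLUMNS = [
    "plate_id", "row", "col", "role", "substance_id", "lot_id",
    "concentration", "run_index", "endpoint_id", "raw_value",
]
_WELL_REQUIRED = ["plate_id", "run_index", "endpoint_id", "raw_value"]

_WELL_LABEL = re.compile(r"^([A-Pa-p])0*([1-9][0-9]?)$")

_UNIT_FACTORS = {
    "ug/ml": 1.0, "µg/ml": 1.0, "μg/ml": 1.0,
    "mg/ml": 1000.0,
}


def parse_well_label(label: str) -> tuple:
    """Parse a well label like "A03" or "a3" into (row letter, 1-based col)."""
    m = _WELL_LABEL.match(str(label).strip())
    if m is None:
        raise FormatError(f"cannot parse well label {label!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if col > 24:
        raise FormatError(f"well column {col} out of range 1-24 in label {label!r}")
    return row, col


def _read_delimited(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".tab"):
        return pd.read_csv(path, sep="\t")
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path)
    return pd.read_csv(path, sep=None, engine="python")


def read_plate_table(
    path: Union[str, Path],
    config: Optional[StudyConfig] = None,
) -> pd.DataFrame:
    """Read raw well measurements into the canonical well table.

    The header must name ``plate_id``, ``run_index``, ``endpoint_id``,
    ``raw_value`` and either a ``well`` label column or ``row``/``col``
    columns. A missing ``role`` column is inferred: wells carrying a
    substance_id are substance wells; wells in columns 1-2 are empty when the
    layout declares them so. An explicit role column is never overridden.
    """
    config = config or StudyConfig()
    df = _read_delimited(path)
    df.columns = [str(c).strip() for c in df.columns]

    missing = [c for c in _WELL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "well" in df.columns:
        parsed = [parse_well_label(w) for w in df["well"]]
        df["row"] = [p[0] for p in parsed]
        df["col"] = [p[1] for p in parsed]
    elif not {"row", "col"} <= set(df.columns):
        raise FormatError(f"{path}: need a 'well' column or 'row'/'col' columns")
    else:
        df["row"] = df["row"].astype(str).str.strip().str.upper()
        df["col"] = df["col"].astype(int)

    bad_rows = sorted(set(df["row"]) - set(ROW_LETTERS))
    if bad_rows:
        raise FormatError(f"{path}: invalid row letter(s) {bad_rows}")
    if ((df["col"] < 1) | (df["col"] > 24)).any():
        raise FormatError(f"{path}: well columns must lie in 1-24")

    for optional in ("substance_id", "lot_id", "concentration"):
        if optional not in df.columns:
            df[optional] = np.nan
    df["concentration"] = pd.to_numeric(df["concentration"], errors="coerce")
    if "concentration_unit" in df.columns:
        factors = (
            df["concentration_unit"].astype(str).str.strip().str.lower()
            .map(_UNIT_FACTORS)
        )
        known = df["concentration_unit"].notna()
        if factors[known].isna().any():
            bad = sorted(df.loc[known & factors.isna(), "concentration_unit"].unique())
            raise FormatError(f"{path}: unknown concentration unit(s) {bad}")
        df["concentration"] = df["concentration"] * factors.fillna(1.0)
        df = df.drop(columns=["concentration_unit"])

    has_substance = df["substance_id"].notna() & (df["substance_id"].astype(str) != "")
    if "role" not in df.columns:
        df["role"] = np.nan
    inferred = np.where(
        has_substance,
        ROLE_SUBSTANCE,
        np.where(
            config.first_two_columns_empty & df["col"].isin([1, 2]),
            ROLE_EMPTY,
            "",  # not inferable from the declared layout
        ),
    )
    df["role"] = df["role"].where(df["role"].notna(), inferred)
    if (df["role"] == "").any():
        bad = df.loc[df["role"] == "", ["plate_id", "row", "col"]].head(5).to_dict("records")
        raise FormatError(
            f"{path}: wells without a substance_id need an explicit role "
            f"(dmso/positive_control/empty), e.g. {bad}"
        )
    bad_role = sorted(set(df["role"]) - set(ROLES))
    if bad_role:
        raise FormatError(f"{path}: unknown role(s) {bad_role}")

    is_sub = df["role"] == ROLE_SUBSTANCE
    if (is_sub & ~has_substance).any():
        raise FormatError(f"{path}: substance wells must carry a substance_id")
    if (is_sub & ~(df["concentration"] > 0)).any():
        raise FormatError(f"{path}: substance wells must carry a positive concentration")
    if (~is_sub & (has_substance | df["concentration"].notna())).any():
        raise FormatError(
            f"{path}: control/empty wells must not carry substance_id or concentration"
        )

    key = ["plate_id", "row", "col", "endpoint_id", "run_index"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        examples = df.loc[dup, key].head(5).to_dict("records")
        raise IntegrityError(f"{path}: duplicate well measurements, e.g. {examples}")

    df["run_index"] = df["run_index"].astype(int)
    df["raw_value"] = pd.to_numeric(df["raw_value"], errors="raise").astype(float)
    return df[WELL_COLUMNS].reset_index(drop=True)


def write_results_long(
    frame: pd.DataFrame,
    path: Union[str, Path],
    allow_empty: bool = False,
) -> None:
    """Write a result table as CSV: one record per row, stable column order.

    Missing values (e.g. the POD of an inactive call) become empty cells,
    never zeros. Floats are written at full shortest-repr precision so the
    matching reader round-trips real fields to well below 1e-12 relative
    error.
    """
    if frame.empty and not allow_empty:
        raise ValueError("refusing to write an empty table without allow_empty=True")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_results_long(path: Union[str, Path]) -> pd.DataFrame:
    """Read back a table written by :func:`write_results_long`."""
    return _read_delimited(path)


# -- endpoint / substance annotation tables ---------------------------------

ENDPOINT_COLUMNS = [
    "endpoint_id", "effect_category", "direction",
    "is_counter_screen", "paired_primary", "timepoint", "family",
]
SUBSTANCE_COLUMNS = ["substance_id", "group", "formulation", "lot_id", "excluded"]


def endpoints_to_frame(endpoints: Iterable[EndpointSpec]) -> pd.DataFrame:
    rows = [
        {
            "endpoint_id": e.endpoint_id,
            "effect_category": e.effect_category,
            "direction": e.direction,
            "is_counter_screen": e.is_counter_screen,
            "paired_primary": e.paired_primary,
            "timepoint": e.timepoint,
            "family": e.family,
        }
        for e in endpoints
    ]
    return pd.DataFrame(rows, columns=ENDPOINT_COLUMNS)


def frame_to_endpoints(frame: pd.DataFrame) -> Dict[str, EndpointSpec]:
    """Build an endpoint_id -> EndpointSpec mapping from an annotation table."""
    specs: Dict[str, EndpointSpec] = {}
    for rec in frame.to_dict("records"):
        spec = EndpointSpec(
            endpoint_id=str(rec["endpoint_id"]),
            effect_category=str(rec.get("effect_category", "other")),
            direction=str(rec.get("direction", "increase")),
            is_counter_screen=bool(rec.get("is_counter_screen", False)),
            paired_primary=_opt_str(rec.get("paired_primary")),
            timepoint=_opt_float(rec.get("timepoint")),
            family=_opt_str(rec.get("family")),
        )
        specs[spec.endpoint_id] = spec
    return specs


def substances_to_frame(substances: Iterable[SubstanceSpec]) -> pd.DataFrame:
    rows = [
        {
            "substance_id": s.substance_id,
            "group": s.group,
            "formulation": s.formulation,
            "lot_id": s.lot_id,
            "excluded": s.excluded,
        }
        for s in substances
    ]
    return pd.DataFrame(rows, columns=SUBSTANCE_COLUMNS)


def frame_to_substances(frame: pd.DataFrame) -> List[SubstanceSpec]:
    return [
        SubstanceSpec(
            substance_id=str(rec["substance_id"]),
            group=str(rec["group"]),
            formulation=str(rec.get("formulation", "extract")),
            lot_id=_opt_str(rec.get("lot_id")),
            excluded=bool(rec.get("excluded", False)),
        )
        for rec in frame.to_dict("records")
    ]


def read_endpoint_table(path: Union[str, Path]) -> Dict[str, EndpointSpec]:
    return frame_to_endpoints(_read_delimited(path))


def read_substance_table(path: Union[str, Path]) -> List[SubstanceSpec]:
    return frame_to_substances(_read_delimited(path))


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value)
    return s if s and s.lower() != "nan" else None


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    v = float(value)
    return None if np.isnan(v) else v
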