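"""Reading and writing chemical property tables.

The on-disk format is delimited text (CSV by default), UTF-8, with a
header row.  Required columns::

    chem_id, log_kow, log_kaw, t_half_air_h, t_half_water_h, t_half_soil_h

Optional columns: ``name, formula, smiles, pka, pkb, log_baf,
km_per_day``.  Half-lives are hours; partition ratios log10; ``log_baf``
is an externally estimated log10 BAF override in L/kg; ``km_per_day`` is
the whole-body biotransformation rate.  Unknown columns are preserved and
passed through to the scored output.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .records import ChemicalRecord, InvalidRecordError

REQUIRED_COLUMNS = (
    "chem_id",
    "log_kow",
    "log_kaw",
    "t_half_air_h",
    "t_half_water_h",
    "t_half_soil_h",
)
OPTIONAL_COLUMNS = (
    "name",
    "formula",
    "smiles",
    "pka",
    "pkb",
    "log_baf",
    "km_per_day",
)


class SchemaError(ValueError):
    """Input table violates the column contract."""


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def table_to_records(
    df: pd.DataFrame,
) -> Tuple[List[ChemicalRecord], List[Tuple[str, str]]]:
    """Typed records from a schema-conforming DataFrame.

    Returns (records, row_errors); rows that fail validation are reported
    as (chem_id, message) rather than aborting the batch.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: List[ChemicalRecord] = []
    errors: List[Tuple[str, str]] = []
    for _, row in df.iterrows():
        cid = str(row["chem_id"])
        try:
            records.append(
                ChemicalRecord(
                    chem_id=cid,
                    name=_opt_str(row.get("name")) or "",
                    formula=_opt_str(row.get("formula")),
                    smiles=_opt_str(row.get("smiles")),
                    log_kow=float(row["log_kow"]),
                    log_kaw=float(row["log_kaw"]),
                    t_half_air=float(row["t_half_air_h"]),
                    t_half_water=float(row["t_half_water_h"]),
                    t_half_soil=float(row["t_half_soil_h"]),
                    pka=_opt_float(row.get("pka")),
                    pkb=_opt_float(row.get("pkb")),
                    log_baf_override=_opt_float(row.get("log_baf")),
                    k_biotransform=_opt_float(row.get("km_per_day")),
                )
            )
        except (InvalidRecordError, TypeError, ValueError) as exc:
            errors.append((cid, str(exc)))
    return records, errors


def records_to_table(records: Sequence[ChemicalRecord]) -> pd.DataFrame:
    """DataFrame in the on-disk column schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "chem_id": r.chem_id,
                "name": r.name,
                "formula": r.formula,
                "smiles": r.smiles,
                "log_kow": r.log_kow,
                "log_kaw": r.log_kaw,
                "t_half_air_h": r.t_half_air,
                "t_half_water_h": r.t_half_water,
                "t_half_soil_h": r.t_half_soil,
                "pka": r.pka,
                "pkb": r.pkb,
                "log_baf": r.log_baf_override,
                "km_per_day": r.k_biotransform,
                "flags": ";".join(r.flags),
            }
        )
    cols = list(REQUIRED_COLUMNS[:1]) + ["name", "formula", "smiles"] + [
        "log_kow", "log_kaw", "t_half_air_h", "t_half_water_h",
        "t_half_soil_h", "pka", "pkb", "log_baf", "km_per_day", "flags",
    ]
    return pd.DataFrame(rows, columns=cols)


def read_chemical_table(
    path, sep: str = ","
) -> Tuple[List[ChemicalRecord], pd.DataFrame]:
    """Read a chemical table; returns (records, original DataFrame).

    The DataFrame keeps every input column (including unknown passthrough
    columns) so downstream writers can merge results back onto it.
    """
    df = pd.read_csv(path, sep=sep, comment="#", encoding="utf-8")
    records, errors = table_to_records(df)
    if errors:
        import logging

        log = logging.getLogger(__name__)
        for cid, msg in errors:
            log.warning("row %s rejected: %s", cid, msg)
        bad = {cid for cid, _ in errors}
        df = df[~df["chem_id"].astype(str).isin(bad)].reset_index(drop=True)
    df.attrs["row_errors"] = errors
    return records, df


def write_chemical_table(records: Sequence[ChemicalRecord], path, sep: str = ",") -> None:
    records_to_table(records).to_csv(path, sep=sep, index=False, encoding="utf-8")


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False, encoding="utf-8")
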