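"""Schema and invariant checks for the four standard pipeline tables.

CSV dialect is pinned: UTF-8, comma separated, '.' decimal, ISO-8601
dates, header row.  Violations are collected as structured records
naming file, row, and column; report mode never raises.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Violation", "validate_tables", "read_table", "TABLE_SCHEMAS"]

TABLE_SCHEMAS: dict[str, list[str]] = {
    "temperature": ["date", "temp_c"],
    "fish": ["fish_id", "year", "month", "class", "site", "haul",
             "sl_mm", "mass_g", "liver_g"],
    "otolith": ["fish_id", "increment_index", "radius_um", "radius_at_capture_um"],
    "stomach": ["fish_id", "prey_taxon", "count", "weight_mg",
                "stomach_total_g", "fish_total_g"],
    "hauls": ["year", "month", "site", "haul_id", "n_cod"],
}


@dataclass
class Violation:
    table: str
    row: int | None
    column: str | None
    message: str

    def __str__(self) -> str:
        loc = f"{self.table}"
        if self.row is not None:
            loc += f" row {self.row}"
        if self.column:
            loc += f" column {self.column}"
        return f"{loc}: {self.message}"


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    missing = set(TABLE_SCHEMAS[kind]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def _check_positive(df, table, col, strict, out):
    bad = df[col] <= 0 if strict else df[col] < 0
    bad = bad.fillna(False)
    for i in df.index[bad]:
        out.append(Violation(table, int(i) + 2, col,  # +2: header + 1-based
                             f"value {df.at[i, col]} must be "
                             f"{'> 0' if strict else '>= 0'}"))


def validate_tables(paths: dict[str, str | Path]) -> list[Violation]:
    """Validate any subset of the standard tables; returns all violations."""
    out: list[Violation] = []
    for kind, path in paths.items():
        if kind not in TABLE_SCHEMAS:
            out.append(Violation(str(path), None, None, f"unknown table kind {kind!r}"))
            continue
        try:
            df = read_table(path, kind)
        except Exception as exc:  # noqa: BLE001
            out.append(Violation(str(path), None, None, str(exc)))
            continue
        if kind == "temperature":
            dates = pd.to_datetime(df["date"], errors="coerce")
            for i in df.index[dates.isna()]:
                out.append(Violation(kind, int(i) + 2, "date", "unparseable date"))
            if dates.notna().all() and not dates.is_monotonic_increasing:
                out.append(Violation(kind, None, "date", "dates not increasing"))
        elif kind == "fish":
            for col in ("sl_mm", "mass_g"):
                _check_positive(df, kind, col, True, out)
            _check_positive(df, kind, "liver_g", False, out)
            heavy = (df["liver_g"] >= df["mass_g"]).fillna(False)
            for i in df.index[heavy]:
                out.append(Violation(kind, int(i) + 2, "liver_g",
                                     "liver mass not below body mass"))
        elif kind == "otolith":
            _check_positive(df, kind, "radius_um", True, out)
            for fid, grp in df.groupby("fish_id"):
                radii = grp.sort_values("increment_index")["radius_um"].to_numpy()
                if np.any(np.diff(radii) <= 0):
                    bad_pos = int(grp.index[np.argmin(np.r_[1.0, np.diff(radii)])])
                    out.append(Violation(kind, bad_pos + 2, "radius_um",
                                         f"fish {fid}: radii not strictly increasing"))
        elif kind == "stomach":
            _check_positive(df, kind, "weight_mg", False, out)
            _check_positive(df, kind, "count", False, out)
        elif kind == "hauls":
            _check_positive(df, kind, "n_cod", False, out)
    return out
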