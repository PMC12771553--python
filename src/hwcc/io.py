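"""Delimited-text readers/writers with validation, plus gridded extraction.

All tables are plain CSV with a header row and ISO-8601 dates. Readers
validate the schema (missing or unexpected columns fail, naming the file and
column) and basic domain invariants (non-negative integer counts, tmin <=
tmax), reporting the offending line. Writers use pandas' shortest-roundtrip
float formatting, so write-then-read reproduces values exactly for strings
and integers and to full precision for reals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import SUBGROUP_ATTRIBUTES

CLIMATE_REQUIRED = ["location_id", "date", "tmax", "tmin"]
CLIMATE_OPTIONAL = ["rh"]
HEALTH_REQUIRED = ["location_id", "date", "cause", "count"]
HEALTH_OPTIONAL = list(SUBGROUP_ATTRIBUTES)
EXPOSURE_COLUMNS = ["location_id", "date", "dhwi", "nhwi", "dhw_flag", "nhw_flag"]


class TableFormatError(ValueError):
    """Raised when an input table violates its schema or invariants."""


def _check_columns(df: pd.DataFrame, required, optional, path) -> None:
    cols = list(df.columns)
    missing = [c for c in required if c not in cols]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    extra = [c for c in cols if c not in required + list(optional)]
    if extra:
        raise TableFormatError(f"{path}: unexpected column(s) {extra}")


def _parse_dates(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise TableFormatError(
            f"{path}: unparseable ISO date in column 'date' ({exc})"
        ) from exc
    return df


def read_climate(path: str | Path) -> pd.DataFrame:
    """Read and validate a daily climate table (location_id, date, tmax, tmin[, rh])."""
    df = pd.read_csv(path)
    _check_columns(df, CLIMATE_REQUIRED, CLIMATE_OPTIONAL, path)
    df = _parse_dates(df, path)
    bad = df["tmin"] > df["tmax"]
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        r = df.iloc[i]
        raise TableFormatError(
            f"{path}: tmin > tmax at line {i + 2} "
            f"(location {r['location_id']}, date {r['date'].date()})"
        )
    return df


def read_health(path: str | Path) -> pd.DataFrame:
    """Read and validate a daily health-count table."""
    df = pd.read_csv(path)
    _check_columns(df, HEALTH_REQUIRED, HEALTH_OPTIONAL, path)
    df = _parse_dates(df, path)
    counts = df["count"]
    if not pd.api.types.is_integer_dtype(counts):
        raise TableFormatError(f"{path}: column 'count' must be integer")
    if (counts < 0).any():
        i = int(np.flatnonzero(counts < 0)[0])
        raise TableFormatError(
            f"{path}: negative count at line {i + 2}, column 'count'"
        )
    return df


def read_exposure(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, EXPOSURE_COLUMNS, ["rh"], path)
    return _parse_dates(df, path)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any result table as CSV with ISO dates."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def write_panel(panel: pd.DataFrame, path: str | Path) -> Path:
    """Write an analysis panel with the stratum key serialized as loc|year|month|weekday."""
    from .design import stratum_id

    out = panel.copy()
    out["stratum"] = stratum_id(out)
    return write_table(out, path)


def read_panel(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _parse_dates(df, path)
    if "stratum" in df.columns and "year" not in df.columns:
        parts = df["stratum"].str.split("|", expand=True)
        df["year"] = parts[1].astype(int)
        df["month"] = parts[2].astype(int)
        df["weekday"] = parts[3].astype(int)
    return df


def extract_gridded(dataset, mapping: pd.DataFrame) -> pd.DataFrame:
    """Extract per-location daily series from a gridded climate dataset.

    ``dataset`` is an xarray Dataset with variables ``tmax``/``tmin`` over
    dims (time, cell); ``mapping`` has columns location_id and cell (the
    integer index of the grid cell assigned to each location, e.g. the cell
    containing its population-weighted centroid). Returns a tabular climate
    frame in the standard schema.
    """
    frames = []
    for loc, cell in zip(mapping["location_id"], mapping["cell"]):
        sel = dataset.isel(cell=int(cell))
        frames.append(
            pd.DataFrame(
                {
                    "location_id": loc,
                    "date": pd.to_datetime(sel["time"].values),
                    "tmax": np.asarray(sel["tmax"].values, dtype=float),
                    "tmin": np.asarray(sel["tmin"].values, dtype=float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def effects_table(effects) -> pd.DataFrame:
    """Flatten EffectEstimate objects into a results frame."""
    rows = []
    for e in effects:
        rows.append(
            {
                "label": e.label,
                "beta": e.beta,
                "se_beta": e.se_beta,
                "percent_change": e.percent_change,
                "se_percent": e.se_percent,
                "ci_low": e.ci95[0],
                "ci_high": e.ci95[1],
                "p_value": e.p_value,
            }
        )
    return pd.DataFrame(rows)


def comparisons_table(results, m: int | None = None) -> pd.DataFrame:
    """Flatten HeterogeneityResult objects, with Bonferroni family size m."""
    from .heterogeneity import bonferroni_adjust

    rows = []
    for r in results:
        rows.append(
            {
                "label_1": r.label_1,
                "label_2": r.label_2,
                "d": r.d,
                "se_d": r.se_d,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "z": r.z,
                "p_value": r.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        fam = m if m is not None else len(out)
        out["m"] = fam
        out["p_bonferroni"] = bonferroni_adjust(out["p_value"].tolist(), fam)
    return out
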