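"""Time-stratified case-crossover design: strata and analysis panels.

Every warm-season day is assigned to a stratum (location, year, month, ISO
weekday). Days sharing a stratum are mutual case/control days: within a
calendar month of a given year and location, a day is compared only with the
other days falling on the same day of the week, which by construction number
3-4 (so each stratum holds 4 or 5 days). Conditioning on the stratum removes
confounding by factors that are stable within a month.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import pandas as pd

STRATUM_COLS = ["location_id", "year", "month", "weekday"]

SUBGROUP_ATTRIBUTES = ("sex", "age_group", "race_ethnicity", "region_flag")


def add_stratum_keys(df: pd.DataFrame, date_col: str = "date") -> pd.DataFrame:
    """Attach year/month/weekday stratum columns (ISO weekday, Monday=1)."""
    out = df.copy()
    dates = pd.to_datetime(out[date_col])
    out["year"] = dates.dt.year
    out["month"] = dates.dt.month
    out["weekday"] = dates.dt.dayofweek + 1
    return out


def build_strata(
    dates: Sequence, locations: Sequence | None = None
) -> pd.DataFrame:
    """Map date (x location) to its stratum key."""
    frame = pd.DataFrame({"date": pd.to_datetime(pd.Index(dates))})
    if locations is not None:
        frame = frame.merge(
            pd.DataFrame({"location_id": list(locations)}), how="cross"
        )
    else:
        frame["location_id"] = "all"
    out = add_stratum_keys(frame)
    return out[["location_id", "date", "year", "month", "weekday"]]


def stratum_id(df: pd.DataFrame) -> pd.Series:
    """Serialized stratum label location|year|month|weekday."""
    return (
        df["location_id"].astype(str)
        + "|" + df["year"].astype(str)
        + "|" + df["month"].astype(str)
        + "|" + df["weekday"].astype(str)
    )


def filter_subgroup(
    health: pd.DataFrame, selection: Mapping[str, object]
) -> pd.DataFrame:
    """Restrict health records to attribute level(s); counts untouched.

    ``selection`` maps attribute name to a level or list of levels; multiple
    attributes select their intersection. Unknown attributes or levels raise
    ``ValueError`` naming the valid choices.
    """
    out = health
    for attr, level in selection.items():
        if attr not in out.columns:
            raise ValueError(
                f"attribute {attr!r} not in health records; available: "
                f"{[c for c in out.columns if c in SUBGROUP_ATTRIBUTES]}"
            )
        levels = [level] if isinstance(level, str) else list(level)
        valid = set(out[attr].dropna().unique())
        unknown = [l for l in levels if l not in valid]
        if unknown:
            raise ValueError(
                f"unknown level(s) {unknown} for {attr!r}; valid levels: {sorted(valid)}"
            )
        out = out[out[attr].isin(levels)]
    return out.copy()


def assemble_panel(
    health: pd.DataFrame,
    exposure: pd.DataFrame,
    cause: str | None = None,
    subgroup: Mapping[str, object] | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Zero-filled stratified panel for one cause/subgroup slice.

    Every location-day covered by ``exposure`` appears exactly once, with
    count 0 where no events occurred. Health records dated outside exposure
    coverage raise ``ValueError`` (listing offending location-days). Rows with
    missing exposure are dropped; their number is recorded in
    ``panel.attrs['n_dropped_days']``.
    """
    h = health.copy()
    h["date"] = pd.to_datetime(h["date"])
    if cause is not None:
        if "cause" not in h.columns:
            raise ValueError("health records have no 'cause' column")
        h = h[h["cause"] == cause]
    if subgroup:
        h = filter_subgroup(h, subgroup)

    exp = exposure.copy()
    exp["date"] = pd.to_datetime(exp["date"])
    counts = (
        h.groupby(["location_id", "date"], as_index=False)["count"].sum()
        if not h.empty
        else pd.DataFrame(columns=["location_id", "date", "count"])
    )
    if not counts.empty:
        covered = exp.set_index(["location_id", "date"]).index
        idx = counts.set_index(["location_id", "date"]).index
        outside = counts[~idx.isin(covered)]
        if not outside.empty:
            sample = [
                f"{r.location_id}@{r.date.date()}" for r in outside.head(10).itertuples()
            ]
            raise ValueError(
                f"{len(outside)} health record day(s) outside exposure coverage: "
                + ", ".join(sample)
            )

    panel = exp.merge(counts, on=["location_id", "date"], how="left")
    panel["count"] = panel["count"].fillna(0).astype(int)
    n_before = len(panel)
    panel = panel.dropna(subset=["dhwi", "nhwi"]).reset_index(drop=True)
    if covariates is not None:
        cov = covariates.copy()
        cov["date"] = pd.to_datetime(cov["date"])
        panel = panel.merge(cov, on=["location_id", "date"], how="left")
    panel = add_stratum_keys(panel)
    panel.attrs["n_dropped_days"] = n_before - len(panel)
    panel.attrs["cause"] = cause
    panel.attrs["subgroup"] = dict(subgroup) if subgroup else None
    return panel
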