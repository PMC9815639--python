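"""Per-pig per-day observations derived from raw feeder visits.

Three variables are computed for every pig and calendar day:

* ``dfv`` — number of feeder visits whose entry time falls within the day
  (00:00:00–23:59:59);
* ``dfc`` — total feed consumed over those visits, grams;
* ``stdfc`` — sample standard deviation (n−1 denominator) of the
  per-visit intakes, grams; undefined (missing) with fewer than 2 visits.

A visit belongs to the day of its *entry* time; visits spanning midnight
are not split.  Roster days with no visits are real observations
``(0, 0, missing)`` unless the day is listed as a recorder gap, in which
case all three values are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IntegrityError
from .io import FeederDataset

OBS_COLUMNS = ["pen_id", "pig_id", "date", "dfv", "dfc", "stdfc"]
VARIABLES = ("dfv", "dfc", "stdfc")


def daily_observations(data: FeederDataset, zero_day: str = "observed") -> pd.DataFrame:
    """One row per (pig, roster day) with the three daily variables.

    ``zero_day`` controls the dialect for roster days without visits:
    ``'observed'`` (default) records them as ``(0, 0, missing)``;
    ``'missing'`` records all three values as missing, for feeds where an
    empty day cannot be told apart from an outage.
    """
    if zero_day not in ("observed", "missing"):
        raise ValueError("zero_day must be 'observed' or 'missing'")
    roster = data.roster
    if roster.empty:
        return pd.DataFrame(columns=OBS_COLUMNS)

    visits = data.visits.copy()
    if len(visits):
        visits["date"] = pd.to_datetime(visits["date"])
        _check_integrity(visits, roster)

    # expand roster intervals into pig-days
    frames = []
    for row in roster.itertuples(index=False):
        days = pd.date_range(row.first_day, row.last_day, freq="D")
        frames.append(
            pd.DataFrame({"pen_id": row.pen_id, "pig_id": row.pig_id, "date": days})
        )
    grid = pd.concat(frames, ignore_index=True)
    # a pig may have several roster intervals; keep unique pig-days
    grid = grid.drop_duplicates(["pen_id", "pig_id", "date"])

    if len(visits):
        agg = (
            visits.groupby(["pen_id", "pig_id", "date"])["feed_g"]
            .agg(dfv="count", dfc="sum", stdfc=lambda s: s.std(ddof=1))
            .reset_index()
        )
    else:
        agg = pd.DataFrame(columns=["pen_id", "pig_id", "date", "dfv", "dfc", "stdfc"])

    obs = grid.merge(agg, on=["pen_id", "pig_id", "date"], how="left")
    obs["dfv"] = obs["dfv"].fillna(0).astype(float)
    obs["dfc"] = obs["dfc"].fillna(0.0)

    if len(data.gaps):
        gaps = data.gaps.copy()
        gaps["date"] = pd.to_datetime(gaps["date"])
        gap_idx = obs.merge(
            gaps.assign(_gap=1), on=["pen_id", "pig_id", "date"], how="left"
        )["_gap"].notna()
        obs.loc[gap_idx.to_numpy(), ["dfv", "dfc", "stdfc"]] = np.nan

    if zero_day == "missing":
        empty = obs["dfv"] == 0
        obs.loc[empty, ["dfv", "dfc", "stdfc"]] = np.nan

    return obs.sort_values(["pen_id", "pig_id", "date"]).reset_index(drop=True)[OBS_COLUMNS]


def _check_integrity(visits: pd.DataFrame, roster: pd.DataFrame) -> None:
    """Every visit must reference a rostered pig on a day it was present."""
    known = roster.groupby(["pen_id", "pig_id"]).agg(
        first=("first_day", "min"), last=("last_day", "max")
    )
    keys = pd.MultiIndex.from_frame(visits[["pen_id", "pig_id"]])
    unknown = ~keys.isin(known.index)
    if unknown.any():
        bad = visits[unknown].iloc[0]
        raise IntegrityError(
            f"visit references unknown pig: pen={bad['pen_id']} pig={bad['pig_id']} "
            f"date={bad['date'].date()}"
        )
    spans = known.loc[keys]
    out = (visits["date"].to_numpy() < spans["first"].to_numpy()) | (
        visits["date"].to_numpy() > spans["last"].to_numpy()
    )
    if out.any():
        bad = visits[out].iloc[0]
        raise IntegrityError(
            f"visit outside pig's roster span: pen={bad['pen_id']} pig={bad['pig_id']} "
            f"date={bad['date'].date()}"
        )


def observation_summary(
    obs: pd.DataFrame,
    pens: pd.DataFrame,
    by: str = "window_class",
    tb_window: tuple[int, int] = (-35, 10),
) -> pd.DataFrame:
    """Mean/SD of each daily variable per group, with group sizes.

    ``by`` is one of ``'herd'``, ``'status'`` or ``'window_class'``; the
    last reproduces the layout of per-herd TB-vs-CTL day-class contrasts
    (a day of a TB pen counts as class TB when it lies inside the TB
    window around the pen's TB date).  Statistics are over non-missing
    values; an SD over fewer than two values is missing.
    """
    if obs.empty:
        raise ValueError("observation table is empty")
    merged = obs.merge(
        pens[["pen_id", "herd_id", "status", "tb_date"]], on="pen_id", how="left"
    )
    if by == "herd":
        keys = ["herd_id"]
    elif by == "status":
        keys = ["herd_id", "status"]
    elif by == "window_class":
        rel = (pd.to_datetime(merged["date"]) - pd.to_datetime(merged["tb_date"])).dt.days
        in_win = (merged["status"] == "TB") & rel.between(tb_window[0], tb_window[1])
        merged["day_class"] = np.where(in_win, "TB", "CTL")
        keys = ["herd_id", "day_class"]
    else:
        raise ValueError(f"unknown grouping {by!r}")

    rows = []
    for group, sub in merged.groupby(keys, dropna=False):
        if not isinstance(group, tuple):
            group = (group,)
        rec: dict = dict(zip(keys, group))
        rec["n_days"] = len(sub)
        for var in VARIABLES:
            vals = sub[var].dropna()
            rec[f"{var}_mean"] = vals.mean() if len(vals) else np.nan
            rec[f"{var}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(rec)
    return pd.DataFrame(rows).sort_values(keys).reset_index(drop=True)


def write_observations_csv(obs: pd.DataFrame, path: str) -> None:
    out = obs.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out["dfv"] = out["dfv"].map(lambda v: "" if pd.isna(v) else f"{v:.0f}")
    for col in ("dfc", "stdfc"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    out.to_csv(path, index=False)


def read_observations_csv(path: str) -> pd.DataFrame:
    obs = pd.read_csv(path, dtype={"pen_id": str, "pig_id": str}, parse_dates=["date"])
    for col in ("dfv", "dfc", "stdfc"):
        obs[col] = pd.to_numeric(obs[col], errors="coerce")
    return obs[OBS_COLUMNS]
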