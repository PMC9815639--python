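"""Dataset container and CSV round-tripping for feeder event logs.

All interchange is plain CSV with ISO-8601 dates (``YYYY-MM-DD``) and
``HH:MM:SS`` times, matching what electronic-feeder exports look like in
practice.  The four tables are:

``visits``
    one row per feeder entry/exit event:
    ``pen_id,pig_id,date,entry_time,exit_time,feed_g``
``pens``
    pen metadata: ``pen_id,herd_id,status,tb_date,rec_start,rec_end``
    (``tb_date`` empty for control pens)
``roster``
    pig presence intervals: ``pen_id,pig_id,first_day,last_day``
``gaps``
    recorder outages: ``pen_id,pig_id,date`` — days on which the pig was
    present but the feeder recorded nothing, so the day is *missing*
    rather than "zero visits".
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

VISIT_COLUMNS = ["pen_id", "pig_id", "date", "entry_time", "exit_time", "feed_g"]
PEN_COLUMNS = ["pen_id", "herd_id", "status", "tb_date", "rec_start", "rec_end"]
ROSTER_COLUMNS = ["pen_id", "pig_id", "first_day", "last_day"]
GAP_COLUMNS = ["pen_id", "pig_id", "date"]


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class FeederDataset:
    """In-memory feeder data: visits plus pen metadata, roster and gaps."""

    visits: pd.DataFrame
    pens: pd.DataFrame
    roster: pd.DataFrame
    gaps: pd.DataFrame = field(default_factory=lambda: _empty(GAP_COLUMNS))

    def __post_init__(self) -> None:
        for name, cols in (
            ("visits", VISIT_COLUMNS),
            ("pens", PEN_COLUMNS),
            ("roster", ROSTER_COLUMNS),
            ("gaps", GAP_COLUMNS),
        ):
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table missing columns {missing}")

    @staticmethod
    def concat(parts: list["FeederDataset"]) -> "FeederDataset":
        def cat(attr: str, cols: list[str]) -> pd.DataFrame:
            frames = [getattr(p, attr) for p in parts if len(getattr(p, attr))]
            if not frames:
                return _empty(cols)
            return pd.concat(frames, ignore_index=True)

        return FeederDataset(
            visits=cat("visits", VISIT_COLUMNS),
            pens=cat("pens", PEN_COLUMNS),
            roster=cat("roster", ROSTER_COLUMNS),
            gaps=cat("gaps", GAP_COLUMNS),
        )

    # ------------------------------------------------------------------ CSV
    def write_csv(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        visits = self.visits.copy()
        if len(visits):
            visits["date"] = pd.to_datetime(visits["date"]).dt.strftime("%Y-%m-%d")
            visits["feed_g"] = visits["feed_g"].map(lambda v: f"{v:.1f}")
        visits.to_csv(os.path.join(directory, "visits.csv"), index=False)

        pens = self.pens.copy()
        for col in ("tb_date", "rec_start", "rec_end"):
            pens[col] = pd.to_datetime(pens[col]).dt.strftime("%Y-%m-%d")
        pens["tb_date"] = pens["tb_date"].fillna("")
        pens.to_csv(os.path.join(directory, "pens.csv"), index=False)

        roster = self.roster.copy()
        for col in ("first_day", "last_day"):
            roster[col] = pd.to_datetime(roster[col]).dt.strftime("%Y-%m-%d")
        roster.to_csv(os.path.join(directory, "roster.csv"), index=False)

        gaps = self.gaps.copy()
        if len(gaps):
            gaps["date"] = pd.to_datetime(gaps["date"]).dt.strftime("%Y-%m-%d")
        gaps.to_csv(os.path.join(directory, "gaps.csv"), index=False)

    @staticmethod
    def read_csv(directory: str) -> "FeederDataset":
        visits = pd.read_csv(
            os.path.join(directory, "visits.csv"),
            dtype={"pen_id": str, "pig_id": str},
            parse_dates=["date"],
        )
        pens = pd.read_csv(
            os.path.join(directory, "pens.csv"),
            dtype={"pen_id": str, "herd_id": str, "status": str},
            parse_dates=["tb_date", "rec_start", "rec_end"],
        )
        roster = pd.read_csv(
            os.path.join(directory, "roster.csv"),
            dtype={"pen_id": str, "pig_id": str},
            parse_dates=["first_day", "last_day"],
        )
        gaps_path = os.path.join(directory, "gaps.csv")
        if os.path.exists(gaps_path):
            gaps = pd.read_csv(
                gaps_path, dtype={"pen_id": str, "pig_id": str}, parse_dates=["date"]
            )
        else:
            gaps = _empty(GAP_COLUMNS)
        return FeederDataset(visits=visits, pens=pens, roster=roster, gaps=gaps)
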