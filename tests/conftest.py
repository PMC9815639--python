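import numpy as np
import pandas as pd
import pytest

import penwatch as pw
from penwatch.io import FeederDataset


def make_visits(rows):
    """rows: (pen_id, pig_id, date, entry_time, feed_g)"""
    return pd.DataFrame(
        [
            {
                "pen_id": p, "pig_id": q, "date": pd.Timestamp(d),
                "entry_time": t, "exit_time": t, "feed_g": float(g),
            }
            for p, q, d, t, g in rows
        ]
    )


@pytest.fixture
def tiny_dataset():
    """Two pens (one TB, one CTL), two pigs each, 20 recorded days."""
    rec_start, rec_end = pd.Timestamp("2019-01-01"), pd.Timestamp("2019-01-20")
    pens = pd.DataFrame(
        [
            {"pen_id": "pA", "herd_id": "h1", "status": "TB",
             "tb_date": pd.Timestamp("2019-01-10"), "rec_start": rec_start, "rec_end": rec_end},
            {"pen_id": "pB", "herd_id": "h1", "status": "CTL",
             "tb_date": pd.NaT, "rec_start": rec_start, "rec_end": rec_end},
        ]
    )
    roster = pd.DataFrame(
        [
            {"pen_id": pen, "pig_id": f"{pen}_{i}", "first_day": rec_start, "last_day": rec_end}
            for pen in ("pA", "pB")
            for i in (1, 2)
        ]
    )
    rng = np.random.default_rng(0)
    rows = []
    for pen in ("pA", "pB"):
        for i in (1, 2):
            for day in pd.date_range(rec_start, rec_end):
                for _ in range(int(rng.integers(1, 4))):
                    rows.append(
                        (pen, f"{pen}_{i}", day, "08:00:00", float(rng.uniform(100, 400)))
                    )
    return FeederDataset(visits=make_visits(rows), pens=pens, roster=roster)


@pytest.fixture(scope="session")
def sim_dataset():
    """Small simulated herd with default drift (2 TB + 2 CTL pens)."""
    profile = pw.scaled_profile(
        pw.swedish_profile(), n_pens=4, tb_pen_count=2, halfspan=35, pigs_per_pen=(10, 12)
    )
    return pw.simulate_herd(profile, pw.DriftModel(), missing_rate=0.02, seed=42)


@pytest.fixture(scope="session")
def sim_observations(sim_dataset):
    return pw.daily_observations(sim_dataset)
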