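"""Synthetic multi-pen feeder event-log generator.

Emulates per-visit records from single-space electronic feeders in
grower-finisher pig pens, at the statistical resolution the downstream
analysis consumes: per-pig daily visit counts (DFV), daily intake (DFC)
and within-day per-visit intake dispersion (StdFC).

The generative model, per pig-day:

* each pig carries log-normal baseline multipliers (mean 1) for its visit
  rate, intake level and intake dispersion — persistent between-pig
  heterogeneity within a pen;
* the visit count is gamma-mixed Poisson (negative binomial), with the
  gamma shape chosen so that the *marginal* count SD matches the herd
  profile (daily visit counts in feeder data are strongly over-dispersed,
  SD of the order of the mean);
* given ``n`` visits, per-visit intakes are gamma draws whose expected
  daily total is the pig-day's DFC target and whose per-visit SD is the
  pig-day's StdFC target.

Pens flagged for a tail-biting (TB) outbreak carry a behavioural drift:
from a configurable onset day the expected DFV/DFC/StdFC are scaled by
multipliers ramping to their day-0 values, then relaxing back to baseline
over a recovery period.  Control pens never drift.  The drift magnitudes
are synthetic stand-ins — calibrated to be plausible against reports of
depressed feeder visiting weeks before outbreaks — not measured effect
sizes; see ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import FeederDataset, GAP_COLUMNS, PEN_COLUMNS, ROSTER_COLUMNS, VISIT_COLUMNS, _empty

#: coefficient of variation of the between-pig log-normal baseline
#: multipliers, per variable.  Visit frequency is a fairly stable
#: individual trait that differs several-fold between pigs, so most of a
#: herd's marginal DFV spread is attributed here; intake level tracks
#: body size and varies less.  Documented constants, not fit to anything.
BETWEEN_PIG_CV = {"dfv": 0.50, "dfc": 0.20, "stdfc": 0.25}

#: coefficient of variation of the between-pen log-normal baseline
#: multipliers.  Pens have idiosyncratic behavioural levels (feeder
#: placement, group dynamics, batch effects); this is what makes a
#: never-seen pen genuinely harder to classify than a pen whose history
#: is in the training data.
BETWEEN_PEN_CV = {"dfv": 0.20, "dfc": 0.15, "stdfc": 0.15}

#: day-level CV of a pig's daily intake around its expectation; daily
#: totals are much more stable than visit counts.
DAY_CV_DFC = 0.12

#: floor on the day-level count variance, as a multiple of the mean, so the
#: gamma-Poisson mixture never degenerates below Poisson dispersion.
_MIN_OVERDISPERSION = 1.05

DEFAULT_START_DATE = pd.Timestamp("2019-01-01")


@dataclass(frozen=True)
class HerdProfile:
    """Marginal daily-behaviour statistics of one herd.

    ``dfv`` is visits/pig/day, ``dfc`` grams/pig/day, ``stdfc`` the
    within-day SD of per-visit intake in grams.  Means and SDs are the
    *marginal* per-pig-day moments the generator targets.
    """

    herd_id: str
    n_pens: int
    pigs_per_pen: tuple[int, int]
    recording_halfspan_days: int
    dfc_mean: float
    dfc_sd: float
    dfv_mean: float
    dfv_sd: float
    stdfc_mean: float
    stdfc_sd: float
    tb_pen_count: int

    def __post_init__(self) -> None:
        if self.n_pens < 0:
            raise ConfigurationError("n_pens must be >= 0")
        if self.tb_pen_count < 0 or self.tb_pen_count > self.n_pens:
            raise ConfigurationError("tb_pen_count must be in [0, n_pens]")
        lo, hi = self.pigs_per_pen
        if not (1 <= lo <= hi <= 60):
            raise ConfigurationError("pigs_per_pen range must lie within [1, 60]")
        if self.recording_halfspan_days < 1:
            raise ConfigurationError("recording_halfspan_days must be >= 1")
        for name in ("dfc_mean", "dfc_sd", "dfv_mean", "dfv_sd", "stdfc_mean", "stdfc_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def span_days(self) -> int:
        return 2 * self.recording_halfspan_days + 1

    def visit_count_shape(self) -> float:
        """Gamma shape of the mixed-Poisson visit count.

        Derived once at profile level so that the structured variance
        (between-pig + between-pen baselines) plus the day-level
        negative-binomial variance approximates the configured marginal
        SD; the same shape is reused under drift so dispersion scales
        with the mean.
        """
        m = self.dfv_mean
        cv2 = (
            (1 + BETWEEN_PIG_CV["dfv"] ** 2) * (1 + BETWEEN_PEN_CV["dfv"] ** 2) - 1
        )
        structured = m**2 * cv2
        v_day = max(self.dfv_sd**2 - structured, _MIN_OVERDISPERSION * m)
        if v_day <= m:
            return math.inf  # effectively Poisson
        return m**2 / (v_day - m)


@dataclass(frozen=True)
class DriftModel:
    """Pre-outbreak behavioural drift applied to TB pens.

    Multipliers scale the pig-day *expected* DFV/DFC/StdFC; 1.0 means no
    change.  ``shape='linear_ramp'`` interpolates from 1 at ``onset_day``
    to the day-0 value; ``'step'`` jumps to the day-0 value at onset.
    After day 0 the multipliers relax linearly back to 1 over
    ``post_day0_recovery_days``.
    """

    onset_day: int = -42
    dfv_multiplier_at_day0: float = 0.7
    dfc_multiplier_at_day0: float = 0.85
    stdfc_multiplier_at_day0: float = 0.85
    shape: str = "linear_ramp"
    post_day0_recovery_days: int = 14

    def __post_init__(self) -> None:
        if self.onset_day >= 0:
            raise ConfigurationError("onset_day must be < 0 (before the TB date)")
        for name in (
            "dfv_multiplier_at_day0",
            "dfc_multiplier_at_day0",
            "stdfc_multiplier_at_day0",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.shape not in ("linear_ramp", "step"):
            raise ConfigurationError("shape must be 'linear_ramp' or 'step'")
        if self.post_day0_recovery_days < 0:
            raise ConfigurationError("post_day0_recovery_days must be >= 0")

    def multipliers(self, day_rel: int) -> tuple[float, float, float]:
        """(DFV, DFC, StdFC) multipliers at ``day_rel`` days from day 0."""
        targets = (
            self.dfv_multiplier_at_day0,
            self.dfc_multiplier_at_day0,
            self.stdfc_multiplier_at_day0,
        )
        if day_rel < self.onset_day:
            return (1.0, 1.0, 1.0)
        if day_rel <= 0:
            if self.shape == "step":
                return targets
            frac = (day_rel - self.onset_day) / (-self.onset_day)
            return tuple(1.0 + frac * (t - 1.0) for t in targets)  # type: ignore[return-value]
        if self.post_day0_recovery_days == 0 or day_rel >= self.post_day0_recovery_days:
            return (1.0, 1.0, 1.0)
        frac = day_rel / self.post_day0_recovery_days
        return tuple(t + frac * (1.0 - t) for t in targets)  # type: ignore[return-value]


#: null drift — TB pens behave exactly like control pens.
NULL_DRIFT = DriftModel(
    onset_day=-42,
    dfv_multiplier_at_day0=1.0,
    dfc_multiplier_at_day0=1.0,
    stdfc_multiplier_at_day0=1.0,
)


def swedish_profile(**overrides) -> HerdProfile:
    """Default Swedish-herd-like profile (boar station, ±70 d recording)."""
    base = dict(
        herd_id="swedish",
        n_pens=42,
        pigs_per_pen=(7, 14),
        recording_halfspan_days=70,
        dfc_mean=2337.1,
        dfc_sd=757.4,
        dfv_mean=24.9,
        dfv_sd=19.4,
        stdfc_mean=128.6,
        stdfc_sd=85.9,
        tb_pen_count=21,
    )
    base.update(overrides)
    return HerdProfile(**base)


def swiss_profile(**overrides) -> HerdProfile:
    """Default Swiss-herd-like profile (experimental farm, ±100 d recording)."""
    base = dict(
        herd_id="swiss",
        n_pens=23,
        pigs_per_pen=(11, 55),
        recording_halfspan_days=100,
        dfc_mean=2282.3,
        dfc_sd=600.2,
        dfv_mean=12.3,
        dfv_sd=6.0,
        stdfc_mean=166.8,
        stdfc_sd=96.3,
        tb_pen_count=6,
    )
    base.update(overrides)
    return HerdProfile(**base)


def scaled_profile(profile: HerdProfile, n_pens: int, tb_pen_count: int,
                   halfspan: int | None = None,
                   pigs_per_pen: tuple[int, int] | None = None) -> HerdProfile:
    """Down-scaled copy of a profile (fewer pens / shorter span); the
    per-pig-day behavioural moments are untouched."""
    kwargs: dict = {"n_pens": n_pens, "tb_pen_count": tb_pen_count}
    if halfspan is not None:
        kwargs["recording_halfspan_days"] = halfspan
    if pigs_per_pen is not None:
        kwargs["pigs_per_pen"] = pigs_per_pen
    return replace(profile, **kwargs)


# --------------------------------------------------------------------------
# sampling


def sample_pig_day(
    pig_baseline: tuple[float, float, float],
    day_multipliers: tuple[float, float, float],
    profile: HerdProfile,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Draw one pig-day: visit count and per-visit intakes in grams.

    ``pig_baseline`` and ``day_multipliers`` are (DFV, DFC, StdFC)
    multiplicative factors.  The count is gamma-mixed Poisson with mean
    ``dfv_mean * bv * mv``; intakes are gamma with expected daily total
    ``dfc_mean * bc * mc`` and per-visit SD ``stdfc_mean * bs * ms``.
    """
    bv, bc, bs = pig_baseline
    mv, mc, ms = day_multipliers
    if min(bv, bc, bs) < 0 or min(mv, mc, ms) < 0:
        raise ConfigurationError("multipliers must be non-negative")
    mean_visits = profile.dfv_mean * bv * mv
    if mean_visits <= 0:
        return 0, np.empty(0)
    shape = profile.visit_count_shape()
    if math.isinf(shape):
        lam = mean_visits
    else:
        lam = rng.gamma(shape, mean_visits / shape)
    n = int(rng.poisson(lam))
    if n == 0:
        return 0, np.empty(0)
    mean_total = profile.dfc_mean * bc * mc
    sd_visit = profile.stdfc_mean * bs * ms
    if mean_total <= 0:
        return n, np.zeros(n)
    # daily total and per-visit dispersion are controlled separately:
    # the total is a tight gamma around its expectation, the visits get
    # gamma weights with the dispersion the StdFC target implies.
    t_shape = 1.0 / DAY_CV_DFC**2
    total = rng.gamma(t_shape, mean_total / t_shape)
    if n == 1 or sd_visit <= 0:
        return n, np.full(n, total / n)
    mu = mean_total / n
    w_shape = max((mu / sd_visit) ** 2, 0.02)
    w = rng.gamma(w_shape, 1.0, n)
    s = w.sum()
    if s <= 0:
        return n, np.full(n, total / n)
    return n, total * w / s


def _lognormal_multipliers(
    rng: np.random.Generator, cvs: dict[str, float]
) -> tuple[float, float, float]:
    out = []
    for var in ("dfv", "dfc", "stdfc"):
        s = cvs[var]
        sigma = math.sqrt(math.log(1.0 + s**2))
        out.append(rng.lognormal(-(sigma**2) / 2.0, sigma))
    return tuple(out)  # type: ignore[return-value]


def simulate_herd(
    profile: HerdProfile,
    drift: DriftModel | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    start_date: pd.Timestamp = DEFAULT_START_DATE,
) -> FeederDataset:
    """Simulate one herd's feeder log.

    TB pens get a TB date placed uniformly at random in the middle third
    of the recording span (so default labeling horizons never overrun the
    edges) and the drift applied around it; control pens are drift-free.
    ``missing_rate`` is the per-pig-day probability of a recorder gap
    (recorded in the ``gaps`` table).  Identical arguments give
    byte-identical output.
    """
    if drift is None:
        drift = DriftModel()
    if not (0.0 <= missing_rate < 1.0):
        raise ConfigurationError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    span = profile.span_days
    rec_start = pd.Timestamp(start_date)
    rec_end = rec_start + pd.Timedelta(days=span - 1)
    dates = pd.date_range(rec_start, rec_end, freq="D")

    visit_rows: list[tuple] = []
    pen_rows: list[tuple] = []
    roster_rows: list[tuple] = []

    for p in range(profile.n_pens):
        pen_id = f"{profile.herd_id}_pen{p:03d}"
        is_tb = p < profile.tb_pen_count
        if is_tb:
            # middle third of the span, so TB windows fit at default spans
            lo, hi = span // 3, 2 * span // 3
            tb_offset = int(rng.integers(lo, hi))
            tb_date = rec_start + pd.Timedelta(days=tb_offset)
        else:
            tb_offset = None
            tb_date = pd.NaT
        pen_rows.append(
            (pen_id, profile.herd_id, "TB" if is_tb else "CTL", tb_date, rec_start, rec_end)
        )

        n_pigs = int(rng.integers(profile.pigs_per_pen[0], profile.pigs_per_pen[1] + 1))
        pen_base = _lognormal_multipliers(rng, BETWEEN_PEN_CV)
        day_mults = [
            drift.multipliers(d - tb_offset) if is_tb else (1.0, 1.0, 1.0)
            for d in range(span)
        ]
        for q in range(n_pigs):
            pig_id = f"{pen_id}_pig{q:02d}"
            roster_rows.append((pen_id, pig_id, rec_start, rec_end))
            pig_base = _lognormal_multipliers(rng, BETWEEN_PIG_CV)
            baseline = tuple(a * b for a, b in zip(pen_base, pig_base))
            for d, date in enumerate(dates):
                n, grams = sample_pig_day(baseline, day_mults[d], profile, rng)
                if n == 0:
                    continue
                entries = np.sort(rng.uniform(0, 86_400 - 1_800, n))
                durations = rng.uniform(60, 1_500, n)
                for g, t0, dur in zip(grams, entries, durations):
                    entry = _fmt_time(t0)
                    exit_ = _fmt_time(min(t0 + dur, 86_399))
                    visit_rows.append((pen_id, pig_id, date, entry, exit_, float(g)))

    visits = pd.DataFrame(visit_rows, columns=VISIT_COLUMNS) if visit_rows else _empty(VISIT_COLUMNS)
    pens = pd.DataFrame(pen_rows, columns=PEN_COLUMNS) if pen_rows else _empty(PEN_COLUMNS)
    roster = (
        pd.DataFrame(roster_rows, columns=ROSTER_COLUMNS) if roster_rows else _empty(ROSTER_COLUMNS)
    )
    data = FeederDataset(visits=visits, pens=pens, roster=roster)
    if missing_rate > 0.0 and len(roster):
        data = inject_missingness(data, pig_dropout_rate=0.0, day_gap_rate=missing_rate, rng=rng)
    return data


def simulate_herds(
    profiles: list[HerdProfile],
    drift: DriftModel | None = None,
    missing_rate: float = 0.0,
    seed: int = 0,
    start_date: pd.Timestamp = DEFAULT_START_DATE,
) -> FeederDataset:
    """Simulate several herds with per-herd sub-seeds and concatenate."""
    parts = [
        simulate_herd(prof, drift, missing_rate, seed=seed + 1_000 * i, start_date=start_date)
        for i, prof in enumerate(profiles)
    ]
    return FeederDataset.concat(parts)


def _fmt_time(seconds: float) -> str:
    s = int(seconds)
    return f"{s // 3600:02d}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def inject_missingness(
    data: FeederDataset,
    pig_dropout_rate: float = 0.0,
    day_gap_rate: float = 0.0,
    rng: np.random.Generator | int = 0,
) -> FeederDataset:
    """Remove data the way real recordings lose it.

    *Dropout*: a pig leaves the pen early — its roster interval is
    truncated at a uniform day and later visits removed.  *Day gaps*:
    individual pig-days lose all visits; the pig stays on the roster and
    the day is logged in ``gaps`` so downstream code treats it as missing
    rather than "present, ate nothing".
    """
    for name, rate in (("pig_dropout_rate", pig_dropout_rate), ("day_gap_rate", day_gap_rate)):
        if not (0.0 <= rate < 1.0):
            raise ConfigurationError(f"{name} must be in [0, 1)")
    if pig_dropout_rate == 0.0 and day_gap_rate == 0.0:
        return data
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    visits = data.visits.copy()
    roster = data.roster.copy().reset_index(drop=True)
    gap_rows: list[tuple] = []

    if pig_dropout_rate > 0.0:
        drop_mask = rng.random(len(roster)) < pig_dropout_rate
        for i in np.flatnonzero(drop_mask):
            first = roster.at[i, "first_day"]
            last = roster.at[i, "last_day"]
            n_days = (last - first).days + 1
            new_last = first + pd.Timedelta(days=int(rng.integers(0, n_days)))
            roster.at[i, "last_day"] = new_last
            sel = (
                (visits["pen_id"] == roster.at[i, "pen_id"])
                & (visits["pig_id"] == roster.at[i, "pig_id"])
                & (pd.to_datetime(visits["date"]) > new_last)
            )
            visits = visits[~sel]

    if day_gap_rate > 0.0:
        drop_keys: set[tuple] = set()
        for row in roster.itertuples(index=False):
            days = pd.date_range(row.first_day, row.last_day, freq="D")
            mask = rng.random(len(days)) < day_gap_rate
            for day in days[mask]:
                gap_rows.append((row.pen_id, row.pig_id, day))
                drop_keys.add((row.pen_id, row.pig_id, day))
        if drop_keys:
            keys = list(
                zip(visits["pen_id"], visits["pig_id"], pd.to_datetime(visits["date"]))
            )
            keep = [k not in drop_keys for k in keys]
            visits = visits[keep]

    gaps = pd.DataFrame(gap_rows, columns=GAP_COLUMNS) if gap_rows else _empty(GAP_COLUMNS)
    if len(data.gaps):
        gaps = pd.concat([data.gaps, gaps], ignore_index=True)
    return FeederDataset(
        visits=visits.reset_index(drop=True), pens=data.pens, roster=roster, gaps=gaps
    )
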