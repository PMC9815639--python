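"""End-to-end pipeline: simulate/ingest -> features -> windows -> bench
-> evaluate, with every artifact written as CSV plus a YAML manifest.

Re-running with the same configuration reproduces all outputs
byte-identically: every random step is seeded from the config, and all
writers use fixed formats.  On failure, ``status.yaml`` in the run
directory names the failed stage so a run can be diagnosed and resumed.
"""

from __future__ import annotations

import os
from importlib import metadata

import pandas as pd
import yaml

from . import evaluate as ev
from .config import PipelineConfig
from .errors import IntegrityError
from .features import daily_observations, write_observations_csv
from .io import FeederDataset
from .simulate import simulate_herds
from .windows import build_windows, write_windows_csv


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute every stage; returns a summary dict (also in the manifest)."""
    os.makedirs(outdir, exist_ok=True)
    stage = "simulate"
    try:
        if config.input_dir:
            data, rejects = ingest_feeder_csv(config.input_dir)
            if len(rejects):
                rejects.to_csv(os.path.join(outdir, "rejects.csv"), index=False)
        else:
            data = simulate_herds(
                config.simulation.herds,
                config.simulation.drift,
                config.simulation.missing_rate,
                seed=config.simulation.seed,
            )
        data.write_csv(os.path.join(outdir, "data"))

        stage = "featurize"
        obs = daily_observations(data)
        write_observations_csv(obs, os.path.join(outdir, "observations.csv"))

        stage = "windowize"
        windows = build_windows(obs, data.pens, config.windows)
        write_windows_csv(windows, os.path.join(outdir, "windows.csv"))

        stage = "bench+evaluate"
        all_results: dict[str, dict] = {}
        for regime in config.evaluate.regimes:
            all_results[regime] = ev.run_benchmark(
                obs,
                data.pens,
                config.windows,
                list(config.bench.models),
                config.bench.tune,
                regime=regime,
                split_seed=config.evaluate.split_seed,
                test_fraction=config.evaluate.test_fraction,
                windows=windows,
            )
            profiles = [r.profile for r in all_results[regime].values()]
            if len(profiles) > 1:
                ev.compare_models(profiles).to_csv(
                    os.path.join(outdir, f"comparisons_{regime.lower()}.csv"),
                    index=False, float_format="%.6g",
                )
        table = ev.results_table(all_results)
        table.to_csv(os.path.join(outdir, "results.csv"), index=False, float_format="%.6g")

        if config.evaluate.sweep.enabled:
            stage = "sweep"
            sweep = ev.sensitivity_sweep(
                obs, data.pens, config.windows, config.bench.tune,
                window_days_grid=config.evaluate.sweep.window_days,
                tb_window_grid=config.evaluate.sweep.tb_windows,
                model=config.evaluate.sweep.model,
                seeds=config.evaluate.sweep.seeds,
                regimes=config.evaluate.regimes,
            )
            sweep.to_csv(os.path.join(outdir, "sweep.csv"), index=False, float_format="%.6g")

        stage = "manifest"
        summary = {
            "config_hash": config.config_hash(),
            "n_windows": int(len(windows)),
            "n_tb_windows": int((windows["label"] == "TB").sum()),
            "results": os.path.join(outdir, "results.csv"),
        }
        manifest = {
            "penwatch_version": _version(),
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "summary": {k: v for k, v in summary.items() if k != "config_hash"},
        }
        with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        _write_status(outdir, "complete", None)
        return summary
    except Exception:
        _write_status(outdir, "failed", stage)
        raise


def _write_status(outdir: str, state: str, failed_stage: str | None) -> None:
    with open(os.path.join(outdir, "status.yaml"), "w") as fh:
        yaml.safe_dump({"state": state, "failed_stage": failed_stage}, fh)


def _version() -> str:
    try:
        return metadata.version("penwatch")
    except metadata.PackageNotFoundError:
        return "unknown"


# --------------------------------------------------------------------------
# real-farm ingest


def ingest_feeder_csv(
    directory: str,
    max_reject_fraction: float = 0.05,
) -> tuple[FeederDataset, pd.DataFrame]:
    """Read and validate feeder CSVs from ``directory``.

    Expects the same file layout the simulator writes (``visits.csv``,
    ``pens.csv``, ``roster.csv``, optional ``gaps.csv``).  Rows failing
    validation (negative intake, unknown pen, date outside the pen's
    recording span) are collected into a reject table; the run aborts if
    the reject fraction exceeds ``max_reject_fraction``.
    """
    data = FeederDataset.read_csv(directory)
    visits = data.visits.copy()
    visits["date"] = pd.to_datetime(visits["date"])
    pens = data.pens.set_index("pen_id")

    reasons = pd.Series("", index=visits.index, dtype=object)
    neg = visits["feed_g"] < 0
    reasons[neg] = "negative feed_g"
    unknown = ~visits["pen_id"].isin(pens.index)
    reasons[unknown & (reasons == "")] = "unknown pen"

    known = ~unknown
    spans = pens.loc[visits.loc[known, "pen_id"], ["rec_start", "rec_end"]]
    out_of_span = pd.Series(False, index=visits.index)
    out_of_span.loc[known] = (
        (visits.loc[known, "date"].to_numpy() < spans["rec_start"].to_numpy())
        | (visits.loc[known, "date"].to_numpy() > spans["rec_end"].to_numpy())
    )
    for i in visits.index[out_of_span & (reasons == "")]:
        pen = visits.at[i, "pen_id"]
        reasons[i] = (
            f"date outside recording span "
            f"[{pens.at[pen, 'rec_start'].date()}..{pens.at[pen, 'rec_end'].date()}]"
        )

    bad = reasons != ""
    rejects = visits[bad].assign(reason=reasons[bad])
    if len(visits) and len(rejects) / len(visits) > max_reject_fraction:
        raise IntegrityError(
            f"{len(rejects)}/{len(visits)} rows rejected "
            f"(> {max_reject_fraction:.0%}); first: {rejects.iloc[0]['reason']}"
        )
    clean = FeederDataset(
        visits=visits[~bad].reset_index(drop=True),
        pens=data.pens,
        roster=data.roster,
        gaps=data.gaps,
    )
    return clean, rejects.reset_index(drop=True)
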