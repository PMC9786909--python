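"""Command-line interface and end-to-end pipeline.

Subcommands: ``count`` (raw CSV -> epoch CSV), ``daily`` (epoch CSV -> daily
CSV), ``agree`` (paired CSV -> agreement JSON), ``simulate`` (scenario JSON ->
raw CSV + ground truth + reference daily CSV), ``tune`` (grid JSON + labelled
recordings -> score table), and ``run`` (full pipeline with a manifest).

Display rounding follows the reporting convention: biases to integers,
percentages to one decimal place, ties away from zero.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from ._util import StepsenseError, round_half_up
from . import agreement as agr
from . import metrics, signal_io, simulator, step_core

logger = logging.getLogger("stepsense")

EPOCH_COLUMNS = ["epoch_start", "steps", "cadence_spm", "is_mvpa"]
DAILY_COLUMNS = ["date", "total_steps", "mvpa_steps", "valid"]
PAIRED_COLUMNS = ["date", "wrist_total", "reference_total", "wrist_mvpa", "reference_mvpa"]


@dataclass
class RunConfig:
    """Pipeline configuration (all defaults match the reporting conventions)."""

    params_preset: str = "verisense2"
    epoch_length_s: float = 5.0
    mvpa_cadence_spm: float = 100.0
    agreement_unit: str = "day"  # day | participant
    log_level: str = "INFO"
    out_dir: Path = Path(".")


def _setup_logging(level: str) -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
    )


def write_epoch_csv(series: metrics.EpochSeries, path: Path) -> None:
    frame = series.to_frame()
    frame["epoch_start"] = frame["epoch_start"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    frame["cadence_spm"] = frame["cadence_spm"].map(lambda v: f"{v:.2f}")
    frame.to_csv(path, index=False)


def read_epoch_csv(path: Path, epoch_length_s: float = 5.0) -> metrics.EpochSeries:
    frame = pd.read_csv(path)
    missing = set(EPOCH_COLUMNS) - set(frame.columns)
    if missing:
        raise StepsenseError(f"{path}: missing epoch columns {sorted(missing)}")
    return metrics.EpochSeries(
        epoch_start=pd.DatetimeIndex(pd.to_datetime(frame["epoch_start"], format="ISO8601")),
        epoch_length_s=epoch_length_s,
        steps=frame["steps"].to_numpy(),
        cadence_spm=frame["cadence_spm"].to_numpy(),
        is_mvpa=frame["is_mvpa"].to_numpy(dtype=bool),
    )


def write_daily_csv(summaries: list[metrics.DailySummary], path: Path) -> None:
    rows = [
        {
            "date": s.date.isoformat(),
            "total_steps": s.total_steps,
            "mvpa_steps": s.mvpa_steps,
            "valid": s.valid,
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=DAILY_COLUMNS).to_csv(path, index=False)


def read_daily_csv(path: Path) -> list[metrics.DailySummary]:
    frame = pd.read_csv(path)
    missing = set(DAILY_COLUMNS) - set(frame.columns)
    if missing:
        raise StepsenseError(f"{path}: missing daily columns {sorted(missing)}")
    return [
        metrics.DailySummary(
            date=pd.Timestamp(row["date"]).date(),
            total_steps=int(row["total_steps"]),
            mvpa_steps=int(row["mvpa_steps"]),
            wear_complete=bool(row["valid"]),
            qc_pass=bool(row["valid"]),
        )
        for _, row in frame.iterrows()
    ]


def write_paired_csv(pairs: list[metrics.PairedDaily], path: Path) -> None:
    rows = [
        {
            "date": p.date.isoformat(),
            "wrist_total": p.wrist_total,
            "reference_total": p.reference_total,
            "wrist_mvpa": p.wrist_mvpa,
            "reference_mvpa": p.reference_mvpa,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=PAIRED_COLUMNS).to_csv(path, index=False)


def read_paired_csv(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(PAIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise StepsenseError(f"{path}: missing paired columns {sorted(missing)}")
    return frame


def display_agreement(result: agr.AgreementResult) -> dict:
    """Agreement result at reporting precision: integer biases, 1-dp percentages."""
    out = result.to_dict()
    out["bias_display"] = round_half_up(result.bias)
    out["bias_ci_display"] = [round_half_up(v) for v in result.bias_ci]
    out["loa_display"] = [round_half_up(v) for v in result.loa]
    if result.mape_pct is not None:
        out["mape_pct_display"] = round_half_up(result.mape_pct, 1)
    if result.percent_bias is not None:
        out["percent_bias_display"] = round_half_up(result.percent_bias, 1)
    return out


def process_recording(
    recording: signal_io.RawRecording, config: RunConfig
) -> tuple[metrics.EpochSeries, step_core.StepEvents]:
    """Count steps and aggregate them to epochs over whole-day spans."""
    params = step_core.load_preset(config.params_preset)
    events = step_core.count_steps(recording, params)
    start = pd.Timestamp(recording.start_time).normalize()
    end_of_data = pd.Timestamp(recording.start_time) + pd.Timedelta(
        seconds=recording.duration_s
    )
    n_epochs = int(np.ceil((end_of_data - start).total_seconds() / config.epoch_length_s))
    span = (start.to_pydatetime(), (start + pd.Timedelta(seconds=n_epochs * config.epoch_length_s)).to_pydatetime())
    series = metrics.aggregate_epochs(
        events, config.epoch_length_s, span=span, mvpa_cadence_spm=config.mvpa_cadence_spm
    )
    return series, events


def run_pipeline(
    config: RunConfig,
    inputs: list[Path],
    reference: Path | None = None,
    agree: bool = False,
) -> int:
    """count -> epochs -> daily -> pair -> agree, with a run manifest.

    Returns a process exit code: 0 on success, 2 when agreement was requested
    but the reference daily file is missing (other outputs are still written).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = step_core.load_preset(config.params_preset)

    daily: list[metrics.DailySummary] = []
    for path in inputs:
        recording = signal_io.read_raw_csv(path)
        series, _ = process_recording(recording, config)
        stem = Path(path).stem
        write_epoch_csv(series, out_dir / f"{stem}_epochs.csv")
        for day, day_series in _split_days(series):
            daily.append(metrics.summarize_day(day_series))
    write_daily_csv(daily, out_dir / "daily.csv")

    exit_code = 0
    if agree:
        if reference is None or not Path(reference).exists():
            logger.error("agreement stage skipped: reference daily file missing")
            exit_code = 2
        else:
            ref_daily = read_daily_csv(Path(reference))
            pairs = metrics.pair_days(daily, ref_daily)
            write_paired_csv(pairs, out_dir / "paired.csv")
            report = {}
            for metric in ("total", "mvpa"):
                arr = agr.pairs_from_paired_daily(pairs, metric)
                if arr.shape[0] >= 2:
                    report[metric] = display_agreement(agr.bland_altman(arr))
            (out_dir / "agreement.json").write_text(json.dumps(report, indent=2))

    manifest = {
        "version": __version__,
        "preset": params.name or config.params_preset,
        "thresholds": params.to_dict(),
        "epoch_length_s": config.epoch_length_s,
        "mvpa_cadence_spm": config.mvpa_cadence_spm,
        "agreement_unit": config.agreement_unit,
        "inputs": [str(p) for p in inputs],
        "reference": str(reference) if reference else None,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return exit_code


def _split_days(series: metrics.EpochSeries):
    dates = series.epoch_start.normalize()
    for day in dates.unique():
        mask = dates == day
        yield day.date(), metrics.EpochSeries(
            epoch_start=series.epoch_start[mask],
            epoch_length_s=series.epoch_length_s,
            steps=series.steps[mask],
            cadence_spm=series.cadence_spm[mask],
            is_mvpa=series.is_mvpa[mask],
        )


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level: str) -> None:
    """Wrist-accelerometer step counting and concurrent-validity toolkit."""
    _setup_logging(log_level)


@cli.command()
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--params", default="verisense2", show_default=True, help="preset name or JSON path")
@click.option("--epoch-seconds", default=5.0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def count(input_path: str, params: str, epoch_seconds: float, out_path: str) -> None:
    """Count steps in a raw CSV and write the 5-s epoch CSV."""
    config = RunConfig(params_preset=params, epoch_length_s=epoch_seconds)
    recording = signal_io.read_raw_csv(input_path)
    series, events = process_recording(recording, config)
    write_epoch_csv(series, Path(out_path))
    click.echo(f"{len(events)} steps -> {out_path}")


@cli.command()
@click.option("--epochs", "epochs_path", required=True, type=click.Path(exists=True))
@click.option("--epoch-seconds", default=5.0, show_default=True)
@click.option("--wear-complete/--wear-incomplete", default=True)
@click.option("--qc-pass/--qc-fail", default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def daily(epochs_path: str, epoch_seconds: float, wear_complete: bool, qc_pass: bool, out_path: str) -> None:
    """Collapse an epoch CSV to per-day summaries."""
    series = read_epoch_csv(Path(epochs_path), epoch_length_s=epoch_seconds)
    summaries = [
        metrics.summarize_day(day_series, wear_complete=wear_complete, qc_pass=qc_pass)
        for _, day_series in _split_days(series)
    ]
    write_daily_csv(summaries, Path(out_path))
    click.echo(f"{len(summaries)} day(s) -> {out_path}")


@cli.command()
@click.option("--pairs", "pairs_path", required=True, type=click.Path(exists=True))
@click.option("--metric", type=click.Choice(["total", "mvpa"]), default="total", show_default=True)
@click.option("--unit", type=click.Choice(["day", "participant"]), default="day", show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def agree(pairs_path: str, metric: str, unit: str, out_path: str) -> None:
    """Bland-Altman agreement from a paired daily CSV."""
    frame = read_paired_csv(Path(pairs_path))
    cols = ("wrist_total", "reference_total") if metric == "total" else ("wrist_mvpa", "reference_mvpa")
    if unit == "participant":
        if "participant" not in frame.columns:
            raise click.ClickException("--unit participant requires a 'participant' column")
        frame = frame.groupby("participant", as_index=False)[list(cols)].mean()
    arr = frame[list(cols)].to_numpy(dtype=float)
    result = agr.bland_altman(arr)
    Path(out_path).write_text(json.dumps(display_agreement(result), indent=2))
    click.echo(
        f"bias {round_half_up(result.bias)} "
        f"(LoA {round_half_up(result.loa[0])}, {round_half_up(result.loa[1])}) -> {out_path}"
    )


@cli.command()
@click.option("--scenario", "scenario_path", required=True, type=click.Path(exists=True))
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--out-dir", required=True, type=click.Path())
def simulate(scenario_path: str, seed: int, out_dir: str) -> None:
    """Simulate a day from a scenario JSON; write raw CSV, truth, reference."""
    spec = json.loads(Path(scenario_path).read_text())
    bouts = [
        (float(b["start_s"]), simulator.GaitBoutSpec(
            cadence_spm=float(b["cadence_spm"]),
            duration_s=float(b["duration_s"]),
            swing_amplitude_g=float(b.get("swing_amplitude_g", 0.6)),
            harmonic_ratio=float(b.get("harmonic_ratio", 0.0)),
            phase_jitter_sd=float(b.get("phase_jitter_sd", 0.0)),
        ))
        for b in spec.get("bouts", [])
    ]
    scenario = simulator.DayScenario(
        bouts=bouts,
        artefact_rate_per_hour=float(spec.get("artefact_rate_per_hour", 0.0)),
        artefact_amplitude_g=float(spec.get("artefact_amplitude_g", 2.0)),
        noise_sd_g=float(spec.get("noise_sd_g", 0.0)),
        seed=seed,
        start_time=datetime.fromisoformat(spec.get("start_time", "2022-01-03T00:00:00")),
        duration_s=float(spec.get("duration_s", 86_400.0)),
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    recording, truth = simulator.simulate_day(scenario)
    signal_io.write_raw_csv(recording, out / "raw.csv")
    (out / "ground_truth.json").write_text(truth.to_json())
    error_model = tuple(spec.get("reference_error_model", (0.0, 0.0)))
    reference = simulator.simulate_reference_device(
        truth, error_model=error_model, rng=np.random.default_rng(seed + 1),
        day=scenario.start_time.date(),
    )
    write_daily_csv([reference], out / "reference_daily.csv")
    click.echo(f"{truth.daily_total} true steps -> {out}")


@cli.command()
@click.option("--grid", "grid_path", required=True, type=click.Path(exists=True))
@click.option("--data", "data_dir", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def tune(grid_path: str, data_dir: str, out_path: str) -> None:
    """Grid-search detector thresholds against labelled recordings.

    DATA_DIR holds ``<name>.csv`` raw recordings plus ``<name>.ref`` files
    each containing the reference daily step total.
    """
    grid_spec = json.loads(Path(grid_path).read_text())
    recordings = []
    for csv_path in sorted(Path(data_dir).glob("*.csv")):
        ref_path = csv_path.with_suffix(".ref")
        if not ref_path.exists():
            raise click.ClickException(f"missing reference total for {csv_path.name}")
        recordings.append((signal_io.read_raw_csv(csv_path), float(ref_path.read_text().strip())))
    if not recordings:
        raise click.ClickException(f"no recordings found in {data_dir}")
    result = agr.tune_parameters(grid_spec, recordings)
    result.scores.to_csv(out_path, index=False)
    click.echo(
        f"{result.n_combos} combos scored ({result.n_skipped} infeasible skipped); "
        f"selected {result.selected.to_dict()}"
    )


@cli.command()
@click.option("--input", "input_paths", multiple=True, required=True, type=click.Path(exists=True))
@click.option("--reference", "reference_path", type=click.Path(), default=None)
@click.option("--params", default="verisense2", show_default=True)
@click.option("--epoch-seconds", default=5.0, show_default=True)
@click.option("--agree/--no-agree", "do_agree", default=False)
@click.option("--out-dir", required=True, type=click.Path())
def run(input_paths, reference_path, params, epoch_seconds, do_agree, out_dir) -> None:
    """Full pipeline: count -> epochs -> daily -> pair -> agree, with manifest."""
    config = RunConfig(params_preset=params, epoch_length_s=epoch_seconds, out_dir=Path(out_dir))
    code = run_pipeline(
        config,
        [Path(p) for p in input_paths],
        reference=Path(reference_path) if reference_path else None,
        agree=do_agree,
    )
    if code != 0:
        sys.exit(code)


def main() -> None:  # pragma: no cover
    cli()
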