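"""Command-line interface: replay the study synthetically or measure rasters.

Subcommands
-----------
simulate
    Generate a synthetic cohort (default: the packaged study-calibrated
    spec), run the full render -> measure -> metrics pipeline and the
    statistical battery, and write metrics.csv, report.json, manifest.json
    and optional per-task screenshot PNGs.
measure
    Standalone measurement stage: read labeled screenshot PNGs
    (background=0, mirror=1, lesion=2) and emit one metric row per image
    (time and validity absent).
stats
    Re-run the comparison battery on an existing metrics CSV.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__, cohortsim
from .metrics import records_to_dataframe
from .raster_measure import MissingLabelError, Screenshot, measure
from .stats import run_study_analysis

CSV_COLUMNS = [
    "group", "participant_id", "trial", "task_index", "tooth",
    "distance_mm", "ratio_pct", "ellipticity", "theta_deg", "time_s",
    "mirror_fully_visible", "no_penetration", "tip_in_box",
    "tip_clear_of_bc", "valid",
]


def _load_spec(config: str | None, seed: int, groups: str | None,
               n: str | None) -> cohortsim.CohortSpec:
    if config:
        spec = cohortsim.load_cohort_spec(config)
    else:
        spec = cohortsim.calibrated_spec()
    spec.seed = seed
    if groups:
        wanted = [g.strip() for g in groups.split(",")]
        missing = [g for g in wanted if g not in spec.profiles]
        if missing:
            raise click.BadParameter(f"groups not in spec: {missing}")
        spec.profiles = {g: spec.profiles[g] for g in wanted}
        spec.n_per_group = {g: spec.n_per_group[g] for g in wanted}
    if n:
        counts = [int(v) for v in n.split(",")]
        if len(counts) != len(spec.profiles):
            raise click.BadParameter("--n needs one count per group")
        spec.n_per_group = dict(zip(spec.profiles, counts))
    return spec


@click.group()
@click.version_option(version=__version__)
def main():
    """Headless mirror-technique simulator and scoring pipeline."""


@main.command()
@click.option("--config", type=click.Path(exists=True), default=None,
              help="Cohort spec YAML (default: packaged calibrated spec).")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True,
              help="Output directory.")
@click.option("--screenshots/--no-screenshots", default=False,
              show_default=True,
              help="Write one labeled PNG per task for each group's first participant.")
@click.option("--reps", type=int, default=2000, show_default=True,
              help="Monte-Carlo replicates for the KS normality screen.")
@click.option("--groups", default=None, help="Comma-separated subset, e.g. ID,ST.")
@click.option("--n", default=None, help="Comma-separated sizes matching --groups.")
def simulate(config, seed, out, screenshots, reps, groups, n):
    """Synthetic replay of the study: cohort -> metrics CSV -> stats report."""
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = _load_spec(config, seed, groups, n)

    sink = None
    if screenshots:
        shot_dir = out_dir / "screenshots"
        shot_dir.mkdir(exist_ok=True)

        def sink(record, shot):
            name = f"{record.group}_task{record.task_index}_tooth{record.tooth}.png"
            shot.to_png(shot_dir / name)
            shot.to_png(shot_dir / name.replace(".png", "_preview.png"), preview=True)

    click.echo(f"simulating {sum(spec.n_per_group.values())} participants "
               f"x {4 * len(spec.trials)} tasks (seed {seed}) ...", err=True)
    records = cohortsim.generate_cohort(spec, screenshot_sink=sink)
    df = records_to_dataframe(records)[CSV_COLUMNS]
    csv_path = out_dir / "metrics.csv"
    df.to_csv(csv_path, index=False, float_format="%.6f")
    click.echo(f"wrote {len(df)} records -> {csv_path}", err=True)

    if df["group"].nunique() >= 2:
        report = run_study_analysis(df, ks_reps=reps, seed=seed)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        click.echo(f"wrote statistics report -> {out_dir / 'report.json'}", err=True)
    else:
        click.echo("single group: skipping between-group statistics", err=True)

    manifest = {
        "mirrorsim_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config": str(config) if config else "packaged:calibrated_cohort.yaml",
        "config_sha256": _config_hash(config),
        "groups": {g: spec.n_per_group[g] for g in spec.profiles},
        "trials": list(spec.trials),
        "n_records": int(len(df)),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _config_hash(config: str | None) -> str:
    if config:
        data = Path(config).read_bytes()
    else:
        import importlib.resources

        data = (importlib.resources.files("mirrorsim.data")
                / "calibrated_cohort.yaml").read_bytes()
    return hashlib.sha256(data).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@main.command(name="measure")
@click.argument("files", nargs=-1, type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True, help="Output CSV path.")
@click.option("--mirror-diameter-mm", type=float, default=20.0, show_default=True)
def measure_cmd(files, out, mirror_diameter_mm):
    """Measure labeled screenshot PNGs; one row per readable image."""
    rows = []
    n_errors = 0
    for path in files:
        try:
            shot = Screenshot.from_png(path)
            m = measure(shot, mirror_diameter_mm=mirror_diameter_mm)
            rows.append({
                "file": str(path),
                "distance_mm": np.hypot(m.dm.cx_px - m.bc.cx_px,
                                        m.dm.cy_px - m.bc.cy_px) * m.mm_per_px,
                "ratio_pct": 100.0 * (m.bc.a_px * m.bc.b_px) / (m.dm.a_px * m.dm.b_px),
                "ellipticity": m.bc.b_px / m.bc.a_px,
                "theta_deg": m.theta_deg,
                "mm_per_px": m.mm_per_px,
            })
        except (MissingLabelError, ValueError, OSError) as exc:
            n_errors += 1
            click.echo(f"error: {path}: {exc}", err=True)
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.6f")
    click.echo(f"measured {len(rows)} image(s), {n_errors} error(s) -> {out}", err=True)
    if not rows:
        sys.exit(1)


@main.command(name="stats")
@click.option("--metrics", "metrics_csv", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True, help="Report JSON path.")
@click.option("--reps", type=int, default=2000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
def stats_cmd(metrics_csv, out, reps, seed):
    """Run the comparison battery on an existing metrics CSV."""
    df = pd.read_csv(metrics_csv)
    report = run_study_analysis(df, ks_reps=reps, seed=seed)
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    click.echo(f"wrote statistics report -> {out}", err=True)


if __name__ == "__main__":
    main()
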