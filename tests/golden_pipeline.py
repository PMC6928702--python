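"""End-to-end CLI pipeline used by the golden determinism test.

Runs simulate -> tune(indiv) -> detect(init, indiv) -> evaluate ->
speedstats on a fixed seed and returns the report files to be compared
byte-for-byte against the stored golden copies.
"""

from pathlib import Path

import pandas as pd
from click.testing import CliRunner

from gaitwb.cli import main
from gaitwb.detector import WalkingBout
from gaitwb.speed_stats import assign_bout_speeds
from gaitwb.synthetic import GroundTruth

GOLDEN_SEED = 123

#: Files compared byte-for-byte against tests/data/golden/.
GOLDEN_FILES = [
    "thresholds_indiv.yaml",
    "bouts_init.csv",
    "bouts_indiv.csv",
    "metrics_init.json",
    "metrics_indiv.json",
    "speeds_init.csv",
    "speeds_indiv.csv",
    "report.json",
    "cdf.csv",
]


def _run(runner, args):
    result = runner.invoke(main, args, catch_exceptions=False)
    assert result.exit_code == 0, result.output
    return result


def _bouts_from_csv(path) -> list:
    df = pd.read_csv(path)
    return [
        WalkingBout(events=[], start=row["start_s"], end=row["end_s"])
        for _, row in df.iterrows()
    ]


def run_golden_pipeline(outdir: Path) -> Path:
    outdir = Path(outdir)
    sim = outdir / "sim"
    runner = CliRunner()

    _run(runner, ["simulate", "default", str(sim), "--seed", str(GOLDEN_SEED)])

    _run(runner, [
        "tune", "--mode", "indiv",
        "--lab-dir", str(sim / "lab"),
        "--left", str(sim / "signals_left.csv"),
        "--right", str(sim / "signals_right.csv"),
        "--subject-id", "golden",
        "--out", str(outdir / "thresholds_indiv.yaml"),
    ])

    _run(runner, [
        "detect",
        "--left", str(sim / "signals_left.csv"),
        "--right", str(sim / "signals_right.csv"),
        "--out-csv", str(outdir / "bouts_init.csv"),
    ])
    _run(runner, [
        "detect",
        "--left", str(sim / "signals_left.csv"),
        "--right", str(sim / "signals_right.csv"),
        "--thresholds", str(outdir / "thresholds_indiv.yaml"),
        "--out-csv", str(outdir / "bouts_indiv.csv"),
    ])

    for mode in ("init", "indiv"):
        _run(runner, [
            "evaluate",
            "--bouts", str(outdir / f"bouts_{mode}.csv"),
            "--labels", str(sim / "labels.csv"),
            "--out", str(outdir / f"metrics_{mode}.json"),
        ])

    # per-cycle ground-truth speeds mapped onto each method's bouts
    truth = GroundTruth.from_json(sim / "truth.json")
    for mode in ("init", "indiv"):
        speeds = assign_bout_speeds(
            _bouts_from_csv(outdir / f"bouts_{mode}.csv"),
            truth.all_cycle_times,
            truth.all_cycle_speeds,
            per="cycle",
        )
        pd.DataFrame({"speed": speeds}).to_csv(
            outdir / f"speeds_{mode}.csv", index=False, float_format="%.6f"
        )

    _run(runner, [
        "speedstats",
        "--a", str(outdir / "speeds_init.csv"),
        "--b", str(outdir / "speeds_indiv.csv"),
        "--label-a", "init",
        "--label-b", "indiv",
        "--out", str(outdir / "report.json"),
        "--cdf", str(outdir / "cdf.csv"),
    ])
    return outdir
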