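"""Shared constants and paths for the analysis drivers.

Two synthetic cohorts are used throughout:

* the *day study* — 52 patients (26 AF-HF / 26 control), recordings
  starting 08:00 scaled to 4 h, emulating the daytime-window
  classification protocol at desk scale;
* the *circadian study* — 16 patients recorded for 16 h (08:00-24:00),
  giving both day and night segments for the transfer analysis.

Intermediate bulky tables (raw RR streams, per-segment features) live
under scratch/; compact result tables land in results/.
"""

from pathlib import Path

from afhf.cohort import CohortConfig
from afhf.pipeline import RunConfig

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

SEED = 7

DAY_STUDY = RunConfig(
    cohort=CohortConfig(n_per_class=26, duration_h=4.0),
    seed=SEED,
    windows=("day",),
)

CIRCADIAN_STUDY = RunConfig(
    cohort=CohortConfig(n_per_class=8, duration_h=16.0),
    seed=SEED + 1,
    windows=("day", "night"),
)


def ensure_dirs() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
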