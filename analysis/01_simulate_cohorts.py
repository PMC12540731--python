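#!/usr/bin/env python
"""Simulate the condition panel used throughout the downstream analyses.

Generates 20-cell cohorts for each experimental condition (control and
CENP-E-inhibited spindles with 2:2, 1:1, 1:0 and 0:0 centrioles per pole,
plus the acute Aurora-A-attenuation arm), writing for each cohort the
tracks, events, intensity and ground-truth tables under
results/cohorts/<preset>/.

Run from the repository root:  python analysis/01_simulate_cohorts.py
"""

import json
from pathlib import Path

from spindlekin import io as skio
from spindlekin.synthetic import get_preset, simulate_experiment

ROOT_SEED = 20260927
N_CELLS = 20
PRESETS = [
    "control_2v2",
    "cenpe_inhibited_2v2",
    "cenpe_inhibited_1v1",
    "cenpe_inhibited_1v0",
    "cenpe_inhibited_0v0",
    "cenpe_inhibited_2v2_auroraA_inhibited",
]

OUT = Path("results/cohorts")


def main() -> None:
    for k, name in enumerate(PRESETS):
        preset = get_preset(name)
        cohort = simulate_experiment(preset, N_CELLS, ROOT_SEED + k)
        dest = OUT / name
        dest.mkdir(parents=True, exist_ok=True)
        skio.write_tracks(cohort.cells, dest / "tracks.csv")
        skio.write_events(cohort.cells, dest / "events.csv")
        skio.write_intensities(cohort.intensities, dest / "intensities.csv")
        cohort.ground_truth.to_csv(dest / "ground_truth.csv", index=False,
                                   float_format=skio.FLOAT_FORMAT)
        (dest / "manifest.json").write_text(
            json.dumps(cohort.manifest, indent=2, sort_keys=True))
        n_polar = int(cohort.ground_truth["initially_polar"].sum())
        print(f"{name}: {N_CELLS} cells, {len(cohort.ground_truth)} pairs, "
              f"{n_polar} initially polar -> {dest}")


if __name__ == "__main__":
    main()
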