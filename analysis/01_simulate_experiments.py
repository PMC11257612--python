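"""Generate the three synthetic calibration experiments at c0 = 1 uM.

Emulates the measurements that constrain the model: zero-gradient swimming
tracks (velocity statistics), alternating-step FRET recordings (kinase
response function), and long constant-background FRET recordings (kinase
noise).  Writes CSVs under results/datasets/ for the fitting driver.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from chemoinfo.models import Environment
from chemoinfo.params import load_published
from chemoinfo.synthetic import (
    PopulationSpec,
    StepProtocol,
    calibrate_swim_generator,
    generate_noise_dataset,
    generate_step_response_dataset,
    generate_track_dataset,
)

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "datasets"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    swim, kin, env = load_published(1.0, generation=True)
    print("calibrating the track generator to the published medians ...")
    cal = calibrate_swim_generator(swim.sigma_v2, swim.tau_v, swim)
    print(f"  calibrated: speed={cal.speed:.2f} um/s, "
          f"mean_run={cal.mean_run:.3f} s, p_run={cal.p_run:.3f}")

    pop = PopulationSpec(swim=cal, kin=kin, n_cells=500)
    tracks = generate_track_dataset(
        pop, Environment(c0=1.0, g=0.0, k_D=env.k_D), 60.0, 0.05, seed=SEED)
    rows = []
    for i, tr in enumerate(tracks):
        rows.append(pd.DataFrame({"cell": i, "t": tr.t, "x": tr.x, "y": tr.y}))
    pd.concat(rows).to_csv(OUT / "tracks.csv.tmp", index=False)
    (OUT / "tracks.csv.tmp").rename(OUT / "tracks.csv")
    print(f"  wrote {len(tracks)} tracks")

    pop_s = PopulationSpec(swim=cal, kin=kin, n_cells=30)
    proto = StepProtocol.for_background(1.0)
    steps = generate_step_response_dataset(pop_s, env, proto, seed=SEED + 1)
    rows = []
    for i, blocks in enumerate(steps):
        for b in blocks:
            rows.append(pd.DataFrame({
                "cell": i, "block": b.meta["block"],
                "direction": b.meta["direction"], "t": b.t,
                "value": b.values}))
    pd.concat(rows).to_csv(OUT / "steps.csv", index=False)
    print(f"  wrote {len(steps)} cells x {len(steps[0])} step blocks")

    pop_n = PopulationSpec(swim=cal, kin=kin, n_cells=50)
    noise = generate_noise_dataset(pop_n, env, seed=SEED + 2)
    rows = [pd.DataFrame({"cell": i, "t": tr.t, "value": tr.values})
            for i, tr in enumerate(noise)]
    pd.concat(rows).to_csv(OUT / "noise.csv", index=False)
    print(f"  wrote {len(noise)} noise traces")

    manifest = {
        "seed": SEED,
        "c0_uM": 1.0,
        "protocol": proto.__dict__,
        "calibrated_swim": {"speed": cal.speed, "mean_run": cal.mean_run,
                            "mean_tumble": cal.mean_tumble,
                            "p_run": cal.p_run},
    }
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
    print("done.")


if __name__ == "__main__":
    main()
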