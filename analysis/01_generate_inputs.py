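#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Two bead trajectories plant the two chromophore designs (phenyl and His66
fragments moving together vs apart), plus decay traces at the published
off-switching rates, repeated switching cycles with bleaching, a titration
curve, and BLA mixture samples.  Everything lands under results/data/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rsfpkit import synthgen, trajio

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2024

# published off-switching rates and contrasts (green form unless noted)
VARIANTS = {
    "C21N_green": dict(k=0.27, sc=83.0),
    "C21N_M163A_green": dict(k=2.31, sc=97.0),
    "C21N_M163T_green": dict(k=3.39, sc=98.0),
    "C21N_F177S_green": dict(k=1.16, sc=94.0),
    "C21N_M163T_red": dict(k=1.45, sc=97.0),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for name, same in (("switchable", True), ("non_switchable", False)):
        case = OUT / name
        case.mkdir(exist_ok=True)
        planted = synthgen.gen_trajectory(
            synthgen.TrajectorySpec(
                chromophore=synthgen.ChromophoreSpec(same_group=same), seed=SEED
            )
        )
        trajio.write_pdb(planted.trajectory, case / "structure.pdb")
        trajio.write_xyz(planted.trajectory, case / "trajectory.xyz")
        synthgen.write_ground_truth(planted, case / "ground_truth.tsv")
        (case / "fragments.json").write_text(
            json.dumps(planted.chromophore_table, indent=2)
        )
        print(f"{name}: {planted.trajectory.n_atoms} atoms x "
              f"{planted.trajectory.n_frames} frames")

    for idx, (variant, pars) in enumerate(VARIANTS.items()):
        amplitude = pars["sc"] / 100.0
        trace = synthgen.gen_decay_trace(
            synthgen.KineticSpec(
                A=amplitude, c=1.0 - amplitude, k=pars["k"], seed=SEED + idx
            )
        )
        synthgen.write_trace_csv(trace, OUT / f"decay_{variant}.csv")
    print(f"decay traces: {len(VARIANTS)} variants, planted k_off "
          f"{[p['k'] for p in VARIANTS.values()]} s^-1")

    cycles = synthgen.gen_switch_cycles(
        synthgen.KineticSpec(
            A=0.95, c=0.05, k=3.39, n_cycles=5, bleach_factor=0.8, seed=SEED
        )
    )
    synthgen.write_cycles_csv(cycles, OUT / "cycles_bleach08.csv")

    curve = synthgen.gen_titration(
        pka=6.3, a_max=1.0, ph_grid=np.arange(4.0, 10.01, 0.5), sigma=0.01, seed=SEED
    )
    synthgen.write_titration_csv(curve, OUT / "titration_pka63.csv")

    samples = synthgen.gen_bla_samples(
        (0.5, 0.3, 0.2), (-0.02, 0.01, 0.05), (0.01, 0.008, 0.01), n=5000, seed=SEED
    )
    pd.DataFrame({"bla_angstrom": samples}).to_csv(OUT / "bla_samples.csv", index=False)
    print("wrote cycles, titration and BLA samples to", OUT)


if __name__ == "__main__":
    main()
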