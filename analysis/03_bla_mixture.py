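#!/usr/bin/env python
"""Three-Gaussian decomposition of the BLA distribution.

Fits the generated bond-length-alternation sample with the EM mixture
estimator and reports the right-most component (largest mean), the
fraction associated with the phenolic-predominant resonance form.
"""

from pathlib import Path

import pandas as pd

from rsfpkit import blamod

BASE = Path(__file__).resolve().parent.parent / "results"
PLANTED_WEIGHTS = (0.5, 0.3, 0.2)
PLANTED_MEANS = (-0.02, 0.01, 0.05)


def main() -> None:
    samples = pd.read_csv(BASE / "data" / "bla_samples.csv")["bla_angstrom"].to_numpy()
    fit = blamod.fit_gmm3(samples, seed=0)
    weight, mean = blamod.rightmost_component(fit)
    table = pd.DataFrame(
        {
            "component": [1, 2, 3],
            "weight": fit.weights.round(4),
            "mean_angstrom": fit.means.round(4),
            "sd_angstrom": fit.sds.round(4),
            "planted_weight": PLANTED_WEIGHTS,
            "planted_mean_angstrom": PLANTED_MEANS,
        }
    )
    out = BASE / "bla_gmm.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print(
        f"rightmost component: weight {weight:.3f} (planted 0.2), "
        f"mean {mean:.4f} Å (planted 0.05)"
    )
    print("wrote", out)


if __name__ == "__main__":
    main()
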