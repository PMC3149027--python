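#!/usr/bin/env python
"""Active-site architecture discrimination from mixed-oligomer titrations.

Simulates the dead-mutant titration into sub-threshold wild type under
the per-monomer and composite hypotheses, shows the two-phase
(activation-then-inhibition) signature unique to per-monomer active
sites, runs the 100-seed recovery study, and demonstrates the trans-HLE
binding penalty carried by the catalytically dead double mutant.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ire1_rnase import transact as tr

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    params = tr.TransModelParams()
    grid = np.geomspace(0.1, 15.0, 25)

    curves = {"mutant_uM": grid}
    for hyp in ("per_monomer", "composite"):
        curves[hyp] = tr.simulate_titration(1.5, grid, tr.H1061N, hyp,
                                            params).k_obs_values
    for label, genotype in (("single_mutant", tr.H1061N),
                            ("double_mutant", tr.H1061N_R1039A)):
        curves[f"hle_{label}"] = tr.simulate_titration(
            0.3, grid, genotype, "per_monomer_trans_hle",
            params).k_obs_values
    table = pd.DataFrame(curves)
    out = ROOT / "results" / "trans_curves.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False)

    base = tr.predict_kobs(1.5, 0.0, params=params)
    for hyp in ("per_monomer", "composite"):
        k = curves[hyp]
        print(f"{hyp}: baseline {base:.4f} 1/s, peak {k.max():.4f} at "
              f"{grid[np.argmax(k)]:.2f} uM mutant "
              f"({k.max() / base:.1f}-fold activation)")
    drop = curves["hle_single_mutant"] / curves["hle_double_mutant"]
    print(f"trans-HLE penalty: double-mutant curve {drop.max():.1f}-fold "
          "below the single mutant at its most sensitive point")

    rows = []
    for gen in ("per_monomer", "composite"):
        counts = tr.recovery_study(gen, n_seeds=100, sd=0.02, seed0=0)
        rows.append({"generating": gen, **counts})
        print(f"recovery study ({gen}): {counts}")
    pd.DataFrame(rows).fillna(0).to_csv(
        ROOT / "results" / "hypothesis_recovery.csv", index=False)
    print(f"wrote {out} and hypothesis_recovery.csv")


if __name__ == "__main__":
    main()
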