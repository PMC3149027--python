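#!/usr/bin/env python
"""Interface census of wild-type/mutant mixtures, checked by simulation.

For the titration endpoints of the trans-complementation experiment the
closed-form binomial census is compared against explicit random-pairing
Monte Carlo; at 1.5 uM wild type + 15 uM mutant only ~1.7% of binding
interfaces remain fully wild type while ~17% are hetero.
"""

from pathlib import Path

import pandas as pd

from ire1_rnase import assembly as asm

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    params = asm.OligomerModelParams()
    rows = []
    for wt, mut in ((1.5, 0.5), (1.5, 1.5), (1.5, 5.0), (1.5, 15.0)):
        mix = asm.MixtureState((asm.Species(wt, True, True),
                                asm.Species(mut, False, True)))
        census = asm.interface_distribution(mix, params)
        mc = asm.monte_carlo_pairing(200, census.wt_fraction, seed=11,
                                     n_trials=50_000)
        p = census.probabilities
        for cls, closed in zip(("ww", "wm", "mm"), p):
            mean, se = mc[cls]
            rows.append((wt, mut, cls, closed, mean, se,
                         abs(mean - closed) <= 3 * se))
    table = pd.DataFrame(rows, columns=[
        "wt_uM", "mut_uM", "interface", "closed_form", "monte_carlo",
        "mc_se", "within_3_sigma"])
    out = ROOT / "results" / "interface_census.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out, index=False)
    print(table.to_string(index=False, float_format="%.5g"))
    assert table["within_3_sigma"].all()
    print(f"\nclosed form and Monte-Carlo pairing agree; wrote {out}")


if __name__ == "__main__":
    main()
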