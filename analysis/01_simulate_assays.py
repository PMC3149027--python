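#!/usr/bin/env python
"""Generate one synthetic instance of every assay the pipeline consumes.

Writes CSV datasets with YAML parameter sidecars under
``results/datasets/``: a wild-type single-turnover time course, enzyme
titrations for wild type and the slow Y1043F mutant, the two
competitive-inhibition series (cognate stem-loop and DNA mimic), an
oligomerization profile, and a per-monomer trans-complementation
titration.
"""

from pathlib import Path

from ire1_rnase import synthetic_data as sd

OUT = Path(__file__).resolve().parents[1] / "results" / "datasets"
SEED = 20230901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    noise = lambda off: sd.NoiseModel(0.02, SEED + off)  # noqa: E731
    design = sd.AssayDesign()

    course, _ = sd.gen_time_course(0.25, 0.9, design, noise(0))
    sd.write_dataset(OUT / "timecourse_wt.csv", "time_course",
                     course.times, course.fractions,
                     {"k_obs": 0.25, "endpoint": 0.9, "seed": SEED})

    for name, k2, sdv, off in (("wt", 0.25, 0.02, 1),
                               ("y1043f", 0.022, 0.002, 2)):
        prof, _ = sd.gen_titration(k2, 1.0, design,
                                   sd.NoiseModel(sdv, SEED + off))
        sd.write_dataset(OUT / f"titration_{name}.csv", "titration",
                         prof.enzyme_concs, prof.k_obs_values,
                         {"k2": k2, "K_half": 1.0, "sd": sdv,
                          "seed": SEED + off})

    for name, K, off in (("hp21", 5.0, 3), ("dna_mimic", 200.0, 4)):
        series, _ = sd.gen_inhibition(0.25, K, design, noise(off))
        sd.write_dataset(OUT / f"inhibition_{name}.csv", "inhibition",
                         series.competitor_concs, series.k_obs_values,
                         {"k0": 0.25, "K": K, "seed": SEED + off})

    olig = sd.gen_oligomerization(noise=noise(5))
    sd.write_dataset(OUT / "oligomerization.csv", "oligomerization",
                     olig.enzyme_concs, olig.od_values, {"seed": SEED + 5})

    trans, _ = sd.gen_trans_titration("per_monomer", noise=noise(6))
    sd.write_dataset(OUT / "trans_titration_per_monomer.csv",
                     "trans_titration", trans.mutant_grid,
                     trans.k_obs_values,
                     {"hypothesis": "per_monomer", "wt_conc": 1.5,
                      "seed": SEED + 6})

    n = len(list(OUT.glob("*.csv")))
    print(f"wrote {n} datasets to {OUT}")


if __name__ == "__main__":
    main()
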