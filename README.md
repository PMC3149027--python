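# ire1-rnase

Quantitative enzymology of the Ire1 endoribonuclease, the sensor of the
unfolded protein response (UPR). Ire1's cytosolic kinase/RNase module
(the Ire1KR32 construct) assembles into oligomers above a low-micromolar
threshold and then cleaves RNA stem-loops bearing a CNGNNGN heptaloop —
the splice sites of *HAC1*/*XBP1* mRNA and, unexpectedly, the unmodified
anticodon stem-loop of tRNA-Phe. This package implements the analysis
chain with which the RNase catalytic center is located functionally,
exercised end to end on synthetic assay data with realistic noise.

## What it computes

**Single-turnover kinetics** (`ire1_rnase.kinetics`). With trace
(≤ 1 pM) labelled substrate and enzyme in excess, progress curves follow
`f(t) = A(1 − e^(−k_obs t))`; enzyme titrations follow the hyperbola
`k_obs = k₂E₀/(K_½ + E₀)`; cold-competitor inhibition follows
`k_obs = k₀/(1 + [C]/K)` (K = Km for the cognate stem-loop HP21, an
apparent Ki for non-substrate ligands); multiple-turnover initial
velocities follow Michaelis–Menten. All four families are fit by
Levenberg–Marquardt least squares with asymptotic standard errors.

**Assembly and interface statistics** (`ire1_rnase.assembly`). A
Hill-type two-state transition `φ(c) = cⁿ/(cⁿ + C_threshⁿ)` models
oligomerization; mixed wild-type/mutant pools pair randomly into
back-to-back RNase-dimer interfaces with the binomial census
(x², 2x(1−x), (1−x)²), validated against explicit Monte-Carlo pairing.

**Trans-complementation modelling** (`ire1_rnase.transact`), the core
computation. Each dimer interface presents the stem-loop in two
orientations; an orientation cleaves only if its receiving monomer
carries the general-acid histidine H1061 (and, under the rival
*composite* architecture, its partner too), while the partner's
helix-loop element (HLE, probed by R1039A) completes the binding surface
in trans. The observed rate is a mass-action partition of the tracer
over all binding modes, bounded by [0, k₂]. Titrating a dead H1061N
mutant into sub-threshold wild type produces the two-phase
activation-then-inhibition curve only under per-monomer active sites;
`discriminate` ranks hypotheses by corrected AIC with a constant-rate
null gate.

**Energetics** (`ire1_rnase.energetics`). ΔΔG‡ = RT ln(fold) at 303.15 K
converts rate ratios and detection-limit bounds into transition-state
stabilization energies.

**Stem-loop scanning** (`ire1_rnase.stemloop`). Locates hairpins with a
7-nt C-N-G-N-N-G-N loop closed by ≥ 5 Watson–Crick pairs and reports the
scissile position 3′ of the loop-position-3 G; a 2′-O-methyl mark there
(as on mature tRNA-Phe) marks the hit non-cleavable.

## Worked example

```
$ ire1 simulate --kind titration --k2 0.25 --k-half 1.0 --sd 0.0 \
      --out titr.csv --seed 1
wrote titr.csv
$ ire1 fit titr.csv
K_half: 1.0000000000000013
K_half_identifiable: true
converged: true
k2: 0.25
model: saturation
standard_errors:
  K_half: 3.3183050648526664e-16
  k2: 2.3478479895803937e-17
$ ire1 energetics --fold 300000 --lower-bound
ddG = >= 7.6 kcal/mol (fold >= 300000, T = 303.15 K)
$ ire1 energetics --fold 10
ddG = 1.4 kcal/mol (fold 10, T = 303.15 K)
```

The titration fit recovers the generating plateau rate k₂ = 0.25 s⁻¹ and
half-saturation K_½ = 1 µM exactly on noiseless data. The two energy
conversions reproduce the headline catalytic contributions: the
detection-limited ≥ 3×10⁵-fold loss upon removing the general-acid
histidine corresponds to ≥ 7.6 kcal/mol of transition-state
stabilization, and the ~10-fold effect of the tyrosine hydroxyl to
1.4 kcal/mol.

The numbered drivers under `analysis/` run the full narrative —
simulate (01), fit (02), interface census (03), hypothesis
discrimination (04), energetics (05), stem-loop scan (06) — and write
their tables to `results/`.

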