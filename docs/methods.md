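# Methods

## Scope and modelling stance

The package models the functional assays that localize the catalytic
center of the Ire1 RNase: single-turnover cleavage kinetics, equilibrium
oligomerization, mixed wild-type/mutant trans-complementation
titrations, mutational transition-state energetics, and consensus
stem-loop detection. Structure determination, docking and
surface-propensity calculations are out of scope. All data are
synthetic: the generators encode the statistical structure the analysis
assumes, so every fitter and model-selection routine can be tested
against known ground truth without laboratory input.

## Kinetic models

Single-turnover conditions put the enzyme in vast excess over a ≤ 1 pM
radiolabelled stem-loop, so the tracer never depletes enzyme or cold
competitor; binding math treats the tracer concentration as exactly
zero. Four curve families are fit (lmfit, Levenberg–Marquardt):

| family | model | parameters |
|---|---|---|
| progress curve | A(1 − e^(−k·t)) | k_obs (s⁻¹), amplitude A |
| enzyme titration | k₂E₀/(K_½+E₀) | plateau k₂ (s⁻¹), K_½ (µM) |
| competitive inhibition | k₀/(1+[C]/K) | k₀ (s⁻¹), K (µM) |
| multiple turnover | k_cat·E₀·S/(Km+S) | k_cat (s⁻¹), Km (µM) |

Initialization is data-driven (log-linear regression of early time
points for rates; the half-maximal abscissa for binding constants), so
results do not depend on user-supplied starting guesses. Errors are
asymptotic standard errors from the fit curvature. Degenerate inputs are
flagged rather than fit: an all-zero time course returns
`converged=False`; a titration sampling only the plateau marks K_½
unidentifiable (relative standard error > 100%); a flat inhibition
series reports K as a lower bound at the largest concentration probed.
Rates below a configurable detection floor (default 10⁻⁶ s⁻¹) are
reported as upper bounds, which is what enables "≥ fold-reduction"
statements for catalytically dead mutants. The titration K_½ and the
competition Km are kept as distinct quantities throughout; the package
never equates them.

## Synthetic data

Noise is additive Gaussian on the measured quantity (fraction cleaved or
k_obs), truncated by clipping to the physical range, with clip events
counted. The default sd of 0.02 is conservative relative to the
within-twofold day-to-day variation typical of gel-quantified rate
measurements. Reaction amplitudes default to 0.9 because gel assays
rarely reach completion. Kinetic assays carry a 303.15 K (30 °C)
temperature field; the light-scattering oligomerization readout is a
room-temperature measurement and keeps its own field. Identical seeds
give bit-identical datasets.

What the generators do *not* emulate: gel-image artifacts, radiolabel
decay, correlated (drift-like) errors within a titration series, and
day effects between replicates. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not
robustness to every systematic error of a real gel assay.

## Oligomerization and interface statistics

Assembly is a two-state Hill transition, monomer pool against assembled
pool, with `φ(c) = cⁿ/(cⁿ+C_threshⁿ)`. Defaults `C_thresh = 3 µM` and
`n_hill = 8` place 1.5 µM wild type just below threshold and reproduce a
sharp light-scattering transition; both are configurable because no
functional form for the transition is established. Mutants carrying
active-site point mutations oligomerize indistinguishably from wild
type, so mixing is ideal: assembled monomers pair uniformly at random
into back-to-back RNase-dimer interfaces, one interface per two
assembled monomers, giving the binomial census (x², 2x(1−x), (1−x)²) at
wild-type fraction x. Higher-order lattice topology is deliberately
collapsed. `monte_carlo_pairing` is the in-package brute-force oracle:
explicit labelling and uniform pairing of a finite pool, compared to the
closed form within Monte-Carlo error.

## Trans-complementation forward model

The mechanistic question is whether each RNase monomer carries a
complete active site ("per-monomer") or the dimer forms one composite
center. The forward model assigns each interface two stem-loop binding
orientations; an orientation is productive iff the monomer receiving
the scissile phosphate is catalysis-intact (per-monomer), additionally
requiring an intact partner under the composite hypothesis. The
helix-loop element acts in trans: an orientation whose partner monomer
carries R1039A binds `f_hle`-fold weaker (default 10, an
order-of-magnitude penalty). Non-productive modes still sequester
tracer. The observed rate is

    k_obs = k₂ · (Σ_prod c_o/K_o + β·c_freeWT/K) / (1 + Σ_all c_o/K_o + c_free/K)

which is bounded by [0, k₂], reduces to a hypothesis-independent value
at zero mutant, and yields the two-phase activation/inhibition shape
under per-monomer defaults. Parameter defaults: k₂ = 0.25 s⁻¹ (wild-type
plateau), K_orient = 1 µM per orientation (putting the wild-type-alone
titration into its plateau above ~3 µM total enzyme, where the
activation profiles are observed to saturate), β = 0.1 basal activity of
non-assembled wild type (leaving room for roughly tenfold
oligomerization-driven activation). The exact published reaction network
for this experiment is not available; the orientation-level binding
formulation is this package's declared surrogate, chosen because it
encodes all eight wild-type/mutant dimer configurations in one rule.
Whether excess-mutant inhibition involves wild-type dilution into
mutant-rich oligomers as well as tracer sequestration cannot be
separated at this level; the model contains both channels.

A stochastic oracle (`simulate_kobs_stochastic`) realizes a finite
monomer pool, assembles a binomial number of monomers, pairs them
uniformly, and samples the fate of a single tracer molecule from the
mass-action partition. Sampling the tracer keeps the Monte-Carlo
standard error dominant over the O(1/n_monomers) finite-pool bias, so
the 3-sigma comparison against the closed form is meaningful at 10⁵
trials.

## Hypothesis discrimination

`discriminate` fits each candidate architecture's forward curve by least
squares and ranks by small-sample-corrected AIC (AICc), calling a winner
only at a margin of ≥ 2 units; otherwise "indeterminate". Three design
choices matter:

* **Calibrated constants.** In the experimental protocol k₂ and the
  binding scale are measured independently from the wild-type-alone
  titration before the mixing experiment is interpreted, so by default
  only the basal activity β is free per hypothesis (`free_params` opens
  k₂, K_orient and f_hle when no calibration exists). Freeing all
  rate-law parameters lets the architectures mimic one another — a
  weak-binding, high-β per-monomer curve can shadow a composite curve —
  and model selection then has no power at realistic noise.
* **Censored-mean fitting.** Measured rates are reported clipped at
  zero; near-zero model values are therefore compared to the censored
  expectation E[max(0, m+ε)] with the noise scale pooled from
  replicates, which removes a systematic upward misfit in the
  inhibitory tail.
* **Null gate.** A constant-rate model is always fit alongside; no
  verdict is issued unless the best architecture outranks it, so flat
  pure-noise data return "indeterminate".

The recovery simulation study uses a titration design of the mutant-free
anchor plus 12 log-spaced concentrations over 0.1–15 µM, each in 10
replicates. The replicate count was set by power analysis on pilot
simulations: composite-generated curves have roughly a tenth of the
noise variance as signal, and ~130 measurements are what bring
their recovery above 95% at noise sd 0.02; wild-type-like per-monomer
curves are recovered essentially always. The study seeds are explicit
and every verdict is deterministic given them.

## Energetics

ΔΔG‡ = R·T·ln(fold) with R = 1.9872×10⁻³ kcal/(mol·K) and T defaulting
to the 303.15 K assay temperature; with these constants the package
reproduces the printed ≥ 7.6 kcal/mol (fold 3×10⁵) and 1.4 kcal/mol
(fold 10) exactly at two significant figures, which is also the
reporting precision; full precision is kept internally. Detection-limit
bounds propagate an `is_lower_bound` flag through every conversion.

## Stem-loop scanner

The consensus is a 7-nt loop C-N-G-N-N-G-N closed by a stem of
consecutive Watson–Crick pairs (≥ 5 by default, configurable because the
canonical substrates show "approximately five"; G·U wobble optional and
off by default). Coordinates are 0-based half-open; `cleavage_site`
counts nucleotides 5′ of the scissile phosphate, which lies 3′ of the
loop-position-3 G — these conventions are declared here because none are
standard. Each consensus window seeds at most one hit with its maximal
stem extension; bulged or interrupted stems are not modelled, and no
thermodynamic folding is attempted. DNA input is normalized T→U with a
logged notice; an ambiguous N matches free loop positions but never the
three fixed consensus bases, and never pairs in a stem. Cleavability
annotation implements the 2′-O-methyl rule: a mark on the scissile G —
and only there — blocks formation of the 2′,3′-cyclic phosphate and
hence cleavage, which is what protects the mature (modified) tRNA-Phe
pool. The test-suite oracle enumerates all window/extension combinations
exhaustively; packaged fixtures are synthetic consensus hairpins, and
the tRNA-Phe anticodon arm used in the analysis scripts is a synthetic
stand-in assembled from the canonical anticodon-arm pattern.

## Problem sizes

Simulation studies in the tests and the acceptance script use 100 seeds
for parameter-recovery and hypothesis-recovery studies, 25–75 seeded
replicates for median fits, 10⁵ Monte-Carlo trials for oracle
comparisons, and 1,000 random 60-mers for scanner/oracle equivalence —
sizes at which the Monte-Carlo error bands quoted above are small
relative to the tested tolerances.

## Known limitations

* The Hill two-state assembly and the orientation-level binding scheme
  are surrogates; they reproduce qualitative signatures (threshold
  assembly, two-phase titration, trans-HLE ordering), not absolute
  published rates, which depend on unpublished raw data.
* Asymptotic standard errors undercover slightly at small n; a bootstrap
  is available behind a flag but is not the default.
* The activation fold of the per-monomer forward model (~4.4 under
  defaults) is parameter-dependent; only its qualitative two-phase shape
  is asserted.
* The scanner treats stems as perfect duplexes and will miss hairpins
  with bulges that a folding program would recover.
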