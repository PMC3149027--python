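"""Cooperative Ire1 self-assembly and mixed-oligomer interface statistics.

Ire1 RNase activation requires assembly into oligomers above a sharp,
low-micromolar concentration threshold (observable as light scattering).
The assembled fraction is modelled as a two-state Hill transition

    phi(c) = c**n / (c**n + C_thresh**n)

Catalytically dead point mutants oligomerize indistinguishably from
wild type, so in a wild-type/mutant mixture the monomers co-assemble
and pair randomly into back-to-back RNase-dimer interfaces. With
wild-type fraction ``x`` the interface classes follow the binomial
partition (x^2, 2x(1-x), (1-x)^2); these hetero-interfaces are the
substrate of the trans-complementation analysis in
:mod:`ire1_rnase.transact`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class OligomerModelParams:
    """Hill-type oligomerization: threshold (uM) and steepness."""

    C_thresh: float = 3.0
    n_hill: float = 8.0

    def __post_init__(self) -> None:
        if self.C_thresh <= 0.0:
            raise ValueError(f"C_thresh must be > 0 (got {self.C_thresh})")
        if self.n_hill < 1.0:
            raise ValueError(f"n_hill must be >= 1 (got {self.n_hill})")


@dataclass(frozen=True)
class Species:
    """One Ire1 variant in a mixture.

    ``catalysis_intact`` tracks the H1061 general acid (False for H1061N);
    ``hle_intact`` tracks the helix-loop-element arginine R1039 (False for
    R1039A).
    """

    concentration: float
    catalysis_intact: bool = True
    hle_intact: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0.0:
            raise ValueError("species concentration must be >= 0")


@dataclass(frozen=True)
class MixtureState:
    """A set of co-oligomerizing Ire1 variants."""

    species: tuple[Species, ...]

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("mixture needs at least one species")

    @property
    def total(self) -> float:
        return float(sum(s.concentration for s in self.species))

    @property
    def wt_fraction(self) -> float:
        """Fraction of monomers that are catalysis-intact."""
        total = self.total
        if total == 0.0:
            raise ValueError("all-zero mixture has no defined composition")
        wt = sum(s.concentration for s in self.species if s.catalysis_intact)
        return wt / total


@dataclass(frozen=True)
class InterfaceCensus:
    """Concentrations (uM) of the RNase-dimer interface classes.

    ``ww``: both monomers catalysis-intact; ``wm``: hetero; ``mm``: both
    mutant. ``wt_fraction`` is the monomer-level wild-type fraction x the
    binomial probabilities (x^2, 2x(1-x), (1-x)^2) were computed from.
    """

    ww: float
    wm: float
    mm: float
    wt_fraction: float
    total_interfaces: float = field(default=0.0)

    @property
    def probabilities(self) -> tuple[float, float, float]:
        if self.total_interfaces == 0.0:
            return (0.0, 0.0, 0.0)
        t = self.total_interfaces
        return (self.ww / t, self.wm / t, self.mm / t)


def oligomer_fraction(c_total: float, params: OligomerModelParams) -> float:
    """Assembled fraction phi(c) = c^n / (c^n + C_thresh^n).

    Monotone non-decreasing in ``c_total``; phi(C_thresh) = 0.5 exactly.
    """
    if c_total < 0.0:
        raise ValueError(f"concentration must be >= 0 (got {c_total})")
    if c_total == 0.0:
        return 0.0
    # work in log space to avoid overflow for large n_hill
    log_r = params.n_hill * (np.log(params.C_thresh) - np.log(c_total))
    if log_r > 700.0:
        return 0.0
    return float(1.0 / (1.0 + np.exp(log_r)))


def interface_distribution(
    mix: MixtureState, params: OligomerModelParams | None = None
) -> InterfaceCensus:
    """Binomial partition of assembled monomers into dimer interfaces.

    Each pair of assembled monomers contributes one RNase-dimer interface,
    so the interface concentration is ``phi * c_total / 2``; random pairing
    distributes it as (x^2, 2x(1-x), (1-x)^2) over (ww, wm, mm).
    """
    params = params or OligomerModelParams()
    total = mix.total
    if total <= 0.0:
        raise ValueError("mixture total concentration must be > 0")
    x = mix.wt_fraction
    phi = oligomer_fraction(total, params)
    c_if = phi * total / 2.0
    return InterfaceCensus(
        ww=c_if * x * x,
        wm=c_if * 2.0 * x * (1.0 - x),
        mm=c_if * (1.0 - x) ** 2,
        wt_fraction=x,
        total_interfaces=c_if,
    )


def monte_carlo_pairing(
    n_monomers: int,
    x: float,
    seed: int,
    n_trials: int = 10_000,
) -> dict[str, tuple[float, float]]:
    """Brute-force oracle for the binomial interface partition.

    Each trial labels ``n_monomers`` monomers wild type independently with
    probability ``x``, pairs them uniformly at random, and tallies the
    (ww, wm, mm) interface classes. Returns, per class, the mean frequency
    across trials and its Monte-Carlo standard error.
    """
    if n_monomers < 2 or n_monomers % 2:
        raise ValueError(f"n_monomers must be even and >= 2 (got {n_monomers})")
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must be in [0, 1] (got {x})")
    rng = np.random.default_rng(seed)
    labels = rng.random((n_trials, n_monomers)) < x
    # uniform random perfect matching realized by a per-trial shuffle
    # followed by pairing of adjacent slots
    labels = rng.permuted(labels, axis=1)
    a = labels[:, 0::2]
    b = labels[:, 1::2]
    n_pairs = n_monomers // 2
    ww = (a & b).sum(axis=1) / n_pairs
    mm = (~a & ~b).sum(axis=1) / n_pairs
    wm = 1.0 - ww - mm
    out: dict[str, tuple[float, float]] = {}
    for name, freqs in (("ww", ww), ("wm", wm), ("mm", mm)):
        out[name] = (
            float(freqs.mean()),
            float(freqs.std(ddof=1) / np.sqrt(n_trials)),
        )
    return out
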