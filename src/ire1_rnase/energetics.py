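"""Transition-state energetics from rate-constant ratios.

A fold-change ``F`` in a first-order rate constant between two enzyme
variants corresponds to a difference in transition-state stabilization

    ddG = R * T * ln(F)

with ``R`` the gas constant in kcal/(mol K). Detection-limited
measurements (a mutant whose rate falls below the assay floor) yield
lower bounds on ``F`` and hence on ``ddG``; the bound flag is carried
through every conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Gas constant, kcal / (mol K).
R_KCAL = 1.9872e-3

#: Default assay temperature, K (30 degrees C).
T_ASSAY = 303.15


@dataclass(frozen=True)
class EnergyResult:
    """A transition-state stabilization energy and its provenance.

    Attributes
    ----------
    ddg : float
        Stabilization energy in kcal/mol (full precision).
    fold : float
        The rate-constant ratio the energy was derived from; >= 1 by
        convention, the direction of the effect is the caller's to track.
    is_lower_bound : bool
        True when the fold change is itself a lower bound (detection
        limited), in which case ``ddg`` is a lower bound too.
    temperature : float
        Temperature in K used for the conversion.
    """

    ddg: float
    fold: float
    is_lower_bound: bool
    temperature: float

    def round_sig(self, sig: int = 2) -> float:
        """``ddg`` rounded to ``sig`` significant figures for reporting."""
        if self.ddg == 0.0:
            return 0.0
        exponent = math.floor(math.log10(abs(self.ddg)))
        return round(self.ddg, -exponent + sig - 1)

    def __str__(self) -> str:  # one-line report used by the CLI
        prefix = ">= " if self.is_lower_bound else ""
        return (
            f"ddG = {prefix}{self.round_sig()} kcal/mol "
            f"(fold {prefix}{self.fold:g}, T = {self.temperature:g} K)"
        )


def ddg_from_fold(
    fold: float,
    temperature: float = T_ASSAY,
    is_lower_bound: bool = False,
) -> EnergyResult:
    """Convert a rate-constant fold change into kcal/mol.

    Parameters
    ----------
    fold : float
        Rate ratio, >= 1. Normalize direction before calling (a 10-fold
        slower mutant enters as ``fold=10``).
    temperature : float
        Kelvin; defaults to the 30 C cleavage-assay temperature.
    is_lower_bound : bool
        Propagated onto the result.
    """
    if fold < 1.0:
        raise ValueError(
            f"fold must be >= 1 (got {fold}); pre-normalize the direction"
        )
    if temperature <= 0.0:
        raise ValueError(f"temperature must be positive (got {temperature})")
    ddg = R_KCAL * temperature * math.log(fold)
    return EnergyResult(ddg=ddg, fold=fold, is_lower_bound=is_lower_bound,
                        temperature=temperature)


def fold_from_ddg(ddg: float, temperature: float = T_ASSAY) -> float:
    """Inverse of :func:`ddg_from_fold` (kcal/mol -> fold)."""
    if temperature <= 0.0:
        raise ValueError(f"temperature must be positive (got {temperature})")
    return math.exp(ddg / (R_KCAL * temperature))


def fold_bound_from_detection_limit(
    k_wt: float,
    detection_floor: float,
    temperature: float = T_ASSAY,
) -> EnergyResult:
    """Lower bound on the fold effect of a mutation whose rate is unmeasurable.

    When a mutant shows no detectable cleavage, all that is known is that
    its rate lies below the assay floor, so the fold reduction relative to
    the wild-type rate ``k_wt`` is at least ``k_wt / detection_floor``.
    The result always carries ``is_lower_bound=True``.
    """
    if detection_floor <= 0.0:
        raise ValueError("detection_floor must be positive")
    if k_wt <= detection_floor:
        raise ValueError(
            f"k_wt ({k_wt}) must exceed the detection floor "
            f"({detection_floor}); no bound is derivable"
        )
    fold = k_wt / detection_floor
    return ddg_from_fold(fold, temperature=temperature, is_lower_bound=True)
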