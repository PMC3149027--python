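"""Curve fitting for the single-turnover Ire1 cleavage assays.

Four curve families cover the quantitative assays:

* single-turnover time courses, fraction cleaved vs time, fit to
  ``A * (1 - exp(-k_obs * t))``;
* enzyme-titration profiles, k_obs vs total enzyme E0, fit to the
  hyperbola ``k2 * E0 / (K_half + E0)`` yielding the plateau rate k2 and
  the half-saturating enzyme concentration K_1/2;
* cold-competitor inhibition of tracer cleavage, fit to
  ``k0 / (1 + C / K)`` — with cognate competitor K is the Michaelis
  constant Km, with a non-substrate ligand it is an apparent Ki;
* multiple-turnover Michaelis-Menten initial velocities,
  ``v = kcat * E0 * S / (Km + S)``.

Under single-turnover conditions the labelled substrate is at tracer
level (<= 1 pM) so the enzyme and competitor pools are never depleted;
all binding math treats the tracer concentration as exactly zero.

Fits use Levenberg-Marquardt least squares (lmfit); reported errors are
asymptotic standard errors from the curvature of the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

#: rates below this floor (1/s) are treated as unmeasurable and reported
#: as upper bounds, enabling ">= fold-reduction" statements
DETECTION_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class TimeCourse:
    """One single-turnover cleavage reaction (times in s, fractions in [0,1])."""

    times: np.ndarray
    fractions: np.ndarray
    enzyme_conc: float = float("nan")
    substrate_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.ndim != 1 or t.size != f.size:
            raise ValueError("times and fractions must be aligned 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if f.size and (np.any(f < -1e-12) or np.any(f > 1 + 1e-12)):
            raise ValueError("fractions must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)


@dataclass(frozen=True)
class TitrationProfile:
    """k_obs (1/s) as a function of total enzyme E0 (uM)."""

    enzyme_concs: np.ndarray
    k_obs_values: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.enzyme_concs, dtype=float)
        k = np.asarray(self.k_obs_values, dtype=float)
        if e.ndim != 1 or e.size != k.size:
            raise ValueError("enzyme_concs and k_obs_values must align")
        if np.any(e <= 0):
            raise ValueError("enzyme concentrations must be > 0")
        object.__setattr__(self, "enzyme_concs", e)
        object.__setattr__(self, "k_obs_values", k)


@dataclass(frozen=True)
class InhibitionSeries:
    """k_obs (1/s) vs cold competitor concentration (uM)."""

    competitor_concs: np.ndarray
    k_obs_values: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.competitor_concs, dtype=float)
        k = np.asarray(self.k_obs_values, dtype=float)
        if c.ndim != 1 or c.size != k.size:
            raise ValueError("competitor_concs and k_obs_values must align")
        if np.any(c < 0):
            raise ValueError("competitor concentrations must be >= 0")
        object.__setattr__(self, "competitor_concs", c)
        object.__setattr__(self, "k_obs_values", k)


@dataclass(frozen=True)
class RateFit:
    """Result of a single-exponential time-course fit."""

    k_obs: float
    endpoint: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    is_upper_bound: bool = False
    poor_fit: bool = False


@dataclass(frozen=True)
class SaturationFit:
    """(k2, K_1/2) from an enzyme-titration profile."""

    k2: float
    K_half: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    K_half_identifiable: bool = True


@dataclass(frozen=True)
class BindingFit:
    """(k0, K) from a competitive-inhibition series.

    ``K`` is Km when the competitor is the cold cognate substrate, an
    apparent Ki otherwise. ``K_is_lower_bound`` is set when the series
    shows no decay, in which case K is only bounded from below.
    """

    k0: float
    K: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    K_is_lower_bound: bool = False


@dataclass(frozen=True)
class MichaelisFit:
    kcat: float
    Km_mt: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True


# ---------------------------------------------------------------------------
# model functions (shared with the generators)

def exponential_progress(t, k_obs, endpoint):
    """Fraction cleaved at time t under first-order approach to a plateau."""
    return endpoint * -np.expm1(-k_obs * np.asarray(t, dtype=float))


def saturation_hyperbola(E0, k2, K_half):
    E0 = np.asarray(E0, dtype=float)
    return k2 * E0 / (K_half + E0)


def competitive_inhibition(C, k0, K):
    C = np.asarray(C, dtype=float)
    return k0 / (1.0 + C / K)


def michaelis_menten(S, kcat_E0, Km):
    S = np.asarray(S, dtype=float)
    return kcat_E0 * S / (Km + S)


# ---------------------------------------------------------------------------
# fitters

def _stderr(result, names: list[str]) -> dict[str, float]:
    out = {}
    for n in names:
        p = result.params[n]
        if p.stderr is not None:
            out[n] = float(p.stderr)
    return out


def fit_exponential(course: TimeCourse) -> RateFit:
    """Fit ``A * (1 - exp(-k t))`` to a time course.

    Initialization: the amplitude from the last observed fractions, the
    rate from a log-linear regression of ``-log(1 - f/A)`` over the early
    points, which removes sensitivity to starting guesses.
    """
    t, f = course.times, course.fractions
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if not np.any(f > 0):
        return RateFit(k_obs=float("nan"), endpoint=float("nan"),
                       converged=False)

    a0 = max(float(f.max()), 1e-6)
    k0 = _init_rate(t, f, a0)

    model = Model(exponential_progress)
    params = model.make_params(k_obs=k0, endpoint=min(a0 / 0.95, 1.0))
    params["k_obs"].set(min=0.0)
    params["endpoint"].set(min=1e-9, max=1.5)
    result = model.fit(f, params, t=t)

    k_hat = float(result.params["k_obs"].value)
    poor = bool(np.corrcoef(f, result.best_fit)[0, 1] < 0) if f.std() else False
    return RateFit(
        k_obs=max(k_hat, DETECTION_FLOOR) if k_hat < DETECTION_FLOOR else k_hat,
        endpoint=float(result.params["endpoint"].value),
        standard_errors=_stderr(result, ["k_obs", "endpoint"]) if result.success else {},
        converged=bool(result.success),
        is_upper_bound=k_hat < DETECTION_FLOOR,
        poor_fit=poor,
    )


def _init_rate(t: np.ndarray, f: np.ndarray, amplitude: float) -> float:
    """Log-linear rate estimate from points below ~80% of the amplitude."""
    frac = np.clip(f / (amplitude / 0.9), 1e-9, 1 - 1e-9)
    early = (frac < 0.8) & (t > 0)
    if early.sum() >= 2:
        slope = np.polyfit(t[early], -np.log1p(-frac[early]), 1)[0]
        if slope > 0:
            return float(slope)
    # fall back to the half-life of the midpoint crossing
    half_idx = int(np.searchsorted(f, amplitude / 2.0))
    t_half = t[min(half_idx, t.size - 1)] or t[-1]
    return float(np.log(2.0) / t_half)


def fit_titration(profile: TitrationProfile) -> SaturationFit:
    """Fit the hyperbola k_obs = k2 E0 / (K_half + E0).

    K_1/2 is flagged unidentifiable when the sampled concentrations only
    probe the plateau (relative standard error above 100%).
    """
    E0, k = profile.enzyme_concs, profile.k_obs_values
    if np.unique(E0).size < 4:
        raise ValueError("need at least 4 distinct enzyme concentrations")

    k2_0 = max(float(k.max()), 1e-9)
    half = np.abs(k - k2_0 / 2.0)
    K0 = float(E0[np.argmin(half)])

    model = Model(saturation_hyperbola)
    params = model.make_params(k2=k2_0, K_half=max(K0, 1e-6))
    params["k2"].set(min=0.0)
    params["K_half"].set(min=1e-12)
    result = model.fit(k, params, E0=E0)

    K_hat = float(result.params["K_half"].value)
    err = _stderr(result, ["k2", "K_half"]) if result.success else {}
    rel_err = err.get("K_half", float("inf")) / K_hat if K_hat > 0 else float("inf")
    return SaturationFit(
        k2=float(result.params["k2"].value),
        K_half=K_hat,
        standard_errors=err,
        converged=bool(result.success),
        K_half_identifiable=bool(result.success and rel_err <= 1.0),
    )


def fit_inhibition(series: InhibitionSeries) -> BindingFit:
    """Fit k_obs = k0 / (1 + C/K); both k0 and K are free.

    A series that is flat within noise carries no information on K beyond
    a lower bound; in that case K is reported as the largest competitor
    concentration probed, flagged as a bound.
    """
    C, k = series.competitor_concs, series.k_obs_values
    if C.size < 4:
        raise ValueError("need at least 4 competitor concentrations")
    if C.min() > 1e-3 * max(C.max(), 1.0):
        raise ValueError("series needs a [C]=0 or near-zero anchor point")

    k0_0 = max(float(k[np.argmin(C)]), 1e-9)
    # flat-series guard: no decay resolvable above the scatter
    decay = k0_0 - float(k[np.argmax(C)])
    scatter = float(np.std(k)) or 1e-12
    if decay < scatter / np.sqrt(C.size):
        return BindingFit(k0=k0_0, K=float(C.max()), converged=True,
                          K_is_lower_bound=True)

    half = np.abs(k - k0_0 / 2.0)
    K0 = float(C[np.argmin(half)]) or float(np.median(C[C > 0]))

    model = Model(competitive_inhibition)
    params = model.make_params(k0=k0_0, K=max(K0, 1e-6))
    params["k0"].set(min=0.0)
    params["K"].set(min=1e-12)
    result = model.fit(k, params, C=C)
    return BindingFit(
        k0=float(result.params["k0"].value),
        K=float(result.params["K"].value),
        standard_errors=_stderr(result, ["k0", "K"]) if result.success else {},
        converged=bool(result.success),
    )


def fit_michaelis(
    substrate_concs: np.ndarray,
    velocities: np.ndarray,
    enzyme_conc: float,
) -> MichaelisFit:
    """Multiple-turnover fit v = kcat E0 S / (Km + S)."""
    S = np.asarray(substrate_concs, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if np.unique(S).size < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be > 0")

    vmax0 = max(float(v.max()), 1e-9)
    Km0 = float(S[np.argmin(np.abs(v - vmax0 / 2.0))])

    model = Model(michaelis_menten)
    params = model.make_params(kcat_E0=vmax0, Km=max(Km0, 1e-6))
    params["kcat_E0"].set(min=0.0)
    params["Km"].set(min=1e-12)
    result = model.fit(v, params, S=S)

    err = _stderr(result, ["kcat_E0", "Km"]) if result.success else {}
    scaled = {"kcat": err.get("kcat_E0", float("nan")) / enzyme_conc,
              "Km_mt": err.get("Km", float("nan"))}
    return MichaelisFit(
        kcat=float(result.params["kcat_E0"].value) / enzyme_conc,
        Km_mt=float(result.params["Km"].value),
        standard_errors={k: v for k, v in scaled.items() if np.isfinite(v)},
        converged=bool(result.success),
    )
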