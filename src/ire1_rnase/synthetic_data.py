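"""Synthetic assay data with the statistical structure of the real assays.

Single-turnover cleavage of a trace (<= 1 pM) radiolabelled stem-loop by
excess Ire1 is quantified from gel band intensities; the generators here
emulate the resulting observables — exponential progress curves with a
plateau below 1, hyperbolic enzyme titrations, competitive-inhibition
decays, sigmoidal light-scattering oligomerization profiles, and the
two-phase wild-type + dead-mutant trans-complementation titration — with
additive Gaussian noise standing in for band-quantification error.

Every generator is deterministic given a :class:`NoiseModel` seed and
writes/reads plain CSV with a YAML parameter sidecar, so the whole
pipeline is testable without any laboratory data. Values pushed outside
their physical range by noise are clipped and the clipping events
counted (``n_clipped`` on each output).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import transact
from .assembly import Species
from .kinetics import (
    InhibitionSeries,
    TimeCourse,
    TitrationProfile,
    competitive_inhibition,
    exponential_progress,
    saturation_hyperbola,
)
from .transact import TransModelParams, TransTitrationData

#: default additive noise (sd on fraction cleaved or k_obs); conservative
#: relative to the within-twofold day-to-day rate variation of the assay
DEFAULT_SD = 0.02


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on the measured quantity."""

    sd_fraction: float = DEFAULT_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class AssayDesign:
    """Sampling grids of one assay.

    Kinetic assays run at 30 C (303.15 K); the light-scattering
    oligomerization readout is taken at room temperature and carries its
    own temperature field where needed.
    """

    time_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 60.0, 13)
    )
    enzyme_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(0.1, 15.0, 12)
    )
    competitor_grid: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            ([0.0], np.geomspace(0.5, 1000.0, 11))
        )
    )
    temperature: float = 303.15

    def __post_init__(self) -> None:
        for name in ("time_grid", "enzyme_grid", "competitor_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.size and (np.any(np.diff(g) <= 0) or np.any(g < 0)):
                raise ValueError(f"{name} must be strictly increasing and >= 0")
            object.__setattr__(self, name, g)
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class OligomerizationProfile:
    """Light-scattering readout (OD at 500 nm) vs total enzyme."""

    enzyme_concs: np.ndarray
    od_values: np.ndarray
    n_clipped: int = 0


def _add_noise(
    values: np.ndarray,
    noise: NoiseModel,
    lo: float = 0.0,
    hi: float | None = None,
) -> tuple[np.ndarray, int]:
    """Additive Gaussian noise followed by clipping; returns clip count."""
    if noise.sd_fraction == 0.0:
        return values.copy(), 0
    noisy = values + noise.rng().normal(0.0, noise.sd_fraction, values.shape)
    clipped = np.clip(noisy, lo, hi)
    return clipped, int(np.sum(clipped != noisy))


def gen_time_course(
    k_obs: float,
    endpoint: float = 0.9,
    design: AssayDesign | None = None,
    noise: NoiseModel | None = None,
    enzyme_conc: float = 3.0,
    substrate_label: str = "HP21",
) -> tuple[TimeCourse, int]:
    """Exponential single-turnover progress curve.

    fraction(t) = endpoint * (1 - exp(-k_obs t)) + noise, clipped to
    [0, 1]. The default endpoint of 0.9 reflects that gel assays rarely
    reach completion. Returns the course and the clip count.
    """
    design = design or AssayDesign()
    noise = noise or NoiseModel()
    if k_obs < 0:
        raise ValueError("k_obs must be >= 0")
    if not 0.0 < endpoint <= 1.0:
        raise ValueError("endpoint must be in (0, 1]")
    if design.time_grid.size == 0:
        raise ValueError("time grid is empty")
    clean = exponential_progress(design.time_grid, k_obs, endpoint)
    noisy, n_clip = _add_noise(clean, noise, lo=0.0, hi=1.0)
    return (
        TimeCourse(times=design.time_grid, fractions=noisy,
                   enzyme_conc=enzyme_conc, substrate_label=substrate_label),
        n_clip,
    )


def gen_titration(
    k2: float,
    K_half: float,
    design: AssayDesign | None = None,
    noise: NoiseModel | None = None,
) -> tuple[TitrationProfile, int]:
    """Hyperbolic enzyme-titration profile k_obs = k2 E0 / (K_half + E0)."""
    design = design or AssayDesign()
    noise = noise or NoiseModel()
    if k2 < 0:
        raise ValueError("k2 must be >= 0")
    if K_half <= 0:
        raise ValueError("K_half must be > 0")
    clean = saturation_hyperbola(design.enzyme_grid, k2, K_half)
    noisy, n_clip = _add_noise(clean, noise, lo=0.0)
    return TitrationProfile(design.enzyme_grid, noisy), n_clip


def gen_inhibition(
    k0: float,
    K: float,
    design: AssayDesign | None = None,
    noise: NoiseModel | None = None,
) -> tuple[InhibitionSeries, int]:
    """Competitive-inhibition decay k_obs = k0 / (1 + C/K).

    Tracer-limit binding: the labelled substrate (<= 1 pM) never depletes
    enzyme or cold competitor, so the competitor concentration enters the
    rate law directly.
    """
    design = design or AssayDesign()
    noise = noise or NoiseModel()
    if K <= 0:
        raise ValueError("K must be > 0")
    if np.any(design.competitor_grid < 0):
        raise ValueError("competitor concentrations must be >= 0")
    clean = competitive_inhibition(design.competitor_grid, k0, K)
    noisy, n_clip = _add_noise(clean, noise, lo=0.0)
    return InhibitionSeries(design.competitor_grid, noisy), n_clip


def gen_oligomerization(
    C_thresh: float = 3.0,
    n_hill: float = 8.0,
    amplitude: float = 0.1,
    design: AssayDesign | None = None,
    noise: NoiseModel | None = None,
) -> OligomerizationProfile:
    """Sigmoidal light-scattering profile OD(c) = amplitude * phi(c) * c.

    All Ire1 point mutants share the wild-type assembly parameters:
    generating the four genotype profiles from identical (C_thresh,
    n_hill) reproduces their experimentally indistinguishable
    oligomerization.
    """
    from .assembly import OligomerModelParams, oligomer_fraction

    design = design or AssayDesign()
    noise = noise or NoiseModel()
    p = OligomerModelParams(C_thresh=C_thresh, n_hill=n_hill)
    c = design.enzyme_grid
    clean = amplitude * np.array([oligomer_fraction(ci, p) for ci in c]) * c
    noisy, n_clip = _add_noise(clean, noise, lo=0.0)
    return OligomerizationProfile(c, noisy, n_clip)


def gen_trans_titration(
    hypothesis: str = "per_monomer",
    params: TransModelParams | None = None,
    mutant_grid: np.ndarray | None = None,
    wt_conc: float = 1.5,
    mutant_genotype: Species = transact.H1061N,
    noise: NoiseModel | None = None,
) -> tuple[TransTitrationData, int]:
    """Two-phase trans-complementation titration (wild type + dead mutant).

    Defaults follow the published design: wild type fixed at 1.5 uM, just
    below its oligomerization threshold, and the catalytically dead
    H1061N mutant titrated over 0.1-15 uM. The generating hypothesis is
    recorded on the output for recovery tests.
    """
    noise = noise or NoiseModel()
    if wt_conc <= 0:
        raise ValueError("wt_conc must be > 0")
    grid = (np.geomspace(0.1, 15.0, 12) if mutant_grid is None
            else np.asarray(mutant_grid, dtype=float))
    if np.any(grid < 0):
        raise ValueError("mutant concentrations must be >= 0")
    clean = transact.simulate_titration(wt_conc, grid, mutant_genotype,
                                        hypothesis, params)
    noisy, n_clip = _add_noise(clean.k_obs_values, noise, lo=0.0)
    return (
        TransTitrationData(wt_conc=wt_conc, mutant_grid=grid,
                           k_obs_values=noisy,
                           mutant_genotype=mutant_genotype,
                           generating_hypothesis=hypothesis),
        n_clip,
    )


# ---------------------------------------------------------------------------
# delimited-text output with YAML parameter sidecars

_COLUMNS = {
    "time_course": ("time_s", "fraction_cleaved"),
    "titration": ("enzyme_uM", "kobs_per_s"),
    "inhibition": ("competitor_uM", "kobs_per_s"),
    "oligomerization": ("enzyme_uM", "od500"),
    "trans_titration": ("mutant_uM", "kobs_per_s"),
}


def write_dataset(
    path: str | Path,
    kind: str,
    x: np.ndarray,
    y: np.ndarray,
    params: dict,
) -> Path:
    """Write a two-column CSV plus a ``<name>.params.yaml`` sidecar."""
    if kind not in _COLUMNS:
        raise ValueError(f"unknown dataset kind {kind!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = _COLUMNS[kind]
    pd.DataFrame({cols[0]: x, cols[1]: y}).to_csv(path, index=False)
    sidecar = path.with_suffix(".params.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"kind": kind, **params}, fh, sort_keys=True)
    return path


def read_dataset(path: str | Path) -> tuple[str, pd.DataFrame]:
    """Read a dataset CSV, inferring its kind from the header columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty input file") from exc
    for kind, cols in _COLUMNS.items():
        if tuple(df.columns[:2]) == cols:
            return kind, df
    raise ValueError(
        f"{path}: unrecognized columns {list(df.columns)!r}; expected one of "
        + ", ".join(str(c) for c in _COLUMNS.values())
    )
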