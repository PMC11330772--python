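"""Seeded generators for every input the analysis pipeline consumes.

Each generator evaluates the corresponding forward model exactly and then
applies a declared noise model, so generator/fitter pairs form parameter-
recovery loops with known ground truth.  Defaults emulate the experimental
designs of the AAO characterization this package implements: saturating
initial-rate grids, stopped-flow kobs series averaged over replicates,
flavin band-shape spectral evolutions and Wiseman-type ITC titrations.

Default noise levels: multiplicative 2% on initial rates, 3% on kobs,
additive 0.002 AU on spectra and additive 2% of the largest |heat| on ITC
injections.  Seeds are explicit arguments, never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .binding_thermo import BindingParams, ItcExperiment, one_site_heats
from .constants import o2_percent_to_uM
from .errors import InputError
from .spectral import SpectraMatrix, StepScheme, species_profiles
from .steady_state import BiSubstrateDataset, SteadyStateParams, rate_from_params
from .transient import (
    BindingKinetics,
    KobsSeries,
    ReductionParams,
    ReoxidationParams,
    hyperbolic_kobs,
    linear_kobs,
)


@dataclass(frozen=True)
class NoiseSpec:
    """Declared noise model; identical seeds give bit-identical output."""

    kind: Literal["multiplicative_gaussian", "additive_gaussian"] = (
        "multiplicative_gaussian"
    )
    sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InputError("noise sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray,
              rng: np.random.Generator | None = None) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sd == 0:
            return values.copy()
        if rng is None:
            rng = self.rng()
        if self.kind == "multiplicative_gaussian":
            return values * (1.0 + rng.normal(0.0, self.sd, values.shape))
        return values + rng.normal(0.0, self.sd, values.shape)


# ---------------------------------------------------------------------------
# reference parameter sets (published steady-state, transient and ITC
# characterizations of PeAAO and BaAAO; second-order constants s^-1 mM^-1)
# ---------------------------------------------------------------------------

STEADY_STATE_PRESETS: dict[tuple[str, str, str], SteadyStateParams] = {
    ("PeAAO", "4-methoxybenzyl", "O2"): SteadyStateParams(201.0, 50.0, 176.0),
    ("PeAAO", "4-methoxybenzyl", "BQ"): SteadyStateParams(49.0, 7.0, 48.0),
    ("BaAAO", "4-methoxybenzyl", "O2"): SteadyStateParams(74.0, 331.0, 134.0),
    ("BaAAO", "4-methoxybenzyl", "BQ"): SteadyStateParams(31.0, 82.0, 70.0),
    ("PeAAO", "3-Cl-4-methoxybenzyl", "O2"): SteadyStateParams(43.0, 11.0, 67.0),
    ("PeAAO", "3-Cl-4-methoxybenzyl", "BQ"): SteadyStateParams(21.0, 4.0, 29.0),
    ("BaAAO", "3-Cl-4-methoxybenzyl", "O2"): SteadyStateParams(70.0, 94.0, 225.0),
    ("BaAAO", "3-Cl-4-methoxybenzyl", "BQ"): SteadyStateParams(23.0, 26.0, 66.0),
}

REDUCTION_PRESETS: dict[tuple[str, str], ReductionParams] = {
    ("PeAAO", "4-methoxybenzyl"): ReductionParams(251.0, 80.0, 0.0),
    ("BaAAO", "4-methoxybenzyl"): ReductionParams(117.0, 765.0, 0.0),
    ("PeAAO", "3-Cl-4-methoxybenzyl"): ReductionParams(96.0, 21.0, 0.0),
    ("BaAAO", "3-Cl-4-methoxybenzyl"): ReductionParams(121.0, 300.0, 0.0),
}

#: apparent second-order reoxidation constants, s^-1 mM^-1 (12 °C)
REOXIDATION_PRESETS: dict[tuple[str, str, str], ReoxidationParams] = {
    ("PeAAO", "4-methoxybenzyl", "O2"): ReoxidationParams(770.0, 17.0),
    ("PeAAO", "4-methoxybenzyl", "BQ"): ReoxidationParams(792.0, 55.0),
    ("BaAAO", "4-methoxybenzyl", "O2"): ReoxidationParams(216.0, 14.0),
    ("BaAAO", "4-methoxybenzyl", "BQ"): ReoxidationParams(175.0, 19.0),
    ("PeAAO", "3-Cl-4-methoxybenzyl", "O2"): ReoxidationParams(790.0, 17.0),
    ("PeAAO", "3-Cl-4-methoxybenzyl", "BQ"): ReoxidationParams(760.0, 55.0),
    ("BaAAO", "3-Cl-4-methoxybenzyl", "O2"): ReoxidationParams(123.0, 14.0),
    ("BaAAO", "3-Cl-4-methoxybenzyl", "BQ"): ReoxidationParams(84.0, 19.0),
}

BINDING_PRESETS: dict[tuple[str, str], BindingKinetics] = {
    ("PeAAO", "4-methoxybenzoic acid"): BindingKinetics(18.0, 3.0),
    ("BaAAO", "4-methoxybenzoic acid"): BindingKinetics(10.0, 18.0),
    # PeAAO / 3-Cl acid: no dissociation detected (koff "nd"); kon only
    ("PeAAO", "3-Cl-4-methoxybenzoic acid"): BindingKinetics(37.0, 0.0),
    ("BaAAO", "3-Cl-4-methoxybenzoic acid"): BindingKinetics(47.0, 13.0),
}

ITC_PRESETS: dict[str, BindingParams] = {
    # Kd 0.05 µM -> Ka 2e7 M^-1; Kd 27.1 µM -> Ka 3.69e4 M^-1
    "BaAAO": BindingParams(Ka_per_M=1e6 / 0.05, dH_kcal_mol=-21.4),
    "PeAAO": BindingParams(Ka_per_M=1e6 / 27.1, dH_kcal_mol=-25.1),
}

#: standard gas-mixture series used for O2 bi-substrate grids, %O2
O2_PERCENT_SERIES: tuple[float, ...] = (4.0, 10.0, 21.0, 44.0, 100.0)


def o2_grid_uM(percents=O2_PERCENT_SERIES, **kwargs) -> np.ndarray:
    """Dissolved-O2 grid (µM) from gas-mixture percentages."""
    return np.array([o2_percent_to_uM(p, **kwargs) for p in percents])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_bisubstrate(
    params: SteadyStateParams,
    model: str = "ping-pong",
    A_grid_uM=None,
    B_grid_uM=None,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 1,
    meta: dict | None = None,
) -> BiSubstrateDataset:
    """Initial-rate grid from the chosen bi-substrate law plus noise.

    Default grids span 0.2–10× the respective Km with five log-spaced
    levels each, mirroring a saturating bi-substrate design.
    """
    if A_grid_uM is None:
        A_grid_uM = np.geomspace(0.2, 10.0, 5) * params.Km_alcohol_uM
    if B_grid_uM is None:
        B_grid_uM = np.geomspace(0.2, 10.0, 5) * params.Km_acceptor_uM
    A_grid_uM = np.asarray(A_grid_uM, dtype=float)
    B_grid_uM = np.asarray(B_grid_uM, dtype=float)
    if np.any(A_grid_uM <= 0) or np.any(B_grid_uM <= 0):
        raise InputError("grids must be strictly positive")

    A_mesh, B_mesh = np.meshgrid(A_grid_uM, B_grid_uM, indexing="ij")
    A = np.tile(A_mesh.ravel(), n_replicates)
    B = np.tile(B_mesh.ravel(), n_replicates)
    rep = np.repeat(np.arange(n_replicates), A_mesh.size)
    clean = np.asarray(rate_from_params(A, B, params, model), dtype=float)
    noisy = np.maximum(noise.apply(clean), 0.0)
    md = dict(meta or {})
    md.update({"generator": "gen_bisubstrate", "model": model,
               "noise": noise, "truth": params})
    return BiSubstrateDataset(A, B, noisy, rep, meta=md)


def gen_kobs(
    params: ReductionParams | ReoxidationParams | BindingKinetics,
    conc_grid_uM,
    noise: NoiseSpec = NoiseSpec(sd=0.03),
    n_replicates: int = 1,
    meta: dict | None = None,
) -> KobsSeries:
    """kobs series from the functional form matching the parameter type.

    With ``n_replicates > 1`` each reported point is the mean of that many
    independently noisy draws (the replicate-averaging used for stopped-
    flow transients), shrinking the effective noise by sqrt(replicates).
    """
    conc = np.asarray(conc_grid_uM, dtype=float)
    if isinstance(params, ReductionParams):
        clean = hyperbolic_kobs(conc, params.kred, params.Kd_alcohol_uM,
                                params.krev)
        role = "reductant"
    elif isinstance(params, ReoxidationParams):
        clean = linear_kobs(conc / 1000.0, params.app_kox,
                            params.krev_intercept)
        role = "electron_acceptor"
    elif isinstance(params, BindingKinetics):
        clean = linear_kobs(conc / 1000.0, params.kon, params.koff)
        role = "dead_end_ligand"
    else:
        raise InputError(f"unsupported parameter type {type(params)!r}")

    rng = noise.rng()
    draws = np.stack(
        [noise.apply(clean, rng) for _ in range(n_replicates)]
    )
    kobs = np.maximum(draws.mean(axis=0), 1e-12)
    se = draws.std(axis=0, ddof=1) / np.sqrt(n_replicates) \
        if n_replicates > 1 else None
    md = dict(meta or {})
    md.update({"generator": "gen_kobs", "noise": noise, "truth": params,
               "n_replicates": n_replicates})
    return KobsSeries(conc, kobs, se=se, ligand_role=role, meta=md)


# ---------------------------------------------------------------------------
# flavin spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianBand:
    center_nm: float
    width_nm: float
    amplitude_AU: float


@dataclass
class FlavinSpectrumTemplate:
    """Sum-of-Gaussian band shapes for the flavin redox states.

    Amplitudes are in AU for a ~10 µM flavoprotein in a 1 cm cell; the
    oxidized state shows band I near 462 nm and band II near 385 nm, both
    largely lost on two-electron reduction to the flavin hydroquinone.
    """

    oxidized: tuple[GaussianBand, ...] = (
        GaussianBand(462.0, 20.0, 0.110),
        GaussianBand(385.0, 16.0, 0.095),
    )
    reduced: tuple[GaussianBand, ...] = (
        GaussianBand(400.0, 60.0, 0.018),
    )
    #: long-wavelength feature distinguishing a partially reduced
    #: intermediate from any oxidized/reduced mixture
    intermediate_extra: tuple[GaussianBand, ...] = (
        GaussianBand(560.0, 45.0, 0.030),
    )
    baseline_AU: float = 0.005

    def __post_init__(self) -> None:
        for band in (*self.oxidized, *self.reduced):
            if band.amplitude_AU < 0:
                raise InputError("band amplitudes must be non-negative")
        peak = max(self.oxidized, key=lambda b: b.amplitude_AU)
        if not (450.0 <= peak.center_nm <= 470.0):
            raise InputError("oxidized band-I peak must lie in 450-470 nm")

    def spectrum(self, state: str, wavelengths) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        bands = {"oxidized": self.oxidized, "reduced": self.reduced}
        if state == "intermediate":
            ox = self.spectrum("oxidized", wl)
            red = self.spectrum("reduced", wl)
            out = 0.5 * (ox + red)
            for band in self.intermediate_extra:
                out += band.amplitude_AU * np.exp(
                    -0.5 * ((wl - band.center_nm) / band.width_nm) ** 2
                )
            return out
        out = np.full_like(wl, self.baseline_AU)
        for band in bands[state]:
            out += band.amplitude_AU * np.exp(
                -0.5 * ((wl - band.center_nm) / band.width_nm) ** 2
            )
        return out


#: stopped-flow style acquisition defaults for a reduction transient
DEFAULT_REDUCTION_TIMES = np.geomspace(0.003, 0.15, 30)
DEFAULT_WAVELENGTHS = np.arange(400.0, 701.0, 5.0)


def gen_spectra(
    scheme: StepScheme,
    template: FlavinSpectrumTemplate | None = None,
    times=None,
    wavelengths=None,
    noise: NoiseSpec = NoiseSpec(kind="additive_gaussian", sd=0.002),
    direction: Literal["reduction", "reoxidation"] = "reduction",
) -> SpectraMatrix:
    """Time-resolved absorbance matrix D = Σ c_i(t)·s_i(λ) + noise.

    Species spectra walk from oxidized to reduced for a reduction
    transient (reversed for reoxidation), with the midpoint mixture as the
    intermediate of a three-species scheme.
    """
    if template is None:
        template = FlavinSpectrumTemplate()
    t = DEFAULT_REDUCTION_TIMES if times is None \
        else np.asarray(times, dtype=float)
    wl = DEFAULT_WAVELENGTHS if wavelengths is None \
        else np.asarray(wavelengths, dtype=float)

    states = (["oxidized", "reduced"] if scheme.n_species == 2
              else ["oxidized", "intermediate", "reduced"])
    if direction == "reoxidation":
        states = states[::-1]
    S = np.vstack([template.spectrum(s, wl) for s in states])
    C = species_profiles(scheme, t)
    D = noise.apply(C @ S)
    return SpectraMatrix(times=t, wavelengths=wl, absorbance=D)


def gen_mono_trace(
    scheme: StepScheme,
    template: FlavinSpectrumTemplate | None = None,
    wavelength_nm: float = 462.0,
    times=None,
    noise: NoiseSpec = NoiseSpec(kind="additive_gaussian", sd=0.002),
    direction: Literal["reduction", "reoxidation"] = "reduction",
) -> tuple[np.ndarray, np.ndarray]:
    """Single-wavelength slice of :func:`gen_spectra` (times, trace)."""
    mat = gen_spectra(scheme, template, times,
                      np.array([wavelength_nm - 1.0, wavelength_nm]),
                      noise, direction)
    return mat.times, mat.absorbance[:, 1]


def gen_itc(
    params: BindingParams,
    exp: ItcExperiment,
    noise: NoiseSpec = NoiseSpec(kind="additive_gaussian", sd=0.02),
) -> ItcExperiment:
    """ITC experiment with simulated heats.

    Additive noise sd is interpreted as a fraction of the largest
    absolute injection heat (instrument noise floor scales with signal
    range, not per-injection magnitude).
    """
    clean = one_site_heats(params, exp)
    scale = float(np.max(np.abs(clean))) if clean.size else 1.0
    abs_noise = NoiseSpec(kind="additive_gaussian",
                          sd=noise.sd * scale, seed=noise.seed)
    heats = abs_noise.apply(clean)
    return ItcExperiment(
        cell_conc_uM=exp.cell_conc_uM,
        syringe_conc_uM=exp.syringe_conc_uM,
        injection_volumes_uL=exp.injection_volumes_uL.copy(),
        cell_volume_uL=exp.cell_volume_uL,
        temperature_K=exp.temperature_K,
        heats_ucal=heats,
        meta={**exp.meta, "generator": "gen_itc", "noise": noise,
              "truth": params},
    )


def default_itc_design(enzyme: str = "BaAAO") -> ItcExperiment:
    """19 × 2 µL titration at the nominal cell/syringe concentrations."""
    cell, syringe = (6.0, 50.0) if enzyme == "BaAAO" else (15.0, 100.0)
    return ItcExperiment(
        cell_conc_uM=cell,
        syringe_conc_uM=syringe,
        injection_volumes_uL=np.full(19, 2.0),
        meta={"enzyme": enzyme},
    )
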