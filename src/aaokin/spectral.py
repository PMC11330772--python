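"""Global analysis of time-resolved absorbance matrices.

Stopped-flow photodiode-array data are a matrix D(t, λ) assumed to follow a
first-order compartment scheme, A -> B (one step) or A -> B -> C (two
steps), so that D = C(k) · S + noise with C the concentration profiles for
rate constants k and S the species spectra.  Fitting uses variable
projection (separable least squares): for any candidate rates the spectra
are the linear least-squares solution S = C⁺D, and only the rates are
optimized on the projected residual.  Spectra are not constrained
non-negative by default — difference spectra may legitimately dip below
zero — but a non-negativity flag is available.

Single-wavelength (monochromator) traces are fitted with the equivalent
sum-of-exponentials-plus-offset model via the same separable split.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._stats import aicc
from .errors import FitError, InputError


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpectraMatrix:
    """Absorbance surface over time × wavelength."""

    times: np.ndarray        # s, strictly increasing, non-negative
    wavelengths: np.ndarray  # nm, strictly increasing
    absorbance: np.ndarray   # (n_times, n_wavelengths), AU

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(self.times < 0):
            raise InputError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InputError("wavelengths must be strictly increasing")
        if self.absorbance.shape != (self.times.size, self.wavelengths.size):
            raise InputError(
                "absorbance must be (n_times, n_wavelengths)"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise InputError("absorbance entries must be finite")


@dataclass
class StepScheme:
    """Sequential first-order scheme with n_species − 1 rate constants."""

    rate_constants: list[float]
    species_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.rate_constants) not in (1, 2):
            raise InputError("supported schemes: A->B and A->B->C")
        if any(k <= 0 for k in self.rate_constants):
            raise InputError("rate constants must be strictly positive")
        if self.species_labels is None:
            self.species_labels = ["A", "B", "C"][: self.n_species]
        if len(set(self.species_labels)) != len(self.species_labels):
            raise InputError("species labels must be unique")

    @property
    def n_species(self) -> int:
        return len(self.rate_constants) + 1


@dataclass
class GlobalFitResult:
    """Outcome of a global (all-wavelength) fit."""

    scheme: StepScheme
    species_spectra: np.ndarray   # (n_species, n_wavelengths)
    rate_stderr: list[float | None]
    residual_rms: float           # AU
    aicc: float
    singular_values: np.ndarray   # descending
    degenerate_warning: bool = False


@dataclass
class MonoExpFit:
    """Sum-of-exponentials fit of a single-wavelength trace."""

    rates: np.ndarray        # s^-1, descending
    amplitudes: np.ndarray   # AU, aligned with rates
    offset: float            # AU
    rate_stderr: np.ndarray
    amplitude_stderr: np.ndarray
    offset_stderr: float
    collinearity_warning: bool = False  # rate separation < 3x


@dataclass
class StepModelSelection:
    choice: int               # 1 or 2 steps
    fit_one: GlobalFitResult
    fit_two: GlobalFitResult | None
    rank: int
    zero_amplitude_warning: bool = False


# ---------------------------------------------------------------------------
# concentration profiles
# ---------------------------------------------------------------------------

def species_profiles(scheme: StepScheme, times) -> np.ndarray:
    """Normalized concentration fractions of each species over time.

    A -> B: c_A = exp(−k1 t), c_B = 1 − c_A.
    A -> B -> C: the two-compartment closed form; at k1 = k2 the confluent
    limit c_B = k1·t·exp(−k1 t) is used.
    """
    t = np.asarray(times, dtype=float)
    ks = scheme.rate_constants
    if len(ks) == 1:
        cA = np.exp(-ks[0] * t)
        return np.column_stack([cA, 1.0 - cA])
    k1, k2 = ks
    cA = np.exp(-k1 * t)
    if abs(k1 - k2) <= 1e-8 * max(k1, k2):
        cB = k1 * t * np.exp(-k1 * t)
    else:
        cB = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    cC = 1.0 - cA - cB
    return np.column_stack([cA, cB, cC])


def _profiles_from_rates(rates: np.ndarray, times: np.ndarray) -> np.ndarray:
    return species_profiles(StepScheme(list(np.abs(rates))), times)


# ---------------------------------------------------------------------------
# rank estimation
# ---------------------------------------------------------------------------

def estimate_rank(
    data: SpectraMatrix, noise_sd: float = 0.0, multiplier: float = 5.0,
) -> int:
    """Number of singular values above the noise floor.

    A singular value is retained when it exceeds
    ``multiplier · noise_sd · sqrt(max(n_times, n_wavelengths))``, a
    Marchenko–Pastur-style bound on the largest noise singular value.
    With noise_sd = 0 a machine-precision relative threshold is used.
    """
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    sv = np.linalg.svd(data.absorbance, compute_uv=False)
    if noise_sd == 0:
        thresh = sv[0] * max(data.absorbance.shape) * np.finfo(float).eps * 10
    else:
        thresh = multiplier * noise_sd * math.sqrt(max(data.absorbance.shape))
    return int(np.sum(sv > thresh))


# ---------------------------------------------------------------------------
# variable projection core
# ---------------------------------------------------------------------------

def _project(rates, times, D, nonneg=False):
    """Solve spectra for given rates; return (spectra, residual matrix)."""
    C = _profiles_from_rates(np.asarray(rates, dtype=float), times)
    if nonneg:
        S = np.empty((C.shape[1], D.shape[1]))
        for j in range(D.shape[1]):
            S[:, j], _ = optimize.nnls(C, D[:, j])
    else:
        S, *_ = np.linalg.lstsq(C, D, rcond=None)
    return S, D - C @ S


def _varpro_rss(log_rates, times, D, nonneg):
    _, R = _project(np.exp(log_rates), times, D, nonneg)
    return R.ravel()


class GlobalSpectralFit:
    """Variable-projection global fit of an n-step first-order scheme.

    Parameters
    ----------
    n_steps
        1 (A->B) or 2 (A->B->C).
    nonnegative_spectra
        Constrain fitted species spectra to be >= 0 (off by default).
    n_grid
        Size of the log-spaced rate grid used to seed the optimizer.

    Attributes (after :meth:`fit`)
    ------------------------------
    rate_constants_ : fitted rates, fast phase first (k1 >= k2).
    species_spectra_ : (n_species, n_wavelengths) linear solution.
    residual_rms_, aicc_, singular_values_, degenerate_warning_.
    """

    def __init__(self, n_steps: int = 1, nonnegative_spectra: bool = False,
                 n_grid: int = 30):
        if n_steps not in (1, 2):
            raise InputError("n_steps must be 1 or 2")
        self.n_steps = n_steps
        self.nonnegative_spectra = nonnegative_spectra
        self.n_grid = n_grid

    def _rate_grid(self, times: np.ndarray) -> np.ndarray:
        t = times[times > 0]
        if t.size == 0:
            raise InputError("need at least one positive time point")
        return np.geomspace(0.05 / t.max(), 5.0 / t.min(), self.n_grid)

    def fit(self, data: SpectraMatrix) -> "GlobalSpectralFit":
        D = data.absorbance
        times = data.times
        n_species = self.n_steps + 1
        if times.size < 3 * n_species:
            raise InputError(
                f"need >= {3 * n_species} time points for a "
                f"{self.n_steps}-step global fit"
            )

        grid = self._rate_grid(times)
        nonneg = self.nonnegative_spectra
        if self.n_steps == 1:
            candidates = [(k,) for k in grid]
        else:
            candidates = [
                (k1, k2) for k1 in grid for k2 in grid if k1 >= k2
            ]
        best_rss, best_k = np.inf, None
        for ks in candidates:
            _, R = _project(np.array(ks), times, D, nonneg)
            rss = float(np.sum(R**2))
            if rss < best_rss:
                best_rss, best_k = rss, np.array(ks, dtype=float)
        if best_k is None:
            raise FitError("rate grid scan failed")

        sol = optimize.least_squares(
            _varpro_rss, np.log(best_k), args=(times, D, nonneg),
            method="lm" if not nonneg else "trf",
        )
        if not sol.success:
            raise FitError(
                "variable-projection optimization did not converge; best "
                f"grid rates were {best_k}"
            )
        rates = np.exp(sol.x)

        # enforce fast-phase-first ordering; re-project after any swap
        order = np.argsort(rates)[::-1]
        rates = rates[order]
        S, R = _project(rates, times, D, nonneg)

        self.rate_constants_ = rates
        self.species_spectra_ = S
        self.residual_rms_ = float(np.sqrt(np.mean(R**2)))
        n_obs = D.size
        n_params = rates.size + S.size
        self.rss_ = float(np.sum(R**2))
        self.aicc_ = aicc(self.rss_, n_obs, n_params)
        self.singular_values_ = np.linalg.svd(D, compute_uv=False)

        # covariance of log-rates from the projected-residual Jacobian
        self.rate_stderr_ = self._rate_se(rates, times, D, nonneg)

        self.degenerate_warning_ = False
        if rates.size == 2:
            ratio = rates[0] / max(rates[1], 1e-300)
            span = np.abs(S).max(axis=1)
            if ratio > 1e4 or (span.max() > 0 and
                               span.min() < 1e-6 * span.max()):
                self.degenerate_warning_ = True
        return self

    def _rate_se(self, rates, times, D, nonneg):
        x = np.log(rates)
        f0 = _varpro_rss(x, times, D, nonneg)
        J = np.empty((f0.size, x.size))
        for i in range(x.size):
            h = 1e-6
            xp = x.copy()
            xp[i] += h
            J[:, i] = (_varpro_rss(xp, times, D, nonneg) - f0) / h
        dof = max(f0.size - x.size, 1)
        s2 = float(np.sum(f0**2)) / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            return [float(rates[i] * math.sqrt(max(cov[i, i], 0.0)))
                    for i in range(x.size)]
        except np.linalg.LinAlgError:
            return [None] * x.size

    def to_result(self) -> GlobalFitResult:
        return GlobalFitResult(
            scheme=StepScheme(list(self.rate_constants_)),
            species_spectra=self.species_spectra_,
            rate_stderr=self.rate_stderr_,
            residual_rms=self.residual_rms_,
            aicc=self.aicc_,
            singular_values=self.singular_values_,
            degenerate_warning=self.degenerate_warning_,
        )


def global_fit(data: SpectraMatrix, n_steps: int = 1,
               nonnegative_spectra: bool = False) -> GlobalFitResult:
    """Fit an A->B (n_steps=1) or A->B->C (n_steps=2) scheme globally."""
    return GlobalSpectralFit(
        n_steps=n_steps, nonnegative_spectra=nonnegative_spectra
    ).fit(data).to_result()


def select_step_model(data: SpectraMatrix, noise_sd: float = 0.0,
                      aicc_margin: float = 10.0) -> StepModelSelection:
    """Choose between one- and two-step schemes.

    The two-step model is selected only when it improves AICc by more than
    ``aicc_margin`` AND the SVD rank estimate supports three spectrally
    distinct species.  Rank-1 data (no evolution) degrade gracefully to a
    one-step result with a zero-amplitude warning.
    """
    rank = estimate_rank(data, noise_sd)
    fit1 = global_fit(data, 1)
    zero_amp = rank <= 1
    try:
        fit2 = global_fit(data, 2)
    except (InputError, FitError):
        fit2 = None
    if (
        fit2 is not None
        and not fit2.degenerate_warning
        and fit1.aicc - fit2.aicc > aicc_margin
        and rank >= 3
    ):
        return StepModelSelection(2, fit1, fit2, rank, zero_amp)
    return StepModelSelection(1, fit1, fit2, rank, zero_amp)


# ---------------------------------------------------------------------------
# monochromator traces
# ---------------------------------------------------------------------------

def monochromator_fit(times, trace, n_exp: int = 1) -> MonoExpFit:
    """Fit y(t) = offset + Σ a_i·exp(−k_i t) to a single-wavelength trace.

    Uses the same separable strategy as the global fit (amplitudes and
    offset linear, rates nonlinear).  A warning flag is raised when fitted
    rates are separated by less than 3×, where exponentials become
    collinear and amplitudes unreliable.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(trace, dtype=float)
    if t.size != y.size:
        raise InputError("times and trace must have equal length")
    if t.size < 10:
        raise InputError("monochromator fit needs >=10 time points")
    if n_exp not in (1, 2):
        raise InputError("n_exp must be 1 or 2")

    span = float(y.max() - y.min())
    if span < 1e-12 * max(1.0, abs(float(y.mean()))):
        # constant trace: zero amplitudes, nominal rate
        rates = np.full(n_exp, 1.0 / max(t[t > 0].min(), 1e-9)
                        if np.any(t > 0) else 1.0)
        return MonoExpFit(
            rates=rates,
            amplitudes=np.zeros(n_exp),
            offset=float(y.mean()),
            rate_stderr=np.full(n_exp, np.nan),
            amplitude_stderr=np.full(n_exp, np.nan),
            offset_stderr=0.0,
        )

    def basis(ks):
        cols = [np.ones_like(t)] + [np.exp(-k * t) for k in ks]
        return np.column_stack(cols)

    def resid(log_k):
        Bm = basis(np.exp(log_k))
        coef, *_ = np.linalg.lstsq(Bm, y, rcond=None)
        return Bm @ coef - y

    tpos = t[t > 0]
    grid = np.geomspace(0.05 / tpos.max(), 5.0 / tpos.min(), 25)
    if n_exp == 1:
        cands = [(k,) for k in grid]
    else:
        cands = [(k1, k2) for k1 in grid for k2 in grid if k1 > k2]
    best = min(cands, key=lambda ks: float(np.sum(resid(np.log(ks)) ** 2)))
    sol = optimize.least_squares(resid, np.log(np.array(best)), method="lm")
    if not sol.success:
        raise FitError("exponential trace fit did not converge")
    rates = np.exp(sol.x)
    order = np.argsort(rates)[::-1]
    rates = rates[order]
    Bm = basis(rates)
    coef, *_ = np.linalg.lstsq(Bm, y, rcond=None)
    offset, amps = float(coef[0]), np.asarray(coef[1:], dtype=float)

    # asymptotic SEs from the full-parameter Jacobian at the optimum
    def model_full(p):
        off = p[0]
        a = p[1:1 + n_exp]
        k = p[1 + n_exp:]
        return off + sum(a[i] * np.exp(-k[i] * t) for i in range(n_exp))

    p0 = np.concatenate([[offset], amps, rates])
    r0 = model_full(p0) - y
    J = np.empty((t.size, p0.size))
    for i in range(p0.size):
        h = 1e-7 * max(abs(p0[i]), 1e-7)
        pp = p0.copy()
        pp[i] += h
        J[:, i] = ((model_full(pp) - y) - r0) / h
    dof = max(t.size - p0.size, 1)
    s2 = float(np.sum(r0**2)) / dof
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p0.size, np.nan)

    collinear = bool(n_exp == 2 and rates[0] < 3.0 * rates[1])
    if collinear:
        warnings.warn("exponential rates separated by <3x; amplitudes "
                      "may be strongly correlated", stacklevel=2)
    return MonoExpFit(
        rates=rates,
        amplitudes=amps,
        offset=offset,
        rate_stderr=se[1 + n_exp:],
        amplitude_stderr=se[1:1 + n_exp],
        offset_stderr=float(se[0]),
        collinearity_warning=collinear,
    )
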