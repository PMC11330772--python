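"""Secondary analysis of stopped-flow observed rate constants.

Three functional forms cover the half-reactions and ligand binding of the
flavoenzyme cycle:

* reduction (hyperbolic): kobs = kred·A/(Kd + A) + krev — an
  enzyme:alcohol complex forms before hydride transfer to the flavin;
* reoxidation (linear): kobs = app_kox·[acceptor] + krev — apparent
  second-order reoxidation of the reduced flavin by O2 or quinone;
* dead-end ligand binding (linear): kobs = kon·[L] + koff, with the
  equilibrium constant Kd = koff/kon.

The two linear y-intercepts carry different meanings (reverse hydride
transfer vs complex dissociation) and are kept in separate result types.
Second-order constants are reported in s^-1 mM^-1 as conventionally
tabulated; concentrations enter in µM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import lmfit
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._stats import weighted_line_fit
from .errors import FitError, InputError

LigandRole = Literal["reductant", "electron_acceptor", "dead_end_ligand"]


@dataclass
class KobsSeries:
    """Observed first-order rate constants vs ligand concentration."""

    conc_uM: np.ndarray
    kobs_per_s: np.ndarray
    se: np.ndarray | None = None
    ligand_role: LigandRole = "reductant"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.kobs_per_s = np.asarray(self.kobs_per_s, dtype=float)
        if self.conc_uM.size != self.kobs_per_s.size:
            raise InputError("conc and kobs must have equal length")
        if np.any(self.conc_uM <= 0):
            raise InputError("ligand concentrations must be strictly positive")
        if np.any(self.kobs_per_s <= 0):
            raise InputError("kobs values must be strictly positive")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.size != self.conc_uM.size:
                raise InputError("se array length mismatch")
        n_levels = np.unique(self.conc_uM).size
        minimum = 4 if self.ligand_role == "reductant" else 3
        if n_levels < minimum:
            raise InputError(
                f"{self.ligand_role} series needs >={minimum} distinct "
                f"concentrations, got {n_levels}"
            )

    def __len__(self) -> int:
        return self.conc_uM.size


@dataclass
class ReductionParams:
    """Hyperbolic reductive half-reaction constants."""

    kred: float            # s^-1, limiting reduction rate
    Kd_alcohol_uM: float   # µM
    krev: float            # s^-1, reverse hydride transfer
    kred_se: float | None = None
    Kd_alcohol_se: float | None = None
    krev_se: float | None = None
    krev_negligible: bool = False   # 95% CI of krev includes 0
    saturation_warning: bool = False  # series did not approach kred

    @property
    def eff_red(self) -> float:
        """kred / Kd(alcohol), s^-1 mM^-1."""
        return self.kred / (self.Kd_alcohol_uM / 1000.0)


@dataclass
class ReoxidationParams:
    """Linear oxidative half-reaction constants."""

    app_kox: float          # s^-1 mM^-1
    krev_intercept: float   # s^-1, empirical y-intercept
    app_kox_se: float | None = None
    krev_intercept_se: float | None = None


@dataclass
class BindingKinetics:
    """Dead-end ligand association/dissociation constants.

    ``Kd_acid_uM`` is ``None`` (reported as "nd") when the fitted koff is
    statistically indistinguishable from zero — no dissociation detected.
    """

    kon: float              # s^-1 mM^-1
    koff: float             # s^-1
    kon_se: float | None = None
    koff_se: float | None = None

    @property
    def koff_detected(self) -> bool:
        if self.koff_se is None:
            return self.koff > 0
        return self.koff - 1.96 * self.koff_se > 0

    @property
    def Kd_acid_uM(self) -> float | None:
        if not self.koff_detected:
            return None
        return self.koff / self.kon * 1000.0

    @property
    def Kd_acid_se(self) -> float | None:
        """First-order (delta-method) propagated SE of Kd = koff/kon."""
        kd = self.Kd_acid_uM
        if kd is None or self.kon_se is None or self.koff_se is None:
            return None
        rel = math.sqrt(
            (self.koff_se / self.koff) ** 2 + (self.kon_se / self.kon) ** 2
        )
        return kd * rel


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def hyperbolic_kobs(A, kred: float, Kd_uM: float, krev: float = 0.0):
    """kobs = kred·A/(Kd + A) + krev with A in µM."""
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise InputError("concentrations must be non-negative")
    out = kred * A / (Kd_uM + A) + krev
    return out if out.ndim else float(out)


def linear_kobs(conc_mM, k2: float, intercept: float = 0.0):
    """kobs = k2·c + intercept with c in mM and k2 in s^-1 mM^-1."""
    conc_mM = np.asarray(conc_mM, dtype=float)
    out = k2 * conc_mM + intercept
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class HyperbolicKobsRegressor(RegressorMixin, BaseEstimator):
    """Least-squares fit of kobs = kred·A/(Kd+A) + krev.

    ``X`` is (n, 1) alcohol concentrations in µM, ``y`` the kobs values.
    Initial guesses: kred <- 1.2·max(kobs), Kd <- concentration at
    half-maximum (interpolated), krev <- min(kobs)/2.
    """

    def __init__(self, fix_krev: bool = False):
        self.fix_krev = fix_krev

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.size != y.size or X.size < 4:
            raise InputError("hyperbolic fit needs >=4 matched points")
        kmax = float(np.max(y))
        order = np.argsort(X)
        xs, ys = X[order], y[order]
        half = kmax / 2.0
        Kd0 = float(np.interp(half, ys, xs)) if ys[0] < half else float(xs[0])
        Kd0 = max(Kd0, 1e-6)

        params = lmfit.Parameters()
        params.add("kred", value=1.2 * kmax, min=1e-9)
        params.add("Kd", value=Kd0, min=1e-9)
        params.add("krev", value=float(np.min(y)) / 2.0, min=0.0,
                   vary=not self.fix_krev)

        def resid(p):
            v = p.valuesdict()
            return hyperbolic_kobs(X, v["kred"], v["Kd"], v["krev"]) - y

        res = lmfit.minimize(resid, params, method="leastsq")
        if not res.success:
            raise FitError("hyperbolic kobs fit did not converge")
        self.result_ = res
        v = res.params
        self.kred_ = float(v["kred"].value)
        self.Kd_ = float(v["Kd"].value)
        self.krev_ = float(v["krev"].value)
        self.stderr_ = {
            name: (None if v[name].stderr is None else float(v[name].stderr))
            for name in v
        }
        self.saturation_warning_ = kmax < 0.7 * self.kred_
        se = self.stderr_.get("krev")
        # "close to zero": CI touches 0 or krev is a vanishing fraction of kred
        self.krev_negligible_ = (
            se is None
            or self.krev_ - 1.96 * se <= 0
            or self.krev_ < 1e-6 * self.kred_
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        return hyperbolic_kobs(X, self.kred_, self.Kd_, self.krev_)


class LinearKobsRegressor(RegressorMixin, BaseEstimator):
    """Weighted straight-line fit of kobs against concentration in mM.

    ``X`` is (n, 1) concentrations in µM (converted internally), ``y`` the
    kobs values; optional per-point SEs give 1/se² weights.
    """

    def fit(self, X, y, se=None):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.size < 3:
            raise InputError("linear kobs fit needs >=3 points")
        conc_mM = X / 1000.0
        slope, intercept, slope_se, intercept_se = weighted_line_fit(
            conc_mM, y, se
        )
        self.slope_ = slope            # s^-1 mM^-1
        self.intercept_ = intercept    # s^-1
        self.slope_se_ = slope_se
        self.intercept_se_ = intercept_se
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        return self.slope_ * (X / 1000.0) + self.intercept_


# ---------------------------------------------------------------------------
# role-specific wrappers
# ---------------------------------------------------------------------------

def _require_role(series: KobsSeries, role: LigandRole) -> None:
    if series.ligand_role != role:
        raise InputError(
            f"expected ligand_role={role!r}, got {series.ligand_role!r}"
        )


def fit_reduction(series: KobsSeries) -> ReductionParams:
    """Fit the hyperbolic reductive half-reaction (kred, Kd, krev)."""
    _require_role(series, "reductant")
    reg = HyperbolicKobsRegressor().fit(series.conc_uM, series.kobs_per_s)
    return ReductionParams(
        kred=reg.kred_,
        Kd_alcohol_uM=reg.Kd_,
        krev=reg.krev_,
        kred_se=reg.stderr_.get("kred"),
        Kd_alcohol_se=reg.stderr_.get("Kd"),
        krev_se=reg.stderr_.get("krev"),
        krev_negligible=reg.krev_negligible_,
        saturation_warning=reg.saturation_warning_,
    )


def fit_reoxidation(series: KobsSeries) -> ReoxidationParams:
    """Fit the linear reoxidation dependence (app_kox, y-intercept)."""
    _require_role(series, "electron_acceptor")
    reg = LinearKobsRegressor().fit(series.conc_uM, series.kobs_per_s,
                                    se=series.se)
    if reg.slope_ <= 0:
        raise FitError("fitted app_kox is non-positive")
    return ReoxidationParams(
        app_kox=reg.slope_,
        krev_intercept=reg.intercept_,
        app_kox_se=reg.slope_se_,
        krev_intercept_se=reg.intercept_se_,
    )


def fit_binding_kinetics(series: KobsSeries) -> BindingKinetics:
    """Fit the linear complex-formation dependence (kon, koff, Kd)."""
    _require_role(series, "dead_end_ligand")
    reg = LinearKobsRegressor().fit(series.conc_uM, series.kobs_per_s,
                                    se=series.se)
    if reg.slope_ <= 0:
        raise FitError("fitted kon is non-positive")
    if reg.intercept_ < 0 and abs(reg.intercept_) > 2 * reg.intercept_se_:
        raise FitError(
            "fitted koff is negative beyond 2 SE; data inconsistent with "
            "a one-step binding model"
        )
    return BindingKinetics(
        kon=reg.slope_,
        koff=max(reg.intercept_, 0.0),
        kon_se=reg.slope_se_,
        koff_se=reg.intercept_se_,
    )
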