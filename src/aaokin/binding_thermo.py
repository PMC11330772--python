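"""One-site ITC isotherm simulation/fitting and thermodynamic relations.

An isothermal titration calorimetry experiment injects ligand (here,
benzoquinone) into a cell containing the enzyme and measures the heat of
each injection.  The one-site model treats the macromolecule as carrying n
equivalent independent sites with association constant Ka and binding
enthalpy ΔH; the bound concentration after each injection follows from the
quadratic binding polynomial, and the injection heat is the change in
total binding enthalpy in the cell corrected for the displaced volume.

Thermodynamic relations (per mole, kcal units)::

    Kd = 1/Ka,   ΔG = R·T·ln(Kd[M]),   −TΔS = ΔG − ΔH

The Wiseman parameter c = n·Ka·[cell] governs identifiability: below
c ≈ 1 the isotherm is featureless (low-c warning) and above c ≈ 1000 the
sigmoid is a step and Ka is only bounded from below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import R_KCAL
from .errors import FitError, InputError


@dataclass
class ItcExperiment:
    """Injection schedule, concentrations and (optionally) observed heats."""

    cell_conc_uM: float          # macromolecule in the cell
    syringe_conc_uM: float       # ligand in the syringe
    injection_volumes_uL: np.ndarray
    cell_volume_uL: float = 200.0
    temperature_K: float = 298.15
    heats_ucal: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.injection_volumes_uL = np.asarray(
            self.injection_volumes_uL, dtype=float
        )
        if self.cell_conc_uM <= 0 or self.syringe_conc_uM <= 0:
            raise InputError("concentrations must be strictly positive")
        if self.cell_volume_uL <= 0 or np.any(self.injection_volumes_uL <= 0):
            raise InputError("volumes must be strictly positive")
        if np.any(self.injection_volumes_uL >= self.cell_volume_uL):
            raise InputError(
                "injection volume must be smaller than the cell volume"
            )
        if self.temperature_K <= 0:
            raise InputError("temperature must be positive")
        if self.heats_ucal is not None:
            self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
            if self.heats_ucal.size != self.injection_volumes_uL.size:
                raise InputError(
                    "heats must match the number of injections"
                )

    @property
    def n_injections(self) -> int:
        return self.injection_volumes_uL.size


@dataclass
class BindingParams:
    """One-site binding parameters with derived thermodynamics."""

    Ka_per_M: float
    dH_kcal_mol: float
    n: float = 1.0
    temperature_K: float = 298.15
    Ka_se: float | None = None
    dH_se: float | None = None
    n_se: float | None = None
    low_c_warning: bool = False
    high_c_warning: bool = False

    def __post_init__(self) -> None:
        if self.Ka_per_M <= 0:
            raise InputError("Ka must be strictly positive")
        if self.n <= 0:
            raise InputError("stoichiometry n must be strictly positive")

    @property
    def Kd_uM(self) -> float:
        return 1e6 / self.Ka_per_M

    @property
    def dG_kcal_mol(self) -> float:
        return thermo_relations(self.Kd_uM, self.dH_kcal_mol,
                                self.temperature_K)[0]

    @property
    def TdS_neg_kcal_mol(self) -> float:
        return thermo_relations(self.Kd_uM, self.dH_kcal_mol,
                                self.temperature_K)[1]

    def c_value(self, cell_conc_uM: float) -> float:
        return self.n * self.Ka_per_M * cell_conc_uM * 1e-6


def thermo_relations(
    Kd_uM: float, dH_kcal_mol: float, temperature_K: float = 298.15,
) -> tuple[float, float]:
    """(ΔG, −TΔS) in kcal/mol from Kd (µM) and ΔH (kcal/mol).

    ΔG = R·T·ln(Kd in M); −TΔS = ΔG − ΔH.  Kd of exactly 1 M gives
    ΔG = 0 (standard-state reference).
    """
    if Kd_uM <= 0:
        raise InputError("Kd must be strictly positive")
    dG = R_KCAL * temperature_K * math.log(Kd_uM * 1e-6)
    return dG, dG - dH_kcal_mol


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _bound_conc_M(site_M: float, ligand_M: float, Kd_M: float) -> float:
    """Bound-site concentration from the quadratic binding polynomial."""
    b = site_M + ligand_M + Kd_M
    disc = b * b - 4.0 * site_M * ligand_M
    if disc < 0:
        if disc < -1e-20 * b * b:
            raise FitError("negative discriminant in binding polynomial")
        disc = 0.0
    bound = 0.5 * (b - math.sqrt(disc))
    if bound < -1e-12 or bound > min(site_M, ligand_M) * (1 + 1e-9) + 1e-18:
        raise FitError("unphysical bound fraction")
    return max(bound, 0.0)


def one_site_heats(
    params: BindingParams, exp: ItcExperiment,
) -> np.ndarray:
    """Per-injection heats (µcal) for the one-site model.

    Cumulative-dilution bookkeeping uses the perfusion approximation: the
    cell volume stays constant and each injection of volume v dilutes both
    species by (1 − v/V0) while adding syringe·v/V0 of ligand.  The heat of
    injection i is the change in total binding enthalpy in the cell,
    q_i = ΔH·V0·(B_i − (1 − v/V0)·B_{i−1}), with B the bound concentration.
    """
    V0 = exp.cell_volume_uL
    Kd_M = 1.0 / params.Ka_per_M
    M = exp.cell_conc_uM * 1e-6       # running totals in M
    L = 0.0
    bound_prev = 0.0
    heats = np.empty(exp.n_injections)
    for i, dv in enumerate(exp.injection_volumes_uL):
        d = 1.0 - dv / V0
        if d <= 0:
            raise InputError("injection volume exceeds the cell volume")
        M *= d
        L = L * d + exp.syringe_conc_uM * 1e-6 * dv / V0
        bound = _bound_conc_M(params.n * M, L, Kd_M)
        # kcal/mol · mol/L · L -> kcal; ×1e9 -> µcal
        heats[i] = (
            params.dH_kcal_mol * (bound - d * bound_prev)
            * V0 * 1e-6 * 1e9
        )
        bound_prev = bound
    return heats


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class OneSiteItcRegressor(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the one-site ITC isotherm.

    ``X`` is (n, 1) injection volumes in µL and ``y`` the injection heats
    in µcal; the cell/syringe design lives in the constructor so fitted
    estimators can predict heats for alternative schedules.

    Attributes
    ----------
    Ka_, dH_, n_ : fitted association constant (M^-1), enthalpy
        (kcal/mol) and stoichiometry.
    Kd_uM_, dG_, TdS_neg_, c_ : derived quantities.
    low_c_warning_, high_c_warning_ : identifiability flags.
    """

    def __init__(self, cell_conc_uM: float = 6.0,
                 syringe_conc_uM: float = 50.0,
                 cell_volume_uL: float = 200.0,
                 temperature_K: float = 298.15,
                 skip_first: bool = False,
                 fix_n: float | None = None):
        self.cell_conc_uM = cell_conc_uM
        self.syringe_conc_uM = syringe_conc_uM
        self.cell_volume_uL = cell_volume_uL
        self.temperature_K = temperature_K
        self.skip_first = skip_first
        self.fix_n = fix_n

    def _experiment(self, volumes) -> ItcExperiment:
        return ItcExperiment(
            cell_conc_uM=self.cell_conc_uM,
            syringe_conc_uM=self.syringe_conc_uM,
            injection_volumes_uL=np.asarray(volumes, dtype=float).reshape(-1),
            cell_volume_uL=self.cell_volume_uL,
            temperature_K=self.temperature_K,
        )

    def fit(self, X, y):
        volumes = np.asarray(X, dtype=float).reshape(-1)
        heats = np.asarray(y, dtype=float).reshape(-1)
        if volumes.size != heats.size:
            raise InputError("X and y length mismatch")
        informative = volumes.size - (1 if self.skip_first else 0)
        if informative < 8:
            raise InputError("one-site fit needs >=8 informative injections")
        exp = self._experiment(volumes)
        mask = np.ones(volumes.size, dtype=bool)
        if self.skip_first:
            mask[0] = False

        total_heat = float(np.sum(heats))
        cell_moles = self.cell_conc_uM * 1e-6 * self.cell_volume_uL * 1e-6
        dH0 = total_heat * 1e-9 / max(cell_moles, 1e-30)  # µcal -> kcal
        if dH0 == 0:
            dH0 = -1.0

        def resid(p):
            v = p.valuesdict()
            bp = BindingParams(
                Ka_per_M=10.0 ** v["logKa"], dH_kcal_mol=v["dH"], n=v["n"],
                temperature_K=self.temperature_K,
            )
            try:
                model = one_site_heats(bp, exp)
            except FitError:
                return np.full(int(mask.sum()), 1e6)
            return model[mask] - heats[mask]

        best = None
        for logKa0 in (4.0, 5.0, 6.0, 7.0, 8.0, 9.0):
            params = lmfit.Parameters()
            params.add("logKa", value=logKa0, min=1.0, max=13.0)
            params.add("dH", value=dH0)
            if self.fix_n is None:
                params.add("n", value=1.0, min=0.05, max=10.0)
            else:
                # below c ~ 1 the isotherm cannot determine n; fixing a
                # known stoichiometry is standard low-c practice
                params.add("n", value=float(self.fix_n), vary=False)
            try:
                res = lmfit.minimize(resid, params, method="leastsq")
            except Exception:
                continue
            if res.success and (best is None or res.chisqr < best.chisqr):
                best = res
        if best is None:
            raise FitError("one-site ITC fit failed to converge")

        v = best.params
        self.result_ = best
        self.Ka_ = float(10.0 ** v["logKa"].value)
        self.dH_ = float(v["dH"].value)
        self.n_ = float(v["n"].value)
        logKa_se = v["logKa"].stderr
        self.Ka_se_ = (
            None if logKa_se is None
            else self.Ka_ * math.log(10.0) * float(logKa_se)
        )
        self.dH_se_ = None if v["dH"].stderr is None else float(v["dH"].stderr)
        self.n_se_ = None if v["n"].stderr is None else float(v["n"].stderr)
        self.Kd_uM_ = 1e6 / self.Ka_
        self.dG_, self.TdS_neg_ = thermo_relations(
            self.Kd_uM_, self.dH_, self.temperature_K
        )
        self.c_ = self.n_ * self.Ka_ * self.cell_conc_uM * 1e-6
        self.low_c_warning_ = self.c_ < 1.0
        self.high_c_warning_ = self.c_ > 1000.0
        return self

    def predict(self, X):
        exp = self._experiment(X)
        return one_site_heats(self.to_params(), exp)

    def to_params(self) -> BindingParams:
        return BindingParams(
            Ka_per_M=self.Ka_, dH_kcal_mol=self.dH_, n=self.n_,
            temperature_K=self.temperature_K,
            Ka_se=self.Ka_se_, dH_se=self.dH_se_, n_se=self.n_se_,
            low_c_warning=self.low_c_warning_,
            high_c_warning=self.high_c_warning_,
        )


def fit_itc(exp: ItcExperiment, skip_first: bool = False,
            fix_n: float | None = None) -> BindingParams:
    """Fit observed injection heats to the one-site model.

    ``fix_n`` clamps the stoichiometry (e.g. to 1.0) instead of fitting
    it — the usual choice for shallow, low-c isotherms where n is
    unidentifiable.
    """
    if exp.heats_ucal is None:
        raise InputError("experiment carries no observed heats")
    reg = OneSiteItcRegressor(
        cell_conc_uM=exp.cell_conc_uM,
        syringe_conc_uM=exp.syringe_conc_uM,
        cell_volume_uL=exp.cell_volume_uL,
        temperature_K=exp.temperature_K,
        skip_first=skip_first,
        fix_n=fix_n,
    )
    reg.fit(exp.injection_volumes_uL, exp.heats_ucal)
    return reg.to_params()
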